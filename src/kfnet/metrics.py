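"""Train/test performance reporting.

Continuous phenotypes: mean squared error and Pearson correlation.
Binary phenotypes: misclassification rate at a threshold and the area under
the ROC curve (the Mann-Whitney probability, ties counted one half).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import roc_auc_score


__all__ = ["FitReport", "mse_cor", "mce_auc", "report_table"]


@dataclass
class FitReport:
    """One row of the performance table (one data split)."""

    split: str
    kind: str  # "continuous" | "categorical"
    primary: float  # mse or mce
    secondary: float  # correlation or auc
    n: int
    flags: tuple[str, ...] = ()

    def as_dict(self) -> dict:
        names = ("mse", "cor") if self.kind == "continuous" else ("mce", "auc")
        return {
            "split": self.split,
            "kind": self.kind,
            names[0]: self.primary,
            names[1]: self.secondary,
            "n": self.n,
            "flags": list(self.flags),
        }


def mse_cor(y: np.ndarray, yhat: np.ndarray) -> tuple[float, float, list[str]]:
    """Mean squared error (population mean) and Pearson correlation.

    A zero-variance argument leaves the correlation undefined; it is
    reported as 0 with a flag rather than NaN.
    """
    y = np.asarray(y, dtype=float).ravel()
    yhat = np.asarray(yhat, dtype=float).ravel()
    if y.size != yhat.size or y.size < 2:
        raise ValueError("need two equal-length vectors of size >= 2")
    if not (np.isfinite(y).all() and np.isfinite(yhat).all()):
        raise ValueError("inputs must be finite")
    mse = float(np.mean((y - yhat) ** 2))
    flags: list[str] = []
    sy, syh = y.std(), yhat.std()
    if sy == 0.0 or syh == 0.0:
        cor = 0.0
        flags.append("zero-variance: correlation undefined, reported as 0")
    else:
        cor = float(np.corrcoef(y, yhat)[0, 1])
    return mse, cor, flags


def mce_auc(
    labels: np.ndarray, scores: np.ndarray, threshold: float = 0.5
) -> tuple[float, float, list[str]]:
    """Misclassification rate at ``threshold`` and ROC AUC.

    Scores at the threshold classify positive. AUC needs both classes; with
    one class absent it is reported as NaN with a flag.
    """
    labels = np.asarray(labels).ravel()
    scores = np.asarray(scores, dtype=float).ravel()
    if labels.size != scores.size:
        raise ValueError("labels and scores must have equal length")
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be 0/1")
    pred = (scores >= threshold).astype(int)
    mce = float(np.mean(pred != labels))
    flags: list[str] = []
    if labels.min() == labels.max():
        flags.append("single-class labels: AUC undefined")
        return mce, float("nan"), flags
    auc = float(roc_auc_score(labels, scores))
    return mce, auc, flags


def report_table(reports: list[FitReport]) -> str:
    """Aligned plain-text table mirroring the MSE/MCE + Cor/AUC layout."""
    kind = reports[0].kind
    head = ("MSE", "Cor") if kind == "continuous" else ("MCE", "AUC")
    lines = [f"{'split':<8s} {'n':>7s} {head[0]:>10s} {head[1]:>10s}"]
    for r in reports:
        lines.append(
            f"{r.split:<8s} {r.n:>7d} {r.primary:>10.4f} {r.secondary:>10.4f}"
        )
    return "\n".join(lines)


def report_json(reports: list[FitReport], **extra) -> str:
    payload = {"reports": [r.as_dict() for r in reports], **extra}
    return json.dumps(payload, indent=2, default=float)
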