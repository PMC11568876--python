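"""Batched fitting of the kernel variance-component model.

For cohorts too large to fit in one MINQUE solve, samples are split into B
near-equal batches, the model is fitted on each batch independently, and the
variance-component coefficients (and fixed effects) are averaged across
batches. Prediction then uses the averaged coefficients with cross kernels
against all training samples; per-batch prediction averaging is available as
an alternative mode.
"""

from __future__ import annotations

import warnings
from typing import Callable, Sequence

import numpy as np

from .kernels import KernelMatrix
from .knn import KnnModel, KnnSpec, expand_components, fit_knn, predict_knn

__all__ = ["split_batches", "fit_knn_batched", "predict_knn_batched"]


def split_batches(
    ids: Sequence, B: int, seed: int
) -> list[list[int]]:
    """Partition sample indices into B batches of near-equal size.

    The assignment is a deterministic function of ``seed``; batch sizes
    differ by at most one. Within each batch the original sample order is
    preserved, so ``B=1`` returns the identity ordering.
    """
    n = len(ids)
    if B < 1:
        raise ValueError("B must be >= 1")
    if B > n:
        raise ValueError(f"cannot split {n} samples into {B} batches")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    sizes = np.full(B, n // B)
    sizes[: n % B] += 1
    batches, start = [], 0
    for size in sizes:
        batch = np.sort(perm[start : start + size])
        batches.append(batch.tolist())
        start += size
    return batches


def _slice_spec(spec: KnnSpec, idx: list[int]) -> KnnSpec:
    ids = [spec.ids[i] for i in idx]
    kernels = [
        KernelMatrix(
            values=k.values[np.ix_(idx, idx)],
            row_ids=ids, col_ids=ids, kind=k.kind, params=dict(k.params),
        )
        for k in spec.input_kernels
    ]
    return KnnSpec(
        input_kernels=kernels, hidden=list(spec.hidden),
        Z=spec.Z[idx, :], ids=ids,
    )


def fit_knn_batched(
    spec: KnnSpec,
    y: np.ndarray,
    B: int,
    seed: int,
    max_iter: int = 20,
    tol: float = 1e-4,
    spec_builder: Callable[[list[int]], KnnSpec] | None = None,
) -> KnnModel:
    """Fit per batch and average the estimates.

    With ``B=1`` this is exactly :func:`kfnet.knn.fit_knn`. Per-batch input
    kernels are sliced from the full kernels unless ``spec_builder`` is
    given, in which case it receives the batch's sample indices and must
    return the batch spec (e.g. recomputing kernels from a genotype subset).
    Batches whose fit fails are dropped with a warning; the averaged model
    keeps the full-cohort components, y and Z so prediction uses all
    training samples.
    """
    y = np.asarray(y, dtype=float).ravel()
    if B == 1:
        return fit_knn(spec, y, max_iter=max_iter, tol=tol)
    batches = split_batches(spec.ids, B, seed)
    thetas, betas, per_batch = [], [], []
    for b, idx in enumerate(batches):
        sub = spec_builder(idx) if spec_builder else _slice_spec(spec, idx)
        try:
            model = fit_knn(sub, y[idx], max_iter=max_iter, tol=tol)
        except Exception as exc:  # noqa: BLE001 — batch failure is recoverable
            warnings.warn(f"batch {b}: fit failed ({exc}); dropped")
            per_batch.append(None)
            continue
        thetas.append(model.theta)
        betas.append(model.beta)
        per_batch.append(model)
    if not thetas:
        raise RuntimeError("all batches failed to fit")
    theta = np.mean(thetas, axis=0)
    beta = np.mean(betas, axis=0)
    components, labels = expand_components(spec)
    meta = {
        "batched": True,
        "B": B,
        "seed": seed,
        "batches": batches,
        "per_batch": per_batch,
        "n_dropped": sum(m is None for m in per_batch),
        "converged": all(
            m.fit_meta.get("converged", False) for m in per_batch if m
        ),
        "iterations": max(
            m.fit_meta.get("iterations", 0) for m in per_batch if m
        ),
    }
    return KnnModel(components, labels, theta, beta, y, spec.Z, meta)


def predict_knn_batched(
    model: KnnModel,
    cross: list[np.ndarray],
    Z_test: np.ndarray,
    mode: str = "average_parameters",
) -> np.ndarray:
    """Predict from a batched fit.

    ``average_parameters`` (default) predicts once with the averaged
    coefficients against all training samples. ``average_predictions``
    predicts with each per-batch model against its own batch and averages
    the predictions.
    """
    if mode == "average_parameters" or not model.fit_meta.get("batched"):
        return predict_knn(model, cross, Z_test)
    if mode != "average_predictions":
        raise ValueError(f"unknown prediction mode {mode!r}")
    preds = []
    for idx, sub in zip(model.fit_meta["batches"], model.fit_meta["per_batch"]):
        if sub is None:
            continue
        sub_cross = [C[:, idx] for C in cross]
        preds.append(predict_knn(sub, sub_cross, Z_test))
    return np.mean(preds, axis=0)
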