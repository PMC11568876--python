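"""Kernel-neural-network variance-component model.

The phenotype is modelled hierarchically: y | a ~ N(Z beta + a, phi I) with
the genetic random effect a having covariance sum_j tau_j H_j(U), where the
hidden kernels H_j are polynomial kernels built on latent Gaussian units
whose covariance is a positive combination of input genotype kernels
sum_l xi_l K_l.

Marginally Var(y) = sum_j tau_j E[H_j(U)] + phi I. For polynomial hidden
kernels of degree 1 or 2 the expectation is available in closed form
(:func:`kfnet.kernels.expected_hidden_kernel`) and is a polynomial in the
xi's, so the marginal covariance is linear in a set of free coefficients
theta_r over an expanded basis of known matrices V_r. Those coefficients are
what MINQUE estimates; the original (tau, xi) are never recovered —
prediction only needs sum_r theta_r V_r.

Estimation is MINQUE(0) for initial values followed by iterative MINQUE,
i.e. re-solving the MINQUE system with prior weights set to the previous
estimates until the coefficients stabilize.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

from .kernels import KernelMatrix, expected_hidden_kernel

__all__ = [
    "HiddenKernel",
    "KnnSpec",
    "KnnModel",
    "expand_components",
    "cross_components",
    "minque",
    "fit_knn",
    "predict_knn",
    "classify",
]


@dataclass(frozen=True)
class HiddenKernel:
    """Configuration of one hidden polynomial kernel H_j."""

    degree: int = 1
    offset: float = 0.0
    m: int = 1

    def __post_init__(self) -> None:
        if self.degree not in (1, 2):
            raise ValueError("hidden kernel degree must be 1 or 2")
        if self.m < 1:
            raise ValueError("hidden width m must be >= 1")


@dataclass
class KnnSpec:
    """Model specification: input kernels, hidden kernels, fixed design."""

    input_kernels: list[KernelMatrix]
    hidden: list[HiddenKernel]
    Z: np.ndarray
    ids: list[tuple[str, str]] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not self.input_kernels:
            raise ValueError("need at least one input kernel")
        if not self.hidden:
            raise ValueError("need at least one hidden kernel")
        self.Z = np.atleast_2d(np.asarray(self.Z, dtype=float))
        n = self.input_kernels[0].values.shape[0]
        if self.Z.shape[0] != n:
            raise ValueError("Z row count does not match kernel size")
        if self.Z.shape[1] >= n:
            raise ValueError("more fixed effects than samples")
        if self.ids is None:
            self.ids = list(self.input_kernels[0].row_ids)
        for k in self.input_kernels:
            if list(k.row_ids) != list(self.ids):
                raise ValueError("input kernels disagree on sample ids/order")


@dataclass
class KnnModel:
    """A fitted variance-component model.

    ``theta`` are the raw MINQUE coefficients of ``components`` (the last
    component is always the identity, whose coefficient is the residual
    variance phi); ``theta_trunc`` has negatives clipped to zero for
    prediction. ``fit_meta`` records iterations, convergence and any
    numerical interventions.
    """

    components: list[np.ndarray]
    labels: list[str]
    theta: np.ndarray
    beta: np.ndarray
    y: np.ndarray
    Z: np.ndarray
    fit_meta: dict = field(default_factory=dict)

    @property
    def theta_trunc(self) -> np.ndarray:
        return np.maximum(self.theta, 0.0)

    @property
    def phi(self) -> float:
        return float(self.theta[-1])

    def covariance(self, truncated: bool = True) -> np.ndarray:
        th = self.theta_trunc if truncated else self.theta
        return sum(t * V for t, V in zip(th, self.components))

    def summary(self) -> str:
        lines = ["component            theta"]
        for lab, t in zip(self.labels, self.theta):
            lines.append(f"{lab:<20s} {t: .6g}")
        lines.append(
            f"converged={self.fit_meta.get('converged')} "
            f"iterations={self.fit_meta.get('iterations')}"
        )
        return "\n".join(lines)


def _sym_outer(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return (np.outer(a, b) + np.outer(b, a)) / 2.0


def _expand_matrices(
    kernels: list[np.ndarray], hidden: list[HiddenKernel]
) -> tuple[list[np.ndarray], list[str]]:
    """Basis matrices V_r spanning sum_j tau_j E[H_j] over free coefficients.

    Degree-1 hidden kernels contribute the input kernels themselves (plus an
    all-ones matrix when the offset is non-zero). Degree-2 hidden kernels
    contribute, for every unordered pair (l, l') of input kernels,

        V = K_l o K_l' + (sym(d_l d_l'^T) + K_l o K_l') / m

    (o is the entrywise product, d_l = diag(K_l)) — the coefficient pattern
    of xi_l xi_l' in the degree-2 closed form — plus offset cross terms K_l
    and the all-ones matrix. Duplicate basis matrices arising from several
    hidden kernels are merged (their coefficients are not separately
    identifiable).
    """
    n = kernels[0].shape[0]
    ones = np.ones((n, n))
    out: dict[str, np.ndarray] = {}

    def add(label: str, V: np.ndarray) -> None:
        out.setdefault(label, V)

    for h in hidden:
        if h.degree == 1:
            for l, K in enumerate(kernels):
                add(f"K{l + 1}", K)
            if h.offset != 0.0:
                add("ones", ones)
        else:
            diags = [np.diag(K).copy() for K in kernels]
            for l, K in enumerate(kernels):
                for lp in range(l, len(kernels)):
                    Kp = kernels[lp]
                    V = K * Kp + (_sym_outer(diags[l], diags[lp]) + K * Kp) / h.m
                    add(f"K{l + 1}*K{lp + 1}|m={h.m}", V)
            if h.offset != 0.0:
                for l, K in enumerate(kernels):
                    add(f"K{l + 1}", K)
                add("ones", ones)
    return list(out.values()), list(out.keys())


def expand_components(spec: KnnSpec) -> tuple[list[np.ndarray], list[str]]:
    """Component matrices of the marginal covariance, identity appended last."""
    kernels = [k.values for k in spec.input_kernels]
    mats, labels = _expand_matrices(kernels, spec.hidden)
    n = kernels[0].shape[0]
    mats.append(np.eye(n))
    labels.append("residual")
    return mats, labels


def cross_components(
    stacked_kernels: list[KernelMatrix] | list[np.ndarray],
    n_test: int,
    hidden: list[HiddenKernel],
) -> tuple[list[np.ndarray], list[str]]:
    """Test-by-train blocks of the component matrices.

    ``stacked_kernels`` are the square input kernels computed on test samples
    stacked above training samples. Expanding on the stacked matrix and
    slicing the off-diagonal block guarantees exact consistency with the
    training-side expansion (the residual identity component is excluded:
    test residuals are independent of training ones).
    """
    mats = [
        k.values if isinstance(k, KernelMatrix) else np.asarray(k, float)
        for k in stacked_kernels
    ]
    full, labels = _expand_matrices(mats, hidden)
    return [V[:n_test, n_test:] for V in full], labels


def _projected_inverse(Vw: np.ndarray, Z: np.ndarray, ridge_log: list):
    """R = Vw^-1 - Vw^-1 Z (Z' Vw^-1 Z)^-1 Z' Vw^-1, with a ridge fallback."""
    n = Vw.shape[0]
    try:
        c = linalg.cho_factor(Vw, check_finite=False)
    except linalg.LinAlgError:
        bump = 1e-8 * np.trace(Vw) / n
        ridge_log.append(bump)
        c = linalg.cho_factor(Vw + bump * np.eye(n), check_finite=False)
    Vi = linalg.cho_solve(c, np.eye(n), check_finite=False)
    ViZ = Vi @ Z
    middle = linalg.solve(Z.T @ ViZ, ViZ.T, assume_a="sym")
    return Vi - ViZ @ middle, Vi


def minque(
    y: np.ndarray,
    Z: np.ndarray,
    components: list[np.ndarray],
    weights: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """One MINQUE solve for the variance-component coefficients.

    Solves S theta = q with S_rs = tr(R V_r R V_s) and q_r = y' R V_r R y,
    where R projects out the fixed effects under the working covariance
    V_w = sum_r weights_r V_r. ``weights=None`` gives MINQUE(0) (V_w = I).
    Returns (theta, beta_GLS, info); beta is GLS under the truncated
    estimated covariance.
    """
    y = np.asarray(y, dtype=float).ravel()
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    n = y.size
    c = len(components)
    info: dict = {"ridge_bumps": [], "singular_S": False}
    if weights is None:
        Vw = np.eye(n)
    else:
        weights = np.asarray(weights, dtype=float)
        Vw = sum(w * V for w, V in zip(weights, components))
    R, _ = _projected_inverse(Vw, Z, info["ridge_bumps"])
    RV = [R @ V for V in components]
    Ry = R @ y
    S = np.empty((c, c))
    for r in range(c):
        for s in range(r, c):
            S[r, s] = S[s, r] = np.sum(RV[r] * RV[s].T)
    q = np.array([Ry @ V @ Ry for V in components])
    try:
        theta = linalg.solve(S, q, assume_a="sym")
        resid = np.linalg.norm(S @ theta - q)
        if resid > 1e-8 * max(np.linalg.norm(q), 1e-300):
            raise linalg.LinAlgError("inaccurate solve")
    except linalg.LinAlgError:
        info["singular_S"] = True
        theta = np.linalg.pinv(S) @ q
    info["system_residual"] = float(
        np.linalg.norm(S @ theta - q) / max(np.linalg.norm(q), 1e-300)
    )
    info["S"], info["q"] = S, q
    beta = _gls_beta(y, Z, components, theta)
    return theta, beta, info


def _floored_weights(theta: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Truncate negatives; floor the residual coefficient to keep Vw PD."""
    w = np.maximum(theta, 0.0)
    floor = 1e-6 * max(float(np.var(y)), 1e-12)
    w[-1] = max(w[-1], floor)
    return w


def _gls_beta(y, Z, components, theta) -> np.ndarray:
    w = _floored_weights(theta, y)
    V = sum(t * M for t, M in zip(w, components))
    try:
        c = linalg.cho_factor(V, check_finite=False)
        ViZ = linalg.cho_solve(c, Z, check_finite=False)
        Viy = linalg.cho_solve(c, y, check_finite=False)
    except linalg.LinAlgError:
        Vi = np.linalg.pinv(V)
        ViZ, Viy = Vi @ Z, Vi @ y
    return linalg.solve(Z.T @ ViZ, Z.T @ Viy, assume_a="sym")


def fit_knn(
    spec: KnnSpec,
    y: np.ndarray,
    max_iter: int = 20,
    tol: float = 1e-4,
) -> KnnModel:
    """MINQUE(0) initial values followed by iterative MINQUE.

    Iteration stops when the maximum relative change of the coefficient
    vector falls below ``tol`` (relative to the coefficient scale) or after
    ``max_iter`` rounds; non-convergence is flagged, not raised.
    """
    y = np.asarray(y, dtype=float).ravel()
    components, labels = expand_components(spec)
    n = y.size
    if components[0].shape[0] != n:
        raise ValueError("y length does not match kernel size")
    meta: dict = {"labels": labels}
    if np.var(y) < 1e-12 * max(1.0, np.mean(y) ** 2):
        theta = np.zeros(len(components))
        beta = _gls_beta(y, spec.Z, components, np.ones(len(components)))
        meta.update(
            converged=True, iterations=0, degenerate=True,
            system_residual=0.0, history=[theta],
        )
        return KnnModel(components, labels, theta, beta, y, spec.Z, meta)

    theta, beta, info = minque(y, spec.Z, components, weights=None)
    history = [theta]
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        weights = _floored_weights(theta, y)
        theta_new, beta, info = minque(y, spec.Z, components, weights=weights)
        scale = max(np.max(np.abs(theta_new)), 1e-12)
        delta = np.max(np.abs(theta_new - theta)) / scale
        theta = theta_new
        history.append(theta)
        if delta < tol:
            converged = True
            break
    meta.update(
        converged=converged,
        iterations=iterations,
        degenerate=False,
        history=history,
        system_residual=info["system_residual"],
        singular_S=info["singular_S"],
        ridge_bumps=info["ridge_bumps"],
        minque0_theta=history[0],
    )
    return KnnModel(components, labels, theta, beta, y, spec.Z, meta)


def predict_knn(
    model: KnnModel,
    cross: list[np.ndarray],
    Z_test: np.ndarray,
) -> np.ndarray:
    """BLUP-style prediction for new samples.

    yhat = Z_test beta + (sum_r theta_r C_r) V^-1 (y - Z beta) with
    coefficients truncated at zero and V the truncated training covariance
    (residual variance floored for invertibility). ``cross`` are the
    test-by-train component blocks in training order, excluding the identity.
    """
    Z_test = np.atleast_2d(np.asarray(Z_test, dtype=float))
    if len(cross) != len(model.components) - 1:
        raise ValueError(
            f"{len(cross)} cross components given, "
            f"expected {len(model.components) - 1}"
        )
    n_train = model.y.size
    for C in cross:
        if C.shape != (Z_test.shape[0], n_train):
            raise ValueError("cross component shape mismatch")
    w = _floored_weights(model.theta, model.y)
    V = sum(t * M for t, M in zip(w, model.components))
    resid = model.y - model.Z @ model.beta
    alpha = linalg.solve(V, resid, assume_a="pos")
    C_total = sum(t * C for t, C in zip(w[:-1], cross))
    if isinstance(C_total, int):  # all-zero coefficients
        C_total = np.zeros((Z_test.shape[0], n_train))
    return Z_test @ model.beta + C_total @ alpha


def classify(scores: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Binary labels from scores; ties at the threshold go to class 1."""
    return (np.asarray(scores, dtype=float) >= threshold).astype(int)
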