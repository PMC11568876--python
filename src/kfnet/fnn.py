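"""Functional neural network for candidate-gene analysis.

Genotypes in a region are smoothed into curves G(t) on a B-spline basis over
rescaled genomic position. Each hidden layer d maps the incoming function
x(t) to a pre-activation function

    h(s) = alpha0_d(s) + \\int alpha_d(s, t) x(t) dt   (+ covariates, layer 1)

with alpha0_d expanded on the layer's basis and alpha_d on the tensor
product of adjacent layers' bases, so the integral reduces to matrix algebra
through the basis Gram matrix. The activation is applied pointwise on a
Gauss-Legendre grid and re-projected onto the layer basis. The scalar head
is alpha0 + \\int alpha(t) x(t) dt, with a logistic link for binary traits.

The loss is mean squared error or mean cross-entropy plus a roughness
penalty lambda * (integrated squared second derivatives of every parameter
function), computed exactly from spline Gram matrices. Training is
full-batch adam with analytic gradients; the penalty weight is selected on
validation data loss over a grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .basis import BasisSystem
from .io_genetics import GenotypeMatrix

__all__ = [
    "BasisSystem",
    "FunctionalCurve",
    "FnnModel",
    "smooth_genotypes",
    "init_fnn",
    "forward",
    "loss",
    "grad",
    "train",
    "fit_flm",
    "predict_flm",
]


@dataclass
class FunctionalCurve:
    """A batch of curves: coefficient rows on a shared basis."""

    basis: BasisSystem
    coefs: np.ndarray  # n x dim

    def __post_init__(self) -> None:
        self.coefs = np.atleast_2d(np.asarray(self.coefs, dtype=float))
        if self.coefs.shape[1] != self.basis.dim:
            raise ValueError("coefficient width does not match basis dimension")

    def __call__(self, t: np.ndarray) -> np.ndarray:
        return self.coefs @ self.basis.evaluate(t).T


def smooth_genotypes(
    x: GenotypeMatrix,
    basis: BasisSystem,
    smooth_lambda: float = 1e-6,
) -> FunctionalCurve:
    """Penalized least-squares projection of each sample's dosages onto the
    basis, over min-max rescaled base-pair positions.

    Missing dosages are simply omitted from the residual sum — the smoothing
    itself supplies the missing-data handling.
    """
    order = np.argsort([v.bp_pos for v in x.variants])
    bp = np.array([x.variants[k].bp_pos for k in order], dtype=float)
    if np.any(np.diff(bp) <= 0):
        raise ValueError("variant positions must be strictly increasing")
    t = (bp - bp[0]) / max(bp[-1] - bp[0], 1.0)
    d = x.dosages[:, order]
    B = basis.evaluate(t)  # p x dim
    Omega = basis.gram(2, 2)
    if smooth_lambda == 0.0 and d.shape[1] < basis.dim:
        raise ValueError(
            "fewer variants than basis functions and no smoothing penalty: "
            "the projection is underdetermined"
        )
    A = B.T @ B + smooth_lambda * Omega
    missing = np.isnan(d)
    coefs = np.empty((d.shape[0], basis.dim))
    complete = ~missing.any(axis=1)
    if complete.any():
        coefs[complete] = np.linalg.solve(A, B.T @ d[complete].T).T
    for i in np.where(~complete)[0]:
        obs = ~missing[i]
        Bi = B[obs]
        Ai = Bi.T @ Bi + smooth_lambda * Omega
        coefs[i] = np.linalg.solve(Ai, Bi.T @ d[i, obs])
    return FunctionalCurve(basis=basis, coefs=coefs)


# ---------------------------------------------------------------------------
# model container and precomputed geometry
# ---------------------------------------------------------------------------

_ACTIVATIONS = {
    "tanh": (np.tanh, lambda v: 1.0 - np.tanh(v) ** 2),
    "relu": (lambda v: np.maximum(v, 0.0), lambda v: (v > 0).astype(float)),
    "identity": (lambda v: v, lambda v: np.ones_like(v)),
}


@dataclass
class FnnModel:
    """Parameter functions of a functional network.

    ``bases[0]`` is the input-curve basis; ``bases[1:]`` are the hidden-layer
    bases. Hidden layer d (1-based) owns an intercept function ``a0[d-1]``
    on ``bases[d]`` and a weight kernel ``W[d-1]`` of shape
    (bases[d].dim, bases[d-1].dim). ``Wz`` injects covariates at the first
    layer; the scalar head is (a0_out, w_out) on the last hidden basis.
    """

    bases: list[BasisSystem]
    W: list[np.ndarray]
    a0: list[np.ndarray]
    Wz: np.ndarray
    w_out: np.ndarray
    a0_out: float
    activation: str = "tanh"
    binary: bool = False
    _geom: dict = field(default_factory=dict, repr=False)

    def geometry(self) -> dict:
        """Cache Gram matrices, quadrature grids and projection operators."""
        if not self._geom:
            g: dict = {"J": [], "E": [], "P": [], "Omega": []}
            for basis in self.bases:
                g["J"].append(basis.gram(0, 0))
                g["Omega"].append(basis.gram(2, 2))
                tq, wq = basis.quadrature()
                E = basis.evaluate(tq)
                Lam = wq[:, None]
                P = np.linalg.solve(E.T @ (Lam * E), (Lam * E).T)
                g["E"].append(E)
                g["P"].append(P)
            self._geom = g
        return self._geom

    def parameters(self) -> dict[str, np.ndarray | float]:
        out: dict = {"Wz": self.Wz, "w_out": self.w_out, "a0_out": self.a0_out}
        for d, (w, a) in enumerate(zip(self.W, self.a0)):
            out[f"W{d + 1}"] = w
            out[f"a0_{d + 1}"] = a
        return out

    def set_parameters(self, params: dict) -> None:
        self.Wz = params["Wz"]
        self.w_out = params["w_out"]
        self.a0_out = float(params["a0_out"])
        for d in range(len(self.W)):
            self.W[d] = params[f"W{d + 1}"]
            self.a0[d] = params[f"a0_{d + 1}"]


def _poly_modes(basis: BasisSystem, n_modes: int) -> np.ndarray:
    """Spline coefficients of the first Legendre polynomials on [0, 1].

    Least-squares projection on a dense grid; splines of order >= 3
    reproduce degree <= 2 polynomials essentially exactly.
    """
    t = np.linspace(0.0, 1.0, 201)
    B = basis.evaluate(t)
    targets = np.polynomial.legendre.legvander(2.0 * t - 1.0, n_modes - 1)
    coefs, *_ = np.linalg.lstsq(B, targets, rcond=None)
    return coefs  # dim x n_modes


def init_fnn(
    input_basis: BasisSystem,
    hidden_knots: tuple[int, ...] = (100, 50),
    n_covariates: int = 0,
    order: int = 4,
    activation: str = "tanh",
    binary: bool = False,
    seed: int = 0,
) -> FnnModel:
    """Fresh model with N(0, 1/fan_in) coefficients from the seed."""
    if activation not in _ACTIVATIONS:
        raise ValueError(f"unknown activation {activation!r}")
    rng = np.random.default_rng(seed)
    bases = [input_basis] + [
        BasisSystem(knots=k, order=order) for k in hidden_knots
    ]
    # Weight kernels are initialized as smooth low-rank random surfaces,
    # alpha(s, t) = sum_jk Z_jk P_j(s) P_k(t) over low-degree Legendre
    # modes projected onto the spline bases. White noise on spline
    # coefficients would be a rough function (a huge roughness penalty at
    # the start) and the basis Gram matrix would shrink its integral by
    # 1/dim; smooth modes keep both the penalty and the layer output scale
    # under control.
    n_modes = 3
    W, a0 = [], []
    for d in range(1, len(bases)):
        P_out = _poly_modes(bases[d], n_modes)
        P_in = _poly_modes(bases[d - 1], n_modes)
        Zr = rng.normal(0.0, 1.0 / n_modes, size=(n_modes, n_modes))
        W.append(P_out @ Zr @ P_in.T)
        a0.append(P_out @ rng.normal(0.0, 0.3, size=n_modes))
    Wz = (
        rng.normal(0.0, 1.0 / np.sqrt(n_covariates),
                   size=(bases[1].dim, n_covariates))
        if n_covariates
        else np.zeros((bases[1].dim, 0))
    )
    w_out = _poly_modes(bases[-1], n_modes) @ rng.normal(
        0.0, 1.0, size=n_modes
    )
    return FnnModel(
        bases=bases, W=W, a0=a0, Wz=Wz, w_out=w_out, a0_out=0.0,
        activation=activation, binary=binary,
    )


# ---------------------------------------------------------------------------
# forward / loss / gradient
# ---------------------------------------------------------------------------

def forward(
    model: FnnModel,
    curves: FunctionalCurve | np.ndarray,
    Z: np.ndarray | None = None,
    return_cache: bool = False,
):
    """Network output for a batch of curves (+ optional covariates).

    Returns raw outputs f (linear predictor); for binary models the class
    probability is sigmoid(f) — apply :func:`predict_proba` or use the
    cached logits directly.
    """
    C = curves.coefs if isinstance(curves, FunctionalCurve) else np.atleast_2d(curves)
    if isinstance(curves, FunctionalCurve) and curves.basis is not model.bases[0]:
        if curves.basis.dim != model.bases[0].dim:
            raise ValueError("curve basis does not match model input basis")
    g = model.geometry()
    sigma, _ = _ACTIVATIONS[model.activation]
    n = C.shape[0]
    q = model.Wz.shape[1]
    if q and (Z is None or np.atleast_2d(Z).shape[1] != q):
        raise ValueError(f"model expects {q} covariates")
    cache = {"C": [C], "V": [], "M": []}
    for d in range(len(model.W)):
        M = model.a0[d][None, :] + C @ g["J"][d] @ model.W[d].T
        if d == 0 and q:
            M = M + np.atleast_2d(Z) @ model.Wz.T
        V = M @ g["E"][d + 1].T
        S = sigma(V)
        C = S @ g["P"][d + 1].T
        cache["M"].append(M)
        cache["V"].append(V)
        cache["C"].append(C)
    f = model.a0_out + C @ (g["J"][-1] @ model.w_out)
    if return_cache:
        return f, cache
    return f


def predict_proba(model: FnnModel, curves, Z=None) -> np.ndarray:
    f = forward(model, curves, Z)
    return 1.0 / (1.0 + np.exp(-f))


def penalty(model: FnnModel) -> float:
    """Sum of integrated squared second derivatives of all parameter
    functions (exact, via spline Gram matrices)."""
    g = model.geometry()
    total = 0.0
    for d in range(len(model.W)):
        Om_s, Om_t = g["Omega"][d + 1], g["Omega"][d]
        J_s, J_t = g["J"][d + 1], g["J"][d]
        W = model.W[d]
        total += float(model.a0[d] @ Om_s @ model.a0[d])
        total += float(np.sum((Om_s @ W) * (W @ J_t)))  # d2/ds2
        total += float(np.sum((J_s @ W) * (W @ Om_t)))  # d2/dt2
        if d == 0 and model.Wz.shape[1]:
            total += float(np.sum(model.Wz * (Om_s @ model.Wz)))
    total += float(model.w_out @ g["Omega"][-1] @ model.w_out)
    return total


def _data_loss(f: np.ndarray, y: np.ndarray, binary: bool) -> float:
    if binary:
        if not np.isin(y, (0, 1)).all():
            raise ValueError("cross-entropy requires 0/1 labels")
        # stable log(1 + exp(f)) - y f
        return float(np.mean(np.logaddexp(0.0, f) - y * f))
    return float(np.mean((f - y) ** 2))


def loss(
    model: FnnModel,
    curves,
    y: np.ndarray,
    Z: np.ndarray | None = None,
    lam: float = 0.0,
) -> float:
    """Penalized loss: data term + lam * roughness penalty."""
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    f = forward(model, curves, Z)
    return _data_loss(f, np.asarray(y, float).ravel(), model.binary) + (
        lam * penalty(model) if lam else 0.0
    )


def grad(
    model: FnnModel,
    curves,
    y: np.ndarray,
    Z: np.ndarray | None = None,
    lam: float = 0.0,
) -> tuple[float, dict]:
    """Penalized loss and its analytic gradient in all parameters."""
    y = np.asarray(y, float).ravel()
    g = model.geometry()
    _, dsigma = _ACTIVATIONS[model.activation]
    f, cache = forward(model, curves, Z, return_cache=True)
    n = y.size
    if model.binary:
        df = (1.0 / (1.0 + np.exp(-f)) - y) / n
    else:
        df = 2.0 * (f - y) / n
    grads: dict = {}
    C_last = cache["C"][-1]
    grads["a0_out"] = float(df.sum())
    grads["w_out"] = g["J"][-1] @ (C_last.T @ df)
    dC = np.outer(df, g["J"][-1] @ model.w_out)
    for d in range(len(model.W) - 1, -1, -1):
        dS = dC @ g["P"][d + 1]
        dV = dS * dsigma(cache["V"][d])
        dM = dV @ g["E"][d + 1]
        grads[f"a0_{d + 1}"] = dM.sum(axis=0)
        grads[f"W{d + 1}"] = dM.T @ (cache["C"][d] @ g["J"][d])
        if d == 0:
            if model.Wz.shape[1]:
                grads["Wz"] = dM.T @ np.atleast_2d(Z)
            else:
                grads["Wz"] = np.zeros_like(model.Wz)
        else:
            dC = dM @ model.W[d] @ g["J"][d]
    value = _data_loss(f, y, model.binary)
    if lam:
        value += lam * penalty(model)
        for d in range(len(model.W)):
            Om_s, Om_t = g["Omega"][d + 1], g["Omega"][d]
            J_s, J_t = g["J"][d + 1], g["J"][d]
            W = model.W[d]
            grads[f"a0_{d + 1}"] = grads[f"a0_{d + 1}"] + lam * 2 * Om_s @ model.a0[d]
            grads[f"W{d + 1}"] = grads[f"W{d + 1}"] + lam * 2 * (
                Om_s @ W @ J_t + J_s @ W @ Om_t
            )
        if model.Wz.shape[1]:
            grads["Wz"] = grads["Wz"] + lam * 2 * g["Omega"][1] @ model.Wz
        grads["w_out"] = grads["w_out"] + lam * 2 * g["Omega"][-1] @ model.w_out
    return value, grads


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _adam_step(params, grads, state, lr, b1=0.9, b2=0.999, eps=1e-8):
    state["t"] += 1
    t = state["t"]
    for k, p in params.items():
        gk = np.asarray(grads[k], dtype=float)
        state["m"][k] = b1 * state["m"][k] + (1 - b1) * gk
        state["v"][k] = b2 * state["v"][k] + (1 - b2) * gk**2
        mhat = state["m"][k] / (1 - b1**t)
        vhat = state["v"][k] / (1 - b2**t)
        step = lr * mhat / (np.sqrt(vhat) + eps)
        params[k] = p - step if np.ndim(p) else float(p - step)
    return params


def _clone_params(params: dict) -> dict:
    return {
        k: (float(v) if np.ndim(v) == 0 else np.array(v, copy=True))
        for k, v in params.items()
    }


def train(
    model_factory,
    train_data: tuple,
    valid_data: tuple,
    lambdas=(1e-4, 1e-3, 1e-2, 1e-1, 1.0, 10.0),
    epochs: int = 500,
    lr: float = 1e-3,
    seed: int = 0,
) -> tuple[FnnModel, float, dict]:
    """Train one model per penalty weight; keep the best validation loss.

    ``model_factory(seed)`` must return a fresh model, so every lambda starts
    from the identical seed-determined initialization. ``train_data`` and
    ``valid_data`` are (curves, y) or (curves, Z, y) tuples. Training is
    full-batch adam; a NaN loss halves the learning rate and restarts once.
    Returns (best model, selected lambda, history).
    """
    def unpack(data):
        if len(data) == 2:
            return data[0], None, np.asarray(data[1], float).ravel()
        return data[0], data[1], np.asarray(data[2], float).ravel()

    Ct, Zt, yt = unpack(train_data)
    Cv, Zv, yv = unpack(valid_data)
    best = None
    history: dict = {"lambdas": {}, "selected": None}
    for lam in lambdas:
        result = _train_one(model_factory, Ct, Zt, yt, lam, epochs, lr, seed)
        model = result["model"]
        fv = forward(model, Cv, Zv)
        val_loss = _data_loss(fv, yv, model.binary)
        history["lambdas"][lam] = {
            "final_train_loss": result["final_loss"],
            "initial_train_loss": result["initial_loss"],
            "valid_loss": val_loss,
            "restarted": result["restarted"],
        }
        if best is None or val_loss < best[1]:
            best = (model, val_loss, lam)
    history["selected"] = best[2]
    return best[0], best[2], history


def _train_one(model_factory, C, Z, y, lam, epochs, lr, seed):
    restarted = False
    while True:
        model: FnnModel = model_factory(seed)
        params = _clone_params(model.parameters())
        state = {
            "t": 0,
            "m": {k: np.zeros_like(np.asarray(v, float)) for k, v in params.items()},
            "v": {k: np.zeros_like(np.asarray(v, float)) for k, v in params.items()},
        }
        model.set_parameters(params)
        initial_loss = loss(model, C, y, Z, lam)
        value = initial_loss
        failed = False
        for _ in range(epochs):
            value, grads = grad(model, C, y, Z, lam)
            if not np.isfinite(value):
                failed = True
                break
            params = _adam_step(params, grads, state, lr)
            model.set_parameters(params)
        if failed or not np.isfinite(value):
            if restarted:
                raise FloatingPointError(
                    "training diverged (NaN loss) even after halving the "
                    "learning rate"
                )
            restarted, lr = True, lr / 2.0
            continue
        final_loss = loss(model, C, y, Z, lam)
        return {
            "model": model,
            "initial_loss": initial_loss,
            "final_loss": final_loss,
            "restarted": restarted,
        }


# ---------------------------------------------------------------------------
# functional linear model (single linear layer) — closed-form reference
# ---------------------------------------------------------------------------

def fit_flm(
    curves: FunctionalCurve,
    y: np.ndarray,
    Z: np.ndarray | None = None,
    lam: float = 0.0,
):
    """Penalized functional linear regression y = a0 + <alpha, G> (+ Z gamma).

    Directly assembles the normal equations in the basis-coefficient
    parameterization: the design column block for alpha is C J (curve
    coefficients times the basis Gram matrix), and the roughness penalty is
    the second-derivative Gram matrix. Serves both as a baseline model and
    as the closed-form reduction of a single linear functional layer.
    """
    C = curves.coefs
    J = curves.basis.gram(0, 0)
    Om = curves.basis.gram(2, 2)
    y = np.asarray(y, float).ravel()
    n = y.size
    blocks = [np.ones((n, 1)), C @ J]
    if Z is not None and np.atleast_2d(Z).shape[1]:
        blocks.append(np.atleast_2d(Z))
    X = np.column_stack(blocks)
    pdim = X.shape[1]
    P = np.zeros((pdim, pdim))
    P[1 : 1 + J.shape[0], 1 : 1 + J.shape[0]] = Om
    coef = np.linalg.solve(X.T @ X / n + lam * P, X.T @ y / n)
    return {"coef": coef, "basis": curves.basis, "has_Z": len(blocks) == 3,
            "nz": 0 if len(blocks) < 3 else np.atleast_2d(Z).shape[1]}


def predict_flm(flm: dict, curves: FunctionalCurve, Z=None) -> np.ndarray:
    C = curves.coefs
    J = curves.basis.gram(0, 0)
    blocks = [np.ones((C.shape[0], 1)), C @ J]
    if flm["has_Z"]:
        blocks.append(np.atleast_2d(Z))
    return np.column_stack(blocks) @ flm["coef"]
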