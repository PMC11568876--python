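"""Kernel matrices on genotypes and their expected hidden-layer analogues.

Built-in square kernels (product, Gaussian, polynomial), the matching
test-by-train cross kernels, and the closed-form expectation of a polynomial
kernel built on Gaussian latent units — the quantity the kernel neural
network's marginal covariance is assembled from.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .io_genetics import AlignmentError, GenotypeMatrix

__all__ = [
    "KernelMatrix",
    "product_kernel",
    "gaussian_kernel",
    "polynomial_kernel",
    "cross_kernel",
    "expected_hidden_kernel",
]


@dataclass
class KernelMatrix:
    """A similarity matrix with sample identity attached.

    Square kernels have ``row_ids == col_ids`` and are symmetric PSD within
    numerical tolerance; cross kernels (test x train) carry both id lists.
    """

    values: np.ndarray
    row_ids: list[tuple[str, str]]
    col_ids: list[tuple[str, str]]
    kind: str = "custom"
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.row_ids), len(self.col_ids)):
            raise ValueError("kernel shape does not match id lists")

    @property
    def is_square(self) -> bool:
        return self.row_ids == self.col_ids

    def validate(self, sym_tol: float = 1e-10, psd_rel_tol: float = 1e-8) -> None:
        """Check symmetry and positive semi-definiteness of a square kernel."""
        if not self.is_square:
            raise ValueError("validate() applies to square kernels only")
        v = self.values
        if not np.allclose(v, v.T, atol=sym_tol):
            raise ValueError("kernel is not symmetric")
        w = np.linalg.eigvalsh((v + v.T) / 2)
        floor = -psd_rel_tol * max(np.trace(v), 1.0) / v.shape[0]
        if w.min() < floor:
            raise ValueError(f"kernel not PSD: min eigenvalue {w.min():.3g}")


def _dense(x: GenotypeMatrix | np.ndarray) -> np.ndarray:
    d = x.dosages if isinstance(x, GenotypeMatrix) else np.asarray(x, float)
    if np.isnan(d).any():
        raise ValueError("missing dosages: impute (see io_genetics.impute_mean)"
                         " before kernel construction")
    return d


def _ids(x: GenotypeMatrix | np.ndarray) -> list[tuple[str, str]]:
    if isinstance(x, GenotypeMatrix):
        return list(x.samples)
    return [("0", str(i)) for i in range(np.asarray(x).shape[0])]


def _standardize(d: np.ndarray, mean=None, std=None):
    """Column-standardize, dropping zero-variance variants (with a warning)."""
    if mean is None:
        mean = d.mean(axis=0)
        std = d.std(axis=0)
    keep = std > 0
    if not keep.all():
        warnings.warn(
            f"dropping {int((~keep).sum())} zero-variance variant(s) "
            "before standardization"
        )
    return (d[:, keep] - mean[keep]) / std[keep], mean, std


def product_kernel(
    x: GenotypeMatrix | np.ndarray, standardize: bool = False
) -> KernelMatrix:
    """K = X X^T / p — the product (linear) kernel.

    With ``standardize`` the columns are centred and scaled first, which makes
    K the GCTA-style genetic relationship matrix.
    """
    d = _dense(x)
    if standardize:
        d, _, _ = _standardize(d)
    p = d.shape[1]
    ids = _ids(x)
    return KernelMatrix(
        values=d @ d.T / p, row_ids=ids, col_ids=ids,
        kind="product", params={"standardize": standardize},
    )


def gaussian_kernel(
    x: GenotypeMatrix | np.ndarray, bandwidth: float = 1.0
) -> KernelMatrix:
    """K_ij = exp(-||x_i - x_j||^2 / (bandwidth * p)).

    The squared distance is divided by the variant count p so the bandwidth
    is dimensionless in the number of SNPs.
    """
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    d = _dense(x)
    p = d.shape[1]
    sq = cdist(d, d, metric="sqeuclidean")
    values = np.exp(-sq / (bandwidth * p))
    np.fill_diagonal(values, 1.0)
    ids = _ids(x)
    return KernelMatrix(
        values=values, row_ids=ids, col_ids=ids,
        kind="gaussian", params={"bandwidth": bandwidth},
    )


def polynomial_kernel(
    x: GenotypeMatrix | np.ndarray, degree: int = 2, offset: float = 1.0
) -> KernelMatrix:
    """K = (X X^T / p + offset)^degree, entrywise power."""
    if degree < 1:
        raise ValueError("degree must be >= 1")
    d = _dense(x)
    p = d.shape[1]
    values = (d @ d.T / p + offset) ** degree
    ids = _ids(x)
    return KernelMatrix(
        values=values, row_ids=ids, col_ids=ids,
        kind="polynomial", params={"degree": degree, "offset": offset},
    )


def cross_kernel(
    x_test: GenotypeMatrix | np.ndarray,
    x_train: GenotypeMatrix | np.ndarray,
    kind: str = "product",
    **params,
) -> KernelMatrix:
    """Test-by-train kernel consistent with the square kernel on stacked data.

    Standardization statistics, when requested for the product kernel, are
    taken from the training set only.
    """
    dt, dr = _dense(x_test), _dense(x_train)
    if dt.shape[1] != dr.shape[1]:
        raise AlignmentError("test and train variant counts differ")
    if isinstance(x_test, GenotypeMatrix) and isinstance(x_train, GenotypeMatrix):
        if [v.id for v in x_test.variants] != [v.id for v in x_train.variants]:
            raise AlignmentError("test and train variant lists differ")
    p = dr.shape[1]
    if kind == "product":
        if params.get("standardize", False):
            dr_s, mean, std = _standardize(dr)
            dt_s, _, _ = _standardize(dt, mean, std)
            values = dt_s @ dr_s.T / p
        else:
            values = dt @ dr.T / p
    elif kind == "gaussian":
        bw = params.get("bandwidth", 1.0)
        if bw <= 0:
            raise ValueError("bandwidth must be positive")
        values = np.exp(-cdist(dt, dr, metric="sqeuclidean") / (bw * p))
    elif kind == "polynomial":
        degree = params.get("degree", 2)
        if degree < 1:
            raise ValueError("degree must be >= 1")
        values = (dt @ dr.T / p + params.get("offset", 1.0)) ** degree
    else:
        raise ValueError(f"unknown kernel kind {kind!r}")
    return KernelMatrix(
        values=values, row_ids=_ids(x_test), col_ids=_ids(x_train),
        kind=kind, params=dict(params),
    )


def expected_hidden_kernel(
    k_u: KernelMatrix | np.ndarray,
    degree: int,
    offset: float = 0.0,
    m: int = 1,
) -> KernelMatrix:
    """E[H(U)] for a polynomial hidden kernel on Gaussian latent units.

    The n x m latent matrix U has i.i.d. columns u ~ N(0, k_u); the hidden
    kernel is H_ij = (u_i . u_j / m + offset)^degree over the rows u_i of U.

    degree 1:  E[H]_ij = k_ij + offset.
    degree 2:  E[H]_ij = (k_ij + offset)^2 + (k_ii k_jj + k_ij^2) / m,
    from the Gaussian fourth-moment identity
    E[z_a z_b z_c z_d] = k_ab k_cd + k_ac k_bd + k_ad k_bc.

    Higher degrees have no closed form here; request a Monte-Carlo estimate
    explicitly instead.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    k = k_u.values if isinstance(k_u, KernelMatrix) else np.asarray(k_u, float)
    if degree == 1:
        values = k + offset
    elif degree == 2:
        diag = np.diag(k)
        values = (k + offset) ** 2 + (np.outer(diag, diag) + k**2) / m
    else:
        raise ValueError(
            f"degree {degree} unsupported: closed forms exist for degrees 1-2"
        )
    if isinstance(k_u, KernelMatrix):
        row_ids, col_ids = list(k_u.row_ids), list(k_u.col_ids)
    else:
        row_ids = col_ids = [("0", str(i)) for i in range(k.shape[0])]
    return KernelMatrix(
        values=values, row_ids=row_ids, col_ids=col_ids,
        kind="hidden_expected",
        params={"degree": degree, "offset": offset, "m": m},
    )
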