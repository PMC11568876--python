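"""Cardinal B-spline basis systems on [0, 1].

A basis is determined by the spline order (4 = cubic) and the number of
equally spaced interior knots; the dimension is ``knots + order``. Gram
matrices of basis-function (derivative) products are computed by per-span
Gauss-Legendre quadrature, which is exact because the integrands are
piecewise polynomials.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.interpolate import BSpline

__all__ = ["BasisSystem"]


@dataclass(frozen=True)
class BasisSystem:
    """Order-``order`` B-splines with equally spaced interior knots on [0,1]."""

    knots: int  # number of interior knots
    order: int = 4

    def __post_init__(self) -> None:
        if self.order < 2:
            raise ValueError("order must be >= 2")
        if self.knots < 0:
            raise ValueError("knots must be >= 0")

    @property
    def degree(self) -> int:
        return self.order - 1

    @property
    def dim(self) -> int:
        return self.knots + self.order

    @property
    def knot_vector(self) -> np.ndarray:
        interior = np.linspace(0.0, 1.0, self.knots + 2)[1:-1]
        return np.r_[
            np.zeros(self.order), interior, np.ones(self.order)
        ]

    def _spline(self) -> BSpline:
        return BSpline(self.knot_vector, np.eye(self.dim), self.degree,
                       extrapolate=False)

    def evaluate(self, t: np.ndarray, deriv: int = 0) -> np.ndarray:
        """len(t) x dim matrix of basis-function (derivative) values."""
        t = np.clip(np.asarray(t, dtype=float), 0.0, 1.0)
        sp = self._spline()
        if deriv:
            sp = sp.derivative(deriv)
        out = sp(t)
        return np.nan_to_num(np.atleast_2d(out))

    def gram(self, deriv_a: int = 0, deriv_b: int | None = None) -> np.ndarray:
        """Exact integral of products of basis derivatives over [0, 1]."""
        if deriv_b is None:
            deriv_b = deriv_a
        return _gram_cached(self.knots, self.order, deriv_a, deriv_b)

    def quadrature(self, n_nodes: int | None = None):
        """Global Gauss-Legendre nodes/weights on [0, 1].

        Default node count is twice the basis dimension, which oversamples
        the piecewise-polynomial integrands enough for stable projection.
        """
        if n_nodes is None:
            n_nodes = 2 * self.dim
        x, w = np.polynomial.legendre.leggauss(n_nodes)
        return (x + 1.0) / 2.0, w / 2.0


@lru_cache(maxsize=64)
def _gram_cached(knots: int, order: int, da: int, db: int) -> np.ndarray:
    basis = BasisSystem(knots=knots, order=order)
    kv = basis.knot_vector
    spans = np.unique(kv)
    deg = basis.degree
    # per-span GL order exact for polynomial degree 2*deg
    npts = deg + 1
    xg, wg = np.polynomial.legendre.leggauss(npts)
    G = np.zeros((basis.dim, basis.dim))
    for a, b in zip(spans[:-1], spans[1:]):
        mid, half = (a + b) / 2.0, (b - a) / 2.0
        t = mid + half * xg
        Ba = basis.evaluate(t, deriv=da)
        Bb = basis.evaluate(t, deriv=db)
        G += half * (Ba * wg[:, None]).T @ Bb
    return G
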