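"""M-spline / I-spline bases and orthogonal polynomial design columns.

M-splines are nonnegative spline basis functions that each integrate to one
over the boundary interval, so nonnegative combinations are valid hazard
functions.  I-splines are their running integrals (0 at the left boundary,
1 at the right).  Both are built on top of ``scipy.interpolate.BSpline``
using the identity ``M_i = k * B_i / (t_{i+k} - t_i)`` for order ``k``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline


@dataclass
class MSplineBasis:
    """M-spline basis of ``n_basis`` functions on [lo, hi].

    Parameters
    ----------
    lo, hi : float
        Boundary knots.
    interior : sequence of float
        Interior knots, strictly inside (lo, hi), nondecreasing.
    degree : int
        Polynomial degree (3 = cubic, the default elsewhere).
    """

    lo: float
    hi: float
    interior: tuple = ()
    degree: int = 3
    _splines: list = field(default_factory=list, repr=False)
    _antiderivs: list = field(default_factory=list, repr=False)

    def __post_init__(self):
        if not self.hi > self.lo:
            raise ValueError("require hi > lo")
        interior = tuple(float(k) for k in self.interior)
        if any(not (self.lo < k < self.hi) for k in interior):
            raise ValueError("interior knots must lie strictly inside (lo, hi)")
        self.interior = interior
        order = self.degree + 1
        knots = np.concatenate(
            [[self.lo] * order, interior, [self.hi] * order]
        ).astype(float)
        self._knots = knots
        self._splines = []
        self._antiderivs = []
        for i in range(self.n_basis):
            coef = np.zeros(self.n_basis)
            span = knots[i + order] - knots[i]
            coef[i] = order / span
            sp = BSpline(knots, coef, self.degree, extrapolate=False)
            self._splines.append(sp)
            self._antiderivs.append(sp.antiderivative())

    @property
    def n_basis(self) -> int:
        return len(self.interior) + self.degree + 1

    @classmethod
    def uniform(cls, lo: float, hi: float, n_basis: int, degree: int = 3):
        """Basis with equally spaced interior knots."""
        n_interior = n_basis - degree - 1
        if n_interior < 0:
            raise ValueError("n_basis too small for this degree")
        interior = np.linspace(lo, hi, n_interior + 2)[1:-1]
        return cls(lo=lo, hi=hi, interior=tuple(interior), degree=degree)

    @classmethod
    def from_quantiles(
        cls, values, n_basis: int, degree: int = 3, lo: float | None = None,
        hi: float | None = None,
    ):
        """Interior knots at evenly spaced quantiles of ``values``."""
        values = np.asarray(values, dtype=float)
        lo = float(values.min()) if lo is None else lo
        hi = float(values.max()) if hi is None else hi
        n_interior = n_basis - degree - 1
        if n_interior < 0:
            raise ValueError("n_basis too small for this degree")
        qs = np.linspace(0, 1, n_interior + 2)[1:-1]
        interior = np.quantile(values, qs)
        eps = 1e-9 * (hi - lo)
        interior = np.clip(interior, lo + eps, hi - eps)
        return cls(lo=lo, hi=hi, interior=tuple(interior), degree=degree)

    def _check(self, t) -> np.ndarray:
        t = np.atleast_1d(np.asarray(t, dtype=float))
        if np.any(t < self.lo - 1e-12) or np.any(t > self.hi + 1e-12):
            raise ValueError("evaluation point outside boundary knots")
        return np.clip(t, self.lo, self.hi)

    def mspline(self, t) -> np.ndarray:
        """Evaluate all basis functions; shape (len(t), n_basis)."""
        t = self._check(t)
        out = np.column_stack([sp(t) for sp in self._splines])
        return np.nan_to_num(out, nan=0.0)

    def ispline(self, t) -> np.ndarray:
        """Running integrals of the basis functions; shape (len(t), n_basis)."""
        t = self._check(t)
        cols = []
        for ad in self._antiderivs:
            v = ad(t) - ad(np.array([self.lo]))[0]
            cols.append(np.nan_to_num(v, nan=0.0))
        return np.column_stack(cols)


@dataclass
class OrthoPoly:
    """Orthonormal polynomial basis fitted on training values.

    Stores the centring constant and the inverse triangular factor of the
    training Vandermonde QR so the identical basis can be evaluated at new
    points (prediction grids).
    """

    mean: float
    r_inv: np.ndarray
    degree: int

    def transform(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        v = np.vander(x - self.mean, self.degree + 1, increasing=True)
        return (v @ self.r_inv)[:, 1:]


def orthogonal_poly(x, degree: int = 2):
    """Orthonormal polynomial columns of ``x`` (degrees 1..degree).

    Returns ``(basis, record)`` where ``basis`` has shape (n, degree) with
    pairwise-orthogonal unit-norm columns, and ``record`` is an
    :class:`OrthoPoly` able to evaluate the same basis at new points.
    """
    x = np.asarray(x, dtype=float)
    if len(np.unique(x)) < degree + 1:
        raise ValueError("need at least degree+1 distinct values")
    mean = float(x.mean())
    v = np.vander(x - mean, degree + 1, increasing=True)
    q, r = np.linalg.qr(v)
    # Fix signs so the leading coefficient of each column is positive.
    signs = np.sign(np.diag(r))
    signs[signs == 0] = 1.0
    q = q * signs
    r = r * signs[:, None]
    record = OrthoPoly(mean=mean, r_inv=np.linalg.inv(r), degree=degree)
    return q[:, 1:], record
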