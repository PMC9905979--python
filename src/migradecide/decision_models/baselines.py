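"""Baseline hazard abstractions for the discrete-night departure model."""

from __future__ import annotations

import numpy as np

from .splines import MSplineBasis


class ConstantBaseline:
    """Time-constant baseline hazard h0(t) = rate."""

    n_weights = 1

    def __init__(self, rate: float):
        if rate < 0:
            raise ValueError("baseline rate must be nonnegative")
        self.rate = float(rate)

    def hazard(self, t):
        return np.full_like(np.asarray(t, dtype=float), self.rate)

    def cumulative(self, t):
        t = np.asarray(t, dtype=float)
        if np.any(t < 0):
            raise ValueError("time must be nonnegative")
        return self.rate * t


class MSplineBaseline:
    """Baseline hazard h0(t) = sum_k w_k M_k(t) with nonnegative weights."""

    def __init__(self, basis: MSplineBasis, weights):
        weights = np.asarray(weights, dtype=float)
        if weights.shape != (basis.n_basis,):
            raise ValueError("weight vector length must equal basis size")
        if np.any(weights < 0):
            raise ValueError("M-spline weights must be nonnegative")
        self.basis = basis
        self.weights = weights

    @property
    def n_weights(self) -> int:
        return self.basis.n_basis

    def hazard(self, t):
        return self.basis.mspline(t) @ self.weights

    def cumulative(self, t):
        return self.basis.ispline(t) @ self.weights
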