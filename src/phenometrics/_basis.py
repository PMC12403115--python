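"""Penalized B-spline basis shared by the trajectory and count-curve fitters.

Knots are placed relative to the observed day range, so shifting every input
day by a constant shifts the basis (and hence any fitted curve) by exactly the
same constant — translation equivariance of the downstream date estimates
follows by construction.
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import BSpline


class SplineBasis:
    """Cubic B-spline basis with a second-difference coefficient penalty.

    Parameters
    ----------
    lo, hi : float
        Domain endpoints (typically first and last observed day).
    n_basis : int
        Number of basis functions (>= degree + 1).
    degree : int
        Spline degree; 3 (cubic) by default.
    """

    def __init__(self, lo: float, hi: float, n_basis: int = 8, degree: int = 3):
        if hi <= lo:
            raise ValueError("basis domain must have hi > lo")
        if n_basis < degree + 1:
            raise ValueError("n_basis must be at least degree + 1")
        self.lo = float(lo)
        self.hi = float(hi)
        self.n_basis = int(n_basis)
        self.degree = int(degree)
        n_interior = n_basis - degree - 1
        interior = np.linspace(lo, hi, n_interior + 2)[1:-1]
        self.knots = np.concatenate(
            [np.full(degree + 1, lo), interior, np.full(degree + 1, hi)]
        )
        # second-difference penalty D2'D2 on the coefficients
        d2 = np.diff(np.eye(n_basis), n=2, axis=0)
        self.penalty = d2.T @ d2
        self.penalty_nullspace_dim = 2  # constants and linear trends unpenalized

    def design(self, x: np.ndarray) -> np.ndarray:
        """Evaluate the basis at `x` (clipped to the domain so extrapolation
        holds the boundary value rather than returning zeros)."""
        xc = np.clip(np.asarray(x, dtype=float), self.lo, self.hi)
        return BSpline.design_matrix(xc, self.knots, self.degree).toarray()


def linear_basis(x: np.ndarray) -> np.ndarray:
    """Design matrix [1, x] for the logistic (midpoint/rate) fallback."""
    x = np.asarray(x, dtype=float)
    return np.column_stack([np.ones_like(x), x])
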