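"""Cyclic cubic regression spline basis for seasonal (day-of-year) effects.

Water temperature follows an annual cycle, so its missing-value sub-model
uses a smooth periodic function of ordinal day t with period 365.25 days.
The basis is the classical cyclic cubic regression spline: coefficients are
the function values at K evenly spaced knots on [0, period), interpolated by
the unique periodic natural cubic spline, giving a basis whose value, first
and second derivatives all match at the period boundary. Penalization of the
coefficients is realized in the model as a hierarchical Gaussian prior
b_s ~ N(0, sigma_b) rather than an explicit quadratic penalty.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SplineBasis", "build_spline_basis", "cyclic_spline_matrix"]

DEFAULT_PERIOD = 365.25


@dataclass(frozen=True)
class SplineBasis:
    """Evaluated basis matrix plus the knot geometry needed to re-evaluate."""

    Z: np.ndarray            # (n, K)
    knots: np.ndarray        # (K,) on [0, period)
    period: float

    @property
    def n_basis(self) -> int:
        return self.Z.shape[1]

    def evaluate(self, t) -> np.ndarray:
        """Evaluate the same K basis functions at new times."""
        return cyclic_spline_matrix(np.asarray(t, dtype=float), self.knots, self.period)


def _cyclic_curvature_map(knots: np.ndarray, period: float) -> np.ndarray:
    """Map knot values f to knot curvatures via the periodic spline system.

    With cyclic knot spacings h_j, the periodic natural cubic spline's second
    derivatives g satisfy B g = D f with cyclic tridiagonal B and D; the
    returned matrix is B^{-1} D.
    """
    K = len(knots)
    h = np.diff(np.append(knots, knots[0] + period))
    B = np.zeros((K, K))
    D = np.zeros((K, K))
    for j in range(K):
        jm, jp = (j - 1) % K, (j + 1) % K
        hm, hj = h[jm], h[j]
        B[j, j] = (hm + hj) / 3.0
        B[j, jm] += hm / 6.0
        B[j, jp] += hj / 6.0
        D[j, j] = -(1.0 / hm + 1.0 / hj)
        D[j, jm] += 1.0 / hm
        D[j, jp] += 1.0 / hj
    return np.linalg.solve(B, D)


def cyclic_spline_matrix(t: np.ndarray, knots: np.ndarray, period: float) -> np.ndarray:
    """Basis matrix rows for times t (any real values; reduced mod period)."""
    t = np.mod(np.asarray(t, dtype=float), period)
    K = len(knots)
    h = np.diff(np.append(knots, knots[0] + period))
    curv = _cyclic_curvature_map(knots, period)
    j = np.clip(np.searchsorted(knots, t, side="right") - 1, 0, K - 1)
    jp = (j + 1) % K
    hj = h[j]
    b = (t - knots[j]) / hj
    a = 1.0 - b
    n = len(t)
    A_f = np.zeros((n, K))
    A_g = np.zeros((n, K))
    rows = np.arange(n)
    np.add.at(A_f, (rows, j), a)
    np.add.at(A_f, (rows, jp), b)
    np.add.at(A_g, (rows, j), (a**3 - a) * hj**2 / 6.0)
    np.add.at(A_g, (rows, jp), (b**3 - b) * hj**2 / 6.0)
    return A_f + A_g @ curv


def build_spline_basis(
    ordinal_day,
    n_basis: int = 10,
    period: float = DEFAULT_PERIOD,
) -> SplineBasis:
    """Cyclic cubic regression spline basis at integer days of year.

    Knots are evenly spaced on [0, period). Each of the ``n_basis`` basis
    functions is the periodic natural cubic spline that is 1 at one knot and
    0 at the others, so a constant function is exactly representable and the
    basis is exactly periodic.
    """
    if n_basis < 4:
        raise ValueError("a cyclic cubic spline needs at least 4 basis functions")
    t = np.asarray(ordinal_day, dtype=float)
    if np.any((t < 0) | (t > 366)):
        raise ValueError("ordinal days must lie in [0, 366]")
    knots = period * np.arange(n_basis) / n_basis
    Z = cyclic_spline_matrix(t, knots, period)
    return SplineBasis(Z=Z, knots=knots, period=period)
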