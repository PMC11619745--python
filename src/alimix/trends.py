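"""Nonparametric trend and correlation statistics.

Monotonic temporal trends in the aluminum series (Al_i, Al_o, Al_d, %Al_i)
are tested with the Mann-Kendall test: the Kendall score
S = sum_{i<j} sign(x_j - x_i) over all time-ordered pairs, with the
tie-corrected null variance and a two-sided p-value. Pairwise association
between Al_i and other water-chemistry variables is measured with Kendall's
tau-b and Pearson's r.

These statistics are implemented from first principles (pair counts, tie
corrections, exact small-sample null for S) so that every ingredient of the
reported tables is inspectable; scipy serves as an independent cross-check
in the test suite, not as the implementation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special, stats

__all__ = ["TrendResult", "CorrelationResult", "mann_kendall", "kendall_tau_b", "pearson"]


@dataclass(frozen=True)
class TrendResult:
    """Mann-Kendall test summary for one series."""

    n: int
    S: int
    tau: float
    var_S: float
    p_value: float
    method: str  # "exact" or "normal"


@dataclass(frozen=True)
class CorrelationResult:
    n: int
    r: float
    p_value: float


def _kendall_S(x: np.ndarray, y: np.ndarray) -> int:
    # O(n^2) pair scan; n is small (site-level series) so clarity wins
    dx = np.sign(x[:, None] - x[None, :])
    dy = np.sign(y[:, None] - y[None, :])
    iu = np.triu_indices(len(x), k=1)
    return int(np.sum(dx[iu] * dy[iu]))


def _tie_groups(x: np.ndarray) -> np.ndarray:
    _, counts = np.unique(x, return_counts=True)
    return counts[counts > 1]


def _exact_p_no_ties(n: int, S: int) -> float:
    """Two-sided exact p for the no-tie null distribution of S.

    The number of permutations of n untied values with a given number of
    inversions follows the Mahonian recursion: the generating polynomial is
    prod_{i=1..n} (1 + z + ... + z^{i-1}). S = n(n-1)/2 - 2 * inversions, so
    the S distribution is read off the inversion counts.
    """
    coeffs = np.ones(1)
    for i in range(2, n + 1):
        coeffs = np.convolve(coeffs, np.ones(i))
    coeffs = coeffs / coeffs.sum()  # P(inversions = k), k = 0..n(n-1)/2
    max_s = n * (n - 1) // 2
    s_values = max_s - 2 * np.arange(coeffs.size)
    # two-sided: P(|S| >= |s_obs|)
    p = float(np.sum(coeffs[np.abs(s_values) >= abs(S)]))
    return min(1.0, p)


def mann_kendall(values, min_n: int = 3) -> TrendResult:
    """Mann-Kendall test for monotonic trend in a time-ordered series.

    Missing values are dropped with order preserved. The score is
    S = sum_{i<j} sign(x_j - x_i); tau uses the tie-corrected denominator
    sqrt((D0 - T) * D0) with D0 = n(n-1)/2 and T = sum t(t-1)/2 over tied
    groups (time carries no ties). For n > 10 the p-value comes from the
    normal approximation with the tie-corrected variance

        var(S) = [n(n-1)(2n+5) - sum t(t-1)(2t+5)] / 18

    and a continuity correction; for n <= 10 with no ties the exact null
    distribution of S is enumerated. Small tied series fall back to the
    corrected normal approximation.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    n = len(x)
    if n < min_n:
        raise ValueError(f"need at least {min_n} non-missing values, got {n}")
    ties = _tie_groups(x)
    d0 = n * (n - 1) / 2
    tie_term = float(np.sum(ties * (ties - 1) / 2))
    if d0 - tie_term <= 0:
        raise ValueError("all values tied; trend undefined")
    time = np.arange(n, dtype=float)
    S = _kendall_S(time, x)
    denom = np.sqrt((d0 - tie_term) * d0)
    tau = S / denom
    var_S = (
        n * (n - 1) * (2 * n + 5)
        - float(np.sum(ties * (ties - 1) * (2 * ties + 5)))
    ) / 18.0
    if n <= 10 and ties.size == 0:
        p = _exact_p_no_ties(n, S)
        method = "exact"
    else:
        if S > 0:
            z = (S - 1) / np.sqrt(var_S)
        elif S < 0:
            z = (S + 1) / np.sqrt(var_S)
        else:
            z = 0.0
        p = float(2 * special.ndtr(-abs(z)))
        method = "normal"
    return TrendResult(n=n, S=S, tau=float(tau), var_S=float(var_S), p_value=p, method=method)


def kendall_tau_b(x, y) -> CorrelationResult:
    """Kendall's tau-b with tie corrections and a two-sided normal p-value.

    Pairs with a missing member are deleted. tau-b = S / sqrt((D0-Tx)(D0-Ty)).
    The null variance of S includes the joint tie-correction terms
    (Kendall's formula), and the p-value uses the normal approximation with
    continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 complete pairs")
    tx, ty = _tie_groups(x), _tie_groups(y)
    d0 = n * (n - 1) / 2
    tx_term = float(np.sum(tx * (tx - 1) / 2))
    ty_term = float(np.sum(ty * (ty - 1) / 2))
    if d0 - tx_term <= 0 or d0 - ty_term <= 0:
        raise ValueError("constant input; tau undefined")
    S = _kendall_S(x, y)
    tau = S / np.sqrt((d0 - tx_term) * (d0 - ty_term))

    def v1(t):
        return float(np.sum(t * (t - 1) * (2 * t + 5)))

    def v2(t):
        return float(np.sum(t * (t - 1) * (t - 2)))

    def v3(t):
        return float(np.sum(t * (t - 1)))

    var_S = (
        (n * (n - 1) * (2 * n + 5) - v1(tx) - v1(ty)) / 18.0
        + v2(tx) * v2(ty) / (9.0 * n * (n - 1) * (n - 2))
        + v3(tx) * v3(ty) / (2.0 * n * (n - 1))
    )
    if S > 0:
        z = (S - 1) / np.sqrt(var_S)
    elif S < 0:
        z = (S + 1) / np.sqrt(var_S)
    else:
        z = 0.0
    p = float(2 * special.ndtr(-abs(z)))
    return CorrelationResult(n=n, r=float(tau), p_value=p)


def pearson(x, y) -> CorrelationResult:
    """Pearson correlation with the two-sided t test on n-2 df.

    Pairs with a missing member are deleted. For |r| = 1 the test statistic
    is unbounded and the p-value is reported as 0.0 (below any representable
    threshold).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 complete pairs")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = np.sqrt(np.sum(xc**2))
    sy = np.sqrt(np.sum(yc**2))
    if sx == 0 or sy == 0:
        raise ValueError("constant input; correlation undefined")
    r = float(np.clip(np.sum(xc * yc) / (sx * sy), -1.0, 1.0))
    if abs(r) >= 1.0:
        p = 0.0
    else:
        t = r * np.sqrt((n - 2) / (1 - r**2))
        p = float(2 * stats.t.sf(abs(t), df=n - 2))
    return CorrelationResult(n=n, r=r, p_value=p)
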