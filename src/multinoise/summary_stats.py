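"""Statistics computed from copy-number trajectories.

Covers the quantities the multimerization analysis reports: means and the
noise measure eta (squared coefficient of variation, variance / mean^2),
tested-vs-null gains with Monte-Carlo standard errors, the normalized
monomer-multimer cross-correlation and its half-life, toggle-switch mean
switching times, and a replicate-based stationarity check.

Monte-Carlo standard errors use batch means: a trajectory sampled on a
regular grid is autocorrelated, so the series is cut into ``n_batches``
contiguous batches, the statistic is computed per batch, and the SE is the
standard deviation of the batch values over ``sqrt(n_batches)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import signal, stats

__all__ = [
    "GainResult",
    "CrossCorrResult",
    "SwitchingResult",
    "eta",
    "gain",
    "batch_stat_se",
    "series_stats",
    "cross_correlation",
    "mean_switching_time",
    "stationarity_fraction",
    "ks_discrete",
]


def eta(series) -> float:
    """Noise of a copy-number series: variance over squared mean."""
    x = np.asarray(series, dtype=float)
    if x.size == 0:
        raise ValueError("series is empty")
    m = x.mean()
    if m == 0:
        raise ValueError("eta is undefined for a zero-mean series")
    return float(x.var() / m**2)


def batch_stat_se(series, stat, n_batches: int = 20) -> float:
    """Batch-means Monte-Carlo SE of ``stat`` evaluated on ``series``."""
    x = np.asarray(series, dtype=float)
    if len(x) < 2 * n_batches:
        n_batches = max(2, len(x) // 2)
    vals = [stat(b) for b in np.array_split(x, n_batches)]
    return float(np.std(vals, ddof=1) / math.sqrt(n_batches))


def series_stats(series, n_batches: int = 20) -> tuple[float, float, float, float]:
    """(mean, mean SE, eta, eta SE) of one series, SEs by batch means."""
    x = np.asarray(series, dtype=float)
    return (
        float(x.mean()),
        batch_stat_se(x, np.mean, n_batches),
        eta(x),
        batch_stat_se(x, eta, n_batches),
    )


@dataclass(frozen=True)
class GainResult:
    """Ratio of a statistic between a tested and a null model."""

    statistic: str
    tested: float
    null: float
    gain: float
    tested_se: float = 0.0
    null_se: float = 0.0
    gain_se: float = 0.0


def gain(
    tested: float,
    null: float,
    statistic: str = "mean",
    tested_se: float = 0.0,
    null_se: float = 0.0,
) -> GainResult:
    """Tested/null ratio with first-order propagated Monte-Carlo SE."""
    if not null > 0:
        raise ValueError("null statistic must be positive")
    g = tested / null
    se = abs(g) * math.sqrt((tested_se / tested) ** 2 + (null_se / null) ** 2) if tested else 0.0
    return GainResult(statistic, float(tested), float(null), float(g),
                      float(tested_se), float(null_se), float(se))


@dataclass(frozen=True)
class CrossCorrResult:
    """Normalized cross-correlation of two series on a lag grid."""

    lags: np.ndarray
    cc: np.ndarray
    zero_lag: float
    half_life: float  # nan when the correlation never falls to half its peak


def cross_correlation(x, y, max_lag: float, dt: float) -> CrossCorrResult:
    """Pearson-normalized cross-correlation of two equally sampled series.

    ``cc[k]`` estimates corr(x(t), y(t + k dt)) for lags ``-max_lag ..
    max_lag``.  The half-life is the smallest positive lag at which the
    correlation first drops to half the zero-lag value, located by linear
    interpolation between lag-grid points.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("series must be one-dimensional with equal length")
    n = len(x)
    L = int(round(max_lag / dt))
    if L < 1 or 2 * L >= n:
        raise ValueError("max_lag must be positive and below half the series span")
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        raise ValueError("cross-correlation is undefined for a zero-variance series")
    xc, yc = x - x.mean(), y - y.mean()
    full = signal.correlate(yc, xc, mode="full", method="fft") / (n * sx * sy)
    mid = n - 1
    cc = full[mid - L : mid + L + 1]
    lags = np.arange(-L, L + 1) * dt
    zero = float(cc[L])
    half = zero / 2.0
    half_life = math.nan
    if zero > 0:
        pos = cc[L:]
        below = np.nonzero(pos < half)[0]
        if below.size:
            i = below[0]
            c0, c1 = pos[i - 1], pos[i]
            frac = (c0 - half) / (c0 - c1)
            half_life = (i - 1 + frac) * dt
    return CrossCorrResult(lags=lags, cc=cc, zero_lag=zero, half_life=half_life)


@dataclass(frozen=True)
class SwitchingResult:
    """Dwell-time summary of a two-state toggle trajectory."""

    mean_switching_time: float
    n_switches: int
    dwells_a: np.ndarray
    dwells_b: np.ndarray

    @property
    def dwells(self) -> np.ndarray:
        return np.concatenate([self.dwells_a, self.dwells_b])


def switch_indices(p1, p2) -> np.ndarray:
    """Sample indices at which the toggle state flips.

    State A is ``p1 > p2``, state B is ``p1 < p2``; ties keep the incumbent
    state (no switch on a tie), and leading ties before the first decided
    sample are ignored.  Returns the switch positions together with the
    state sign (+1 for A) after each switch, stacked as a (k, 2) array.
    """
    p1 = np.asarray(p1)
    p2 = np.asarray(p2)
    if p1.shape != p2.shape or p1.ndim != 1:
        raise ValueError("series must be one-dimensional with equal length")
    s = np.sign(p1.astype(np.int64) - p2.astype(np.int64))
    decided = np.nonzero(s != 0)[0]
    if decided.size == 0:
        return np.empty((0, 2), dtype=np.int64)
    # carry the incumbent state through ties
    filled = s.copy()
    first = decided[0]
    cur = s[first]
    out = []
    for i in range(first + 1, len(s)):
        v = filled[i]
        if v == 0 or v == cur:
            continue
        cur = v
        out.append((i, cur))
    return np.asarray(out, dtype=np.int64).reshape(-1, 2)


def mean_switching_time(p1, p2, dt: float) -> SwitchingResult:
    """Mean dwell time of the toggle defined by which multimer dominates.

    A dwell is the time between two consecutive switches (``dt`` times the
    number of samples between them); the mean is over completed dwells
    only, so at least two switches are required.
    """
    sw = switch_indices(p1, p2)
    if len(sw) < 2:
        raise ValueError(
            f"only {len(sw)} switch(es) observed; need at least 2 for a completed dwell"
        )
    idx = sw[:, 0]
    states = sw[:, 1]
    dwell = np.diff(idx) * dt
    # the dwell between switch i and i+1 is spent in the state entered at i
    a = dwell[states[:-1] > 0]
    b = dwell[states[:-1] < 0]
    return SwitchingResult(
        mean_switching_time=float(dwell.mean()),
        n_switches=int(len(sw)),
        dwells_a=a,
        dwells_b=b,
    )


def ks_discrete(samples, dist, seed: int = 0):
    """One-sample KS test of integer counts against a discrete distribution.

    A naive KS against a discrete CDF is badly miscalibrated because the
    empirical-CDF steps collide with the pmf atoms; instead the samples are
    mapped through the randomized probability integral transform
    ``U = F(x - 1) + V * pmf(x)`` (V uniform, drawn from ``seed``), which is
    exactly Uniform(0, 1) under the null, and tested against uniformity.
    """
    rng = np.random.default_rng(seed)
    x = np.asarray(samples)
    u = dist.cdf(x - 1) + rng.random(len(x)) * dist.pmf(x)
    return stats.kstest(u, "uniform")


def stationarity_fraction(replicates, alpha: float = 0.05) -> float:
    """Fraction of sample times statistically indistinguishable from the end.

    ``replicates`` is an (n_replicates, n_times) array of a species' counts
    across independent runs on a common grid.  For each time t the
    cross-replicate distribution is compared with the distribution at the
    final time by a two-sample KS test; the returned value is the fraction
    of times (excluding the last) at which the test does not reject at
    level ``alpha``.
    """
    r = np.asarray(replicates, dtype=float)
    if r.ndim != 2 or r.shape[0] < 2:
        raise ValueError("need at least 2 replicate trajectories")
    end = r[:, -1]
    keep = 0
    n_t = r.shape[1] - 1
    for j in range(n_t):
        col = r[:, j]
        if np.array_equal(col, end):
            keep += 1
            continue
        p = stats.ks_2samp(col, end, method="asymp").pvalue
        if p >= alpha:
            keep += 1
    return keep / n_t
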