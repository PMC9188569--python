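"""Fitness inference from two-strain competition assays.

In a co-culture at steady state, the ratio between two competitors evolves
exponentially at a rate equal to their growth-rate difference, so the
log-odds of the numerator strain is linear in time with slope delta-mu.
This module detects when the log-odds series has become linear (steady
state reached) and estimates the slope with its standard error by ordinary
least squares.

Log-odds, log(n1 / n2), rather than raw counts are used throughout: for a
two-strain system the slope is identical and the statistic is invariant to
the total number of events acquired per time point.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import linregress

__all__ = [
    "RatioSeries",
    "SteadyWindow",
    "detect_steady_window",
    "FitnessEstimate",
    "estimate_fitness_difference",
]


@dataclass(frozen=True)
class RatioSeries:
    """Per-time-point strain counts from classified cytometry events.

    ``counts`` is (n_times, 2); column 0 is the numerator strain (positive
    slope means it grows faster). Log-odds are defined only where both
    counts are positive.
    """

    times: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        c = np.asarray(self.counts, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "counts", c)
        if t.ndim != 1 or c.shape != (t.size, 2):
            raise ValueError("times must be 1-d and counts of shape (n_times, 2)")
        if (c < 0).any():
            raise ValueError("counts must be >= 0")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")

    @property
    def usable(self) -> np.ndarray:
        """Mask of points where both strains were observed."""
        return (self.counts[:, 0] > 0) & (self.counts[:, 1] > 0)

    @property
    def log_odds(self) -> np.ndarray:
        """log(count_1 / count_2); NaN where undefined."""
        out = np.full(len(self.times), np.nan)
        m = self.usable
        out[m] = np.log(self.counts[m, 0] / self.counts[m, 1])
        return out

    @classmethod
    def from_fractions(
        cls, times: Sequence[float], fractions: Sequence[float], n_events: int | Sequence[int]
    ) -> "RatioSeries":
        """Build from numerator-strain fractions and total event counts."""
        f = np.asarray(fractions, dtype=float)
        n = np.broadcast_to(np.asarray(n_events, dtype=float), f.shape)
        counts = np.column_stack([f * n, (1.0 - f) * n])
        return cls(np.asarray(times, dtype=float), counts)


@dataclass(frozen=True)
class SteadyWindow:
    start: int
    stop: int  # exclusive
    reason: str = ""

    @property
    def found(self) -> bool:
        return self.stop > self.start

    @property
    def indices(self) -> np.ndarray:
        return np.arange(self.start, self.stop)


def detect_steady_window(
    series: RatioSeries,
    min_points: int = 3,
    tolerance: float = 0.05,
) -> SteadyWindow:
    """Longest linear suffix of the log-odds series.

    Linearity of the ratio logarithm over at least ``min_points`` time
    points marks steady state. Operationalized as: the longest suffix
    window of usable points (>= ``min_points``) whose least-squares line
    has maximum absolute residual below ``tolerance`` (log units). Returns
    an empty window (``found == False``) when no suffix qualifies or fewer
    than ``min_points`` usable points exist -- never an exception.
    """
    usable_idx = np.flatnonzero(series.usable)
    if usable_idx.size < min_points:
        return SteadyWindow(0, 0, reason="insufficient data")
    t = series.times[usable_idx]
    y = series.log_odds[usable_idx]
    n = usable_idx.size
    for start in range(0, n - min_points + 1):
        ts, ys = t[start:], y[start:]
        coeffs = np.polyfit(ts, ys, 1)
        resid = ys - np.polyval(coeffs, ts)
        if np.max(np.abs(resid)) < tolerance:
            return SteadyWindow(int(usable_idx[start]), int(usable_idx[-1]) + 1)
    return SteadyWindow(0, 0, reason="no steady state")


@dataclass(frozen=True)
class FitnessEstimate:
    delta_mu: float
    stderr: float
    n_points: int
    dropped: int = 0


def estimate_fitness_difference(
    series: RatioSeries,
    window: SteadyWindow | None = None,
) -> FitnessEstimate:
    """Growth-rate difference (h^-1) from the log-odds slope.

    Ordinary least-squares slope of log-odds vs time over the window
    (default: the full series); the standard error comes from the residual
    variance. Positive means the numerator strain grows faster. Points
    with a zero count inside the window are dropped and counted; fewer
    than 3 remaining points is an error.
    """
    if window is None:
        window = SteadyWindow(0, len(series.times))
    idx = window.indices
    if idx.size == 0:
        raise ValueError("empty steady-state window")
    usable = series.usable[idx]
    dropped = int(np.count_nonzero(~usable))
    keep = idx[usable]
    if keep.size < 3:
        raise ValueError(
            f"only {keep.size} usable points in window (need >= 3); {dropped} dropped"
        )
    t = series.times[keep]
    y = series.log_odds[keep]
    res = linregress(t, y)
    stderr = float(res.stderr) if np.isfinite(res.stderr) else 0.0
    return FitnessEstimate(
        delta_mu=float(res.slope), stderr=stderr, n_points=int(keep.size), dropped=dropped
    )
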