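"""Per-segment Gaussian fits and segment-cost matrices.

Two within-segment families are supported:

* piecewise linear: cell length regressed on axial position by ordinary least
  squares, with a segment-specific residual variance (maximum-likelihood,
  RSS/n);
* change in the variance: constant global mean, segment-specific variance
  (used for residual series).

Both yield, for every feasible cell range ``u..v``, the maximised Gaussian
log-likelihood ``-(n/2) * (log(2*pi*sigma2) + 1)``.  A small variance floor
keeps the cost finite on collinear stretches; fits hitting the floor are
flagged degenerate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "VAR_FLOOR",
    "MIN_SEGMENT_LENGTH",
    "SegmentFit",
    "InfeasibleSegmentError",
    "DegeneratePositionsError",
    "fit_segment",
    "linear_cost_matrix",
    "variance_cost_matrix",
]

#: variance floor (um^2) applied inside segment costs
VAR_FLOOR = 1e-6
#: default minimum number of cells per segment (3 needed for a positive
#: residual variance in the linear fit; 4 adds stability)
MIN_SEGMENT_LENGTH = 4

_LOG2PI = np.log(2.0 * np.pi)


class InfeasibleSegmentError(ValueError):
    """Segment shorter than the configured minimum."""


class DegeneratePositionsError(ValueError):
    """All positions in the segment coincide; the slope is undefined."""


@dataclass(frozen=True)
class SegmentFit:
    """Ordinary-least-squares Gaussian fit of cell length on position.

    ``slope`` is in um of cell length per um of axis; multiply by 1000 for the
    conventional um/mm reporting.  ``sigma`` is the maximum-likelihood residual
    standard deviation ``sqrt(RSS/n)`` (floored), and ``loglik`` the segment
    log-likelihood at the ML parameters.
    """

    start: int
    end: int
    intercept: float
    slope: float
    sigma: float
    rss: float
    correlation: float
    slope_se: float
    loglik: float
    degenerate: bool = False

    @property
    def n(self) -> int:
        return self.end - self.start + 1

    @property
    def slope_per_mm(self) -> float:
        return 1000.0 * self.slope

    def predict(self, position) -> np.ndarray | float:
        return self.intercept + self.slope * np.asarray(position, dtype=float)


def _gauss_loglik(n, sigma2):
    return -0.5 * n * (_LOG2PI + np.log(sigma2) + 1.0)


def fit_segment(
    profile,
    start: int,
    end: int,
    min_len: int = MIN_SEGMENT_LENGTH,
    var_floor: float = VAR_FLOOR,
) -> SegmentFit:
    """OLS fit of length on position over cells ``start..end`` (inclusive)."""
    n = end - start + 1
    if start < 0 or end >= profile.n_cells or n < min_len:
        raise InfeasibleSegmentError(
            f"segment [{start}, {end}] infeasible (min length {min_len})"
        )
    p = profile.positions[start : end + 1]
    x = profile.lengths[start : end + 1]
    spp = float(np.sum((p - p.mean()) ** 2))
    if spp <= 0:
        raise DegeneratePositionsError("all positions equal; slope undefined")
    sxx = float(np.sum((x - x.mean()) ** 2))
    spx = float(np.sum((p - p.mean()) * (x - x.mean())))
    slope = spx / spp
    intercept = float(x.mean() - slope * p.mean())
    rss = max(sxx - slope * spx, 0.0)
    sigma2 = rss / n
    degenerate = sigma2 < var_floor
    sigma2 = max(sigma2, var_floor)
    corr = spx / np.sqrt(spp * sxx) if sxx > 0 else 0.0
    slope_se = np.sqrt((rss / (n - 2)) / spp) if n > 2 else np.nan
    return SegmentFit(
        start=start,
        end=end,
        intercept=intercept,
        slope=slope,
        sigma=float(np.sqrt(sigma2)),
        rss=rss,
        correlation=float(corr),
        slope_se=float(slope_se),
        loglik=float(_gauss_loglik(n, sigma2)),
        degenerate=degenerate,
    )


def _range_sums(values: np.ndarray) -> np.ndarray:
    """S[u, v] = sum of values[u..v] (upper triangle), via cumulative sums."""
    c = np.concatenate(([0.0], np.cumsum(values)))
    return c[None, 1:] - c[:-1, None]


def linear_cost_matrix(
    positions: np.ndarray,
    lengths: np.ndarray,
    min_len: int = MIN_SEGMENT_LENGTH,
    var_floor: float = VAR_FLOOR,
) -> np.ndarray:
    """Segment log-likelihood for every cell range under the linear family.

    ``cost[u, v]`` is the maximised OLS Gaussian log-likelihood of cells
    ``u..v``; entries with fewer than ``min_len`` cells are ``-inf``.
    Computed from running sums of p, p^2, x, x^2 and p*x in O(T^2).
    """
    p = np.asarray(positions, dtype=float)
    x = np.asarray(lengths, dtype=float)
    T = p.size
    n = np.arange(1, T + 1)[None, :] - np.arange(T)[:, None]
    with np.errstate(invalid="ignore", divide="ignore"):
        sp, sx = _range_sums(p), _range_sums(x)
        spp, sxx, spx = _range_sums(p * p), _range_sums(x * x), _range_sums(p * x)
        sppc = spp - sp * sp / n
        sxxc = sxx - sx * sx / n
        spxc = spx - sp * sx / n
        beta = np.where(sppc > 1e-12, spxc / np.where(sppc > 1e-12, sppc, 1.0), 0.0)
        rss = np.clip(sxxc - beta * spxc, 0.0, None)
        sigma2 = np.maximum(rss / n, var_floor)
        cost = _gauss_loglik(n, sigma2)
    cost[n < max(min_len, 1)] = -np.inf
    return cost


def variance_cost_matrix(
    series: np.ndarray,
    min_len: int = MIN_SEGMENT_LENGTH,
    var_floor: float = VAR_FLOOR,
    mean: float | None = None,
) -> tuple[np.ndarray, float]:
    """Segment log-likelihood matrix for the change-in-the-variance family.

    The mean is global (fixed to ``mean`` or the series average); per segment
    only the variance, the mean squared deviation from that global mean, is
    profiled.  Returns the cost matrix and the mean used.
    """
    x = np.asarray(series, dtype=float)
    alpha = float(x.mean()) if mean is None else float(mean)
    d2 = (x - alpha) ** 2
    T = x.size
    n = np.arange(1, T + 1)[None, :] - np.arange(T)[:, None]
    with np.errstate(invalid="ignore", divide="ignore"):
        s2 = np.maximum(_range_sums(d2) / n, var_floor)
        cost = _gauss_loglik(n, s2)
    cost[n < max(min_len, 1)] = -np.inf
    return cost, alpha
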