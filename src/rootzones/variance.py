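"""Residual-series analysis with the Gaussian change-in-the-variance model.

After a piecewise linear segmentation is retained, the residual series
(measured lengths minus the piecewise linear function) is segmented again
with a model in which only the variance changes.  If the change points of
that model co-localize with the zone limits of the linear model (overlapping
uncertainty intervals), the limits are supported by a change in dispersion
and not only by a change in slope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import (
    ChangeInVarianceModel,
    PiecewiseLinearResults,
    PosteriorSummary,
    VarianceSegmentationResults,
)
from .selection import ModelSelectionResult

__all__ = [
    "residual_series",
    "fit_variance_segmentation",
    "colocalized",
    "ResidualAnalysis",
    "analyze_residuals",
]


def residual_series(profile, results: PiecewiseLinearResults) -> np.ndarray:
    """Measured series minus the piecewise linear function, per cell.

    The residual of cell t uses the line of the segment that contains t under
    ``results``; within each segment residuals average to zero (OLS).
    """
    if results.profile is not profile and results.profile.n_cells != profile.n_cells:
        raise ValueError("results were not fitted on this profile")
    return results.resid


def fit_variance_segmentation(
    series: np.ndarray,
    positions: np.ndarray | None = None,
    max_zones: int = 4,
    min_len: int = 4,
) -> tuple[VarianceSegmentationResults, ModelSelectionResult]:
    """Slope-heuristic-selected change-in-the-variance segmentation."""
    model = ChangeInVarianceModel(
        series, positions=positions, min_segment_length=min_len
    )
    results = model.fit_select(max_zones)
    return results, results.selection


def colocalized(interval_a, interval_b) -> bool:
    """Closed-interval overlap test between two (lo, hi) um intervals."""
    (a_lo, a_hi), (b_lo, b_hi) = interval_a, interval_b
    if a_lo > a_hi or b_lo > b_hi:
        raise ValueError("malformed interval (low > high)")
    return max(a_lo, b_lo) <= min(a_hi, b_hi)


@dataclass(frozen=True)
class ResidualAnalysis:
    """Joint view of the linear-model limits and the variance-model limits."""

    variance_results: VarianceSegmentationResults
    variance_selection: ModelSelectionResult
    linear_summary: PosteriorSummary
    variance_summary: PosteriorSummary | None
    colocalization: tuple[bool, ...]

    @property
    def n_colocalized(self) -> int:
        return sum(self.colocalization)


def analyze_residuals(
    results: PiecewiseLinearResults,
    max_zones: int | None = None,
    min_len: int = 4,
    coverage: float = 0.95,
) -> ResidualAnalysis:
    """Fit the variance model to the residuals of a linear segmentation and
    test per-limit co-localization of the two models' uncertainty intervals.

    A linear-model limit counts as co-localized when the variance model has a
    limit of the same index whose uncertainty interval overlaps; limits with
    no counterpart (the variance model selected fewer zones) are not.  The
    candidate grid extends two zones beyond the linear model's count so the
    penalty slope is estimated from models past the one of interest.
    """
    if max_zones is None:
        max_zones = results.n_zones + 2
    resid = results.resid
    var_results, var_sel = fit_variance_segmentation(
        resid, positions=results.profile.positions, max_zones=max_zones, min_len=min_len
    )
    lin_summary = results.posterior_summary(coverage)
    var_summary = (
        var_results.posterior_summary(coverage) if var_results.n_zones > 1 else None
    )
    flags = []
    for j, lin_iv in enumerate(lin_summary.intervals):
        if var_summary is not None and j < len(var_summary.intervals):
            flags.append(lin_iv.overlaps(var_summary.intervals[j]))
        else:
            flags.append(False)
    return ResidualAnalysis(
        variance_results=var_results,
        variance_selection=var_sel,
        linear_summary=lin_summary,
        variance_summary=var_summary,
        colocalization=tuple(flags),
    )
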