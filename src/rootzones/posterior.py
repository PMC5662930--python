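"""Functional access to segmentation-space posteriors for a profile.

Thin wrappers over :class:`~rootzones.model.PiecewiseLinearModel`'s posterior
machinery for callers who do not want to keep a model object around.  All
sums over the segmentation space are exact (forward-backward recursions in
log-sum-exp arithmetic with a uniform prior over feasible segmentations).
"""

from __future__ import annotations

import numpy as np

from .costs import MIN_SEGMENT_LENGTH
from .dp import credible_interval as credible_interval  # re-export
from .model import PiecewiseLinearModel, PosteriorSummary
from .profiles import CellLengthProfile

__all__ = [
    "log_evidence",
    "segmentation_posterior",
    "zone_occupancy_profiles",
    "changepoint_posterior",
    "segmentation_probability_profiles",
    "posterior_summary",
    "credible_interval",
]


def _model(profile: CellLengthProfile, min_len: int) -> PiecewiseLinearModel:
    return PiecewiseLinearModel(profile, min_segment_length=min_len)


def log_evidence(
    profile: CellLengthProfile, n_zones: int, min_len: int = MIN_SEGMENT_LENGTH
) -> float:
    """log-sum of likelihoods over all feasible J-zone segmentations."""
    return _model(profile, min_len).log_evidence(n_zones)


def segmentation_posterior(results, log_evidence_value: float) -> float:
    """exp(llf - log evidence): the segmentation's posterior weight."""
    value = float(np.exp(results.llf - log_evidence_value))
    if value > 1 + 1e-9:
        raise ValueError("log evidence is smaller than the segmentation likelihood")
    return value


def zone_occupancy_profiles(
    profile: CellLengthProfile, n_zones: int, min_len: int = MIN_SEGMENT_LENGTH
) -> np.ndarray:
    """T x J matrix of posterior zone-membership probabilities per cell."""
    return posterior_summary(profile, n_zones, min_len).zone_occupancy


def changepoint_posterior(
    profile: CellLengthProfile,
    n_zones: int,
    j: int,
    min_len: int = MIN_SEGMENT_LENGTH,
) -> np.ndarray:
    """Posterior distribution of change point j (1-based) over cell indices."""
    summary = posterior_summary(profile, n_zones, min_len)
    if not 1 <= j <= n_zones - 1:
        raise IndexError(f"change-point index {j} out of range 1..{n_zones - 1}")
    return summary.changepoint_posteriors[j - 1]


def segmentation_probability_profiles(
    profile: CellLengthProfile, n_zones: int, min_len: int = MIN_SEGMENT_LENGTH
) -> np.ndarray:
    """T x J max-type profiles: best single-segmentation posterior per cell/zone."""
    return posterior_summary(profile, n_zones, min_len).segmentation_profiles


def posterior_summary(
    profile: CellLengthProfile,
    n_zones: int,
    min_len: int = MIN_SEGMENT_LENGTH,
    coverage: float = 0.95,
) -> PosteriorSummary:
    return _model(profile, min_len).posterior_summary(n_zones, coverage)
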