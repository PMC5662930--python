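"""Biological labeling of segmentations and the retained-segmentation strategy.

A statistical segmentation only becomes a developmental zonation once its
segments are identified with the division zone (DZ, short cells), an optional
transition zone (TZ), the elongation zone (EZ, steadily increasing cell
length) and the mature zone (MZ, long and dispersed cells).  The selection
strategy mirrors how practitioners combine change-point inference with
biological expectations:

1. the slope heuristic picks the number of zones and the optimal segmentation
   is labeled;
2. if two expected zones appear merged (no elongation zone), well-supported
   segmentations with one more zone are screened;
3. if the piecewise linear function has an implausibly large discontinuity at
   a limit, well-supported alternative segmentations at the same number of
   zones are screened;
4. whatever is retained is reported with its provenance, so that expert
   overrides remain possible.

The first-root-hair position is never used to choose a segmentation; it is
only compared with the retained EZ-MZ limit afterwards.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from . import dp
from .costs import SegmentFit
from .model import CredibleInterval, PiecewiseLinearModel, PiecewiseLinearResults
from .profiles import CellLengthProfile
from .selection import ModelSelectionResult

__all__ = [
    "ZoningConfig",
    "ZoneLimit",
    "ZonedRoot",
    "UndefinedTestError",
    "UnsupportedPatternError",
    "slope_significant",
    "label_zones",
    "continuity_intervals",
    "continuity_overlap",
    "hair_match",
    "select_final_segmentation",
]


class UndefinedTestError(ValueError):
    """Slope test or confidence interval undefined (no residual freedom)."""


class UnsupportedPatternError(ValueError):
    """More segments than the DZ/TZ/EZ/MZ ontology can label."""


@dataclass(frozen=True)
class ZoningConfig:
    """Thresholds parameterizing the labeling and selection strategy.

    ``ez_slope_threshold`` (um/mm) disambiguates EZ from DZ in 2-zone fits
    only; ``jump_factor`` bounds acceptable discontinuities as a multiple of
    the smaller adjacent residual sd; ``support_ratio`` defines the
    "well-supported" alternatives (posterior within that factor of the
    optimum's).
    """

    significance: float = 0.05
    ez_slope_threshold: float = 20.0
    jump_factor: float = 2.0
    support_ratio: float = 10.0
    continuity_level: float = 0.95
    coverage: float = 0.95
    max_zones: int = 5
    n_best: int = 10
    min_segment_length: int = 4

    def __post_init__(self) -> None:
        for name in ("significance", "continuity_level", "coverage"):
            if not 0 < getattr(self, name) < 1 and name != "coverage":
                raise ValueError(f"{name} must be in (0, 1)")
        if not 0 < self.coverage <= 1:
            raise ValueError("coverage must be in (0, 1]")
        if min(self.ez_slope_threshold, self.jump_factor, self.support_ratio) <= 0:
            raise ValueError("thresholds must be positive")


@dataclass(frozen=True)
class ZoneLimit:
    """One retained limit between consecutive zones, with its diagnostics."""

    position_um: float
    interval: CredibleInterval
    jump_um: float
    jump_acceptable: bool
    ci_rootward: tuple[float, float] | None
    ci_shootward: tuple[float, float] | None
    continuity: bool | None


@dataclass(frozen=True)
class ZonedRoot:
    """Biologically labeled segmentation of one root."""

    root_id: str
    labels: tuple[str, ...]
    results: PiecewiseLinearResults
    limits: tuple[ZoneLimit, ...]
    selection: ModelSelectionResult
    provenance: str  # "optimal" | "alternative rank k" | "J+1 model rank k"
    rank: int
    model_weight: float
    segmentation_posterior: float
    diagnosis: str | None = None
    hair_match_: bool | None = None
    warnings_: tuple[str, ...] = field(default=())

    @property
    def n_zones(self) -> int:
        return len(self.labels)

    @property
    def ez_mz_limit(self) -> ZoneLimit | None:
        if len(self.labels) >= 2 and self.labels[-2] == "EZ":
            return self.limits[-1]
        return None

    def zone(self, label: str) -> SegmentFit | None:
        if label not in self.labels:
            return None
        return self.results.segments[self.labels.index(label)]

    def to_dict(self) -> dict:
        p = self.results.profile.positions
        zones = []
        starts = [float(p[0]), *(l.position_um for l in self.limits)]
        ends = [*(l.position_um for l in self.limits), float(p[-1])]
        for label, seg, s, e in zip(self.labels, self.results.segments, starts, ends):
            zones.append(
                {
                    "label": label,
                    "start_um": float(s),
                    "end_um": float(e),
                    "slope_per_mm": float(seg.slope_per_mm),
                    "correlation": float(seg.correlation),
                    "n_cells": int(seg.n),
                    "residual_sd": float(seg.sigma),
                }
            )
        limits = []
        for l in self.limits:
            limits.append(
                {
                    "position_um": float(l.position_um),
                    "uncertainty_um": [float(l.interval.lo_um), float(l.interval.hi_um)],
                    "jump_um": float(l.jump_um),
                    "continuity": {
                        "ci_rootward": [float(v) for v in l.ci_rootward]
                        if l.ci_rootward
                        else None,
                        "ci_shootward": [float(v) for v in l.ci_shootward]
                        if l.ci_shootward
                        else None,
                        "overlap": None if l.continuity is None else bool(l.continuity),
                    },
                }
            )
        return {
            "root_id": self.root_id,
            "zones": zones,
            "limits": limits,
            "hair_match": None if self.hair_match_ is None else bool(self.hair_match_),
            "provenance": self.provenance,
            "rank": self.rank,
            "diagnosis": self.diagnosis,
            "model_weight": self.model_weight,
            "segmentation_posterior": self.segmentation_posterior,
            "warnings": list(self.warnings_),
        }


def slope_significant(fit: SegmentFit, level: float = 0.05) -> tuple[bool, float]:
    """Two-sided t-test of slope = 0 with n - 2 degrees of freedom."""
    if fit.n < 3 or not math.isfinite(fit.slope_se) or fit.slope_se == 0:
        raise UndefinedTestError("slope test undefined (no residual freedom)")
    t = fit.slope / fit.slope_se
    p = 2.0 * stats.t.sf(abs(t), fit.n - 2)
    return bool(p < level), float(p)


def _slope_significantly_positive(fit: SegmentFit, level: float) -> bool:
    try:
        sig, _ = slope_significant(fit, level)
    except UndefinedTestError:
        return False
    return sig and fit.slope > 0


def label_zones(
    results: PiecewiseLinearResults, config: ZoningConfig | None = None
) -> tuple[tuple[str, ...], str | None]:
    """Map a 1-4 segment fit to ordered zone labels plus a diagnosis.

    The diagnosis flags label patterns that conflict with the expected
    DZ -> (TZ) -> EZ -> MZ succession: ``"merged"`` for a 2-segment fit whose
    first segment does not look like an elongation zone (EZ and MZ presumably
    merged), ``"EZ-missing"`` for a 3-segment fit whose middle slope is not
    significantly positive, and ``"unexpected-pattern"`` for a 4-segment fit
    whose leading segments are not both short-celled.
    """
    config = config or ZoningConfig()
    segs = results.segments
    J = len(segs)
    if J == 1:
        return ("MZ",), None
    if J == 2:
        first_is_ez = (
            _slope_significantly_positive(segs[0], config.significance)
            and segs[0].slope_per_mm >= config.ez_slope_threshold
        )
        if first_is_ez:
            return ("EZ", "MZ"), None
        return ("DZ", "MZ"), "merged"
    if J == 3:
        diagnosis = None
        if not _slope_significantly_positive(segs[1], config.significance):
            diagnosis = "EZ-missing"
        return ("DZ", "EZ", "MZ"), diagnosis
    if J == 4:
        lengths = results.profile.lengths
        ez = segs[2]
        ez_start = float(ez.predict(results.limit_positions[1]))
        short = all(
            float(np.mean(lengths[s.start : s.end + 1])) < ez_start
            for s in segs[:2]
        )
        return ("DZ", "TZ", "EZ", "MZ"), (None if short else "unexpected-pattern")
    raise UnsupportedPatternError(f"cannot label {J} segments as developmental zones")


def _mean_ci(profile: CellLengthProfile, fit: SegmentFit, x0: float, level: float):
    """OLS confidence interval for the conditional mean at position x0."""
    if fit.n < 3 or fit.degenerate:
        raise UndefinedTestError("confidence interval undefined for degenerate fit")
    p = profile.positions[fit.start : fit.end + 1]
    sxx = float(np.sum((p - p.mean()) ** 2))
    s = math.sqrt(fit.rss / (fit.n - 2))
    tq = stats.t.ppf(0.5 + level / 2.0, fit.n - 2)
    half = tq * s * math.sqrt(1.0 / fit.n + (x0 - p.mean()) ** 2 / sxx)
    center = float(fit.predict(x0))
    return center - half, center + half


def continuity_intervals(
    results: PiecewiseLinearResults, j: int, level: float = 0.95
) -> tuple[tuple[float, float], tuple[float, float]]:
    """Rootward and shootward confidence intervals for the mean cell length
    at limit j (1-based), one from each adjacent zone's regression line."""
    if not 1 <= j <= results.n_zones - 1:
        raise IndexError(f"limit index {j} out of range 1..{results.n_zones - 1}")
    x0 = float(results.limit_positions[j - 1])
    profile = results.profile
    return (
        _mean_ci(profile, results.segments[j - 1], x0, level),
        _mean_ci(profile, results.segments[j], x0, level),
    )


def continuity_overlap(ci_rootward, ci_shootward) -> bool:
    """Closed-interval overlap: the piecewise line is approximately continuous
    at the limit when the two conditional-mean CIs intersect."""
    (a_lo, a_hi), (b_lo, b_hi) = ci_rootward, ci_shootward
    if a_lo > a_hi or b_lo > b_hi:
        raise ValueError("malformed confidence interval")
    return max(a_lo, b_lo) <= min(a_hi, b_hi)


def hair_match(
    labels: tuple[str, ...],
    limit: ZoneLimit | None,
    hair_position: float | None,
) -> bool | None:
    """Does the first root hair fall in EZ or inside the EZ-MZ limit's
    uncertainty interval?  ``None`` when there is no EZ-MZ limit or no hair."""
    if hair_position is None or limit is None:
        return None
    if hair_position <= limit.position_um:
        return True
    return limit.interval.lo_um <= hair_position <= limit.interval.hi_um


def _jump_ok(results: PiecewiseLinearResults, factor: float) -> bool:
    for j in range(1, results.n_zones):
        smaller_sd = min(results.segments[j - 1].sigma, results.segments[j].sigma)
        if abs(results.jump_at_limit(j)) > factor * smaller_sd:
            return False
    return True


def _well_supported(model, n_zones, config) -> list[PiecewiseLinearResults]:
    """Top-N segmentations whose posterior is within ``support_ratio`` of the
    optimum's, best first."""
    tops = model.top_segmentations(n_zones, config.n_best)
    if not tops:
        return []
    best = tops[0].llf
    cut = math.log(config.support_ratio)
    return [r for r in tops if best - r.llf <= cut]


def select_final_segmentation(
    profile: CellLengthProfile,
    config: ZoningConfig | None = None,
    hair_position: float | None = None,
) -> ZonedRoot:
    """Full retained-segmentation pipeline for one root.

    Slope heuristic -> optimal segmentation -> labeling -> (if zones appear
    merged) screening of well-supported segmentations with one more zone ->
    (if a limit has an implausible jump) screening of well-supported
    alternative segmentations at the same number of zones.  If no candidate
    passes, the optimal segmentation is retained and the problem reported in
    ``warnings_``.
    """
    config = config or ZoningConfig()
    if hair_position is None:
        hair_position = profile.metadata.first_hair_position
    model = PiecewiseLinearModel(
        profile, min_segment_length=config.min_segment_length
    )
    selection = model.select_zones(config.max_zones)
    retained = model.fit(selection.selected)
    labels, diagnosis = label_zones(retained, config)
    provenance, notes = "optimal", []

    if diagnosis in ("merged", "EZ-missing"):
        J_up = retained.n_zones + 1
        if J_up <= model.max_feasible_zones:
            for cand in _well_supported(model, J_up, config):
                c_labels, c_diag = label_zones(cand, config)
                if c_diag is None and "EZ" in c_labels and _jump_ok(cand, config.jump_factor):
                    retained, labels, diagnosis = cand, c_labels, None
                    provenance = f"J+1 model rank {cand.rank}"
                    break
            else:
                notes.append(
                    f"no well-supported {J_up}-zone alternative resolved "
                    f"diagnosis {diagnosis!r}"
                )
        else:
            notes.append(f"diagnosis {diagnosis!r} but {J_up} zones infeasible")

    if not _jump_ok(retained, config.jump_factor):
        replaced = False
        for cand in _well_supported(model, retained.n_zones, config):
            if cand.rank == retained.rank:
                continue
            c_labels, c_diag = label_zones(cand, config)
            if c_diag is None and _jump_ok(cand, config.jump_factor):
                retained, labels, diagnosis = cand, c_labels, c_diag
                provenance = f"alternative rank {cand.rank}"
                replaced = True
                break
        if not replaced:
            notes.append(
                "discontinuity beyond the jump rule at one or more limits; "
                "optimal segmentation retained"
            )

    J = retained.n_zones
    cps = (
        dp.changepoint_posteriors(model.cost_matrix, J, config.min_segment_length)
        if J > 1
        else np.zeros((0, profile.n_cells))
    )
    limits = []
    for j in range(1, J):
        tau = int(retained.change_points[j - 1])
        lo, hi = dp.credible_interval(cps[j - 1], tau, config.coverage)
        interval = CredibleInterval(
            map_index=tau,
            lo_index=lo,
            hi_index=hi,
            map_um=float(profile.positions[tau]),
            lo_um=float(profile.positions[lo]),
            hi_um=float(profile.positions[hi]),
            coverage=config.coverage,
        )
        try:
            ci_root, ci_shoot = continuity_intervals(
                retained, j, config.continuity_level
            )
            cont = continuity_overlap(ci_root, ci_shoot)
        except UndefinedTestError:
            ci_root = ci_shoot = cont = None
        jump = retained.jump_at_limit(j)
        smaller_sd = min(retained.segments[j - 1].sigma, retained.segments[j].sigma)
        limits.append(
            ZoneLimit(
                position_um=float(profile.positions[tau]),
                interval=interval,
                jump_um=jump,
                jump_acceptable=abs(jump) <= config.jump_factor * smaller_sd,
                ci_rootward=ci_root,
                ci_shootward=ci_shoot,
                continuity=cont,
            )
        )

    limits = tuple(limits)
    in_grid = J in selection.n_zones_grid
    zoned = ZonedRoot(
        root_id=profile.root_id,
        labels=labels,
        results=retained,
        limits=limits,
        selection=selection,
        provenance=provenance,
        rank=retained.rank,
        model_weight=selection.weight(J) if in_grid else 0.0,
        segmentation_posterior=retained.segmentation_posterior(),
        diagnosis=diagnosis,
        warnings_=tuple(notes),
    )
    ez_limit = zoned.ez_mz_limit
    return ZonedRoot(
        **{
            **zoned.__dict__,
            "hair_match_": hair_match(labels, ez_limit, hair_position),
        }
    )
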