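"""Heteroscedastic multiple change-point models, statsmodels-style.

Two model classes share the segmentation machinery and differ only in the
within-segment family:

* :class:`PiecewiseLinearModel` -- cell length regressed on axial position,
  one OLS line and one residual variance per developmental zone;
* :class:`ChangeInVarianceModel` -- constant global mean, one variance per
  segment (used on residual series).

``fit(n_zones)`` returns a results object carrying the optimal segmentation
(the most probable one at fixed J, by dynamic programming), per-segment
estimates and the log-likelihood; ``fit_select()`` first chooses the number
of zones by the slope heuristic.  The latent segmentation space is exposed
through ``top_segmentations`` (N-best enumeration) and ``posterior_summary``
(evidence, zone-occupancy and change-point posteriors, credible intervals).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property

import numpy as np
import pandas as pd

from . import dp
from .costs import (
    MIN_SEGMENT_LENGTH,
    VAR_FLOOR,
    SegmentFit,
    fit_segment,
    linear_cost_matrix,
    variance_cost_matrix,
)
from .dp import InfeasibleSegmentationError
from .profiles import CellLengthProfile
from .selection import ModelSelectionResult, slope_heuristic_select

__all__ = [
    "PiecewiseLinearModel",
    "PiecewiseLinearResults",
    "ChangeInVarianceModel",
    "VarianceSegmentationResults",
    "PosteriorSummary",
    "CredibleInterval",
]

DEFAULT_MAX_ZONES = {"linear": 5, "variance": 4}


@dataclass(frozen=True)
class CredibleInterval:
    """Contiguous posterior interval for one change point."""

    map_index: int
    lo_index: int
    hi_index: int
    map_um: float
    lo_um: float
    hi_um: float
    coverage: float

    def overlaps(self, other: "CredibleInterval") -> bool:
        return max(self.lo_um, other.lo_um) <= min(self.hi_um, other.hi_um)


@dataclass(frozen=True)
class PosteriorSummary:
    """Posterior quantities summed over the whole segmentation space at fixed J.

    ``zone_occupancy[t, j]`` is the posterior probability that cell t lies in
    segment j; ``segmentation_profiles[t, j]`` the max-type analogue (highest
    posterior of a single segmentation assigning t to j);
    ``changepoint_posteriors[j-1]`` the distribution of change point j over
    cell indices; ``intervals[j-1]`` its credible interval around the optimal
    (MAP) change point.
    """

    n_zones: int
    log_evidence: float
    optimal_log_likelihood: float
    zone_occupancy: np.ndarray
    segmentation_profiles: np.ndarray
    changepoint_posteriors: np.ndarray
    intervals: tuple[CredibleInterval, ...]

    @property
    def optimal_posterior(self) -> float:
        """Posterior weight of the optimal segmentation among all feasible."""
        return float(np.exp(self.optimal_log_likelihood - self.log_evidence))

    def to_frame(self) -> pd.DataFrame:
        """Tidy (cell_index, zone, probability) export of the occupancy."""
        T, J = self.zone_occupancy.shape
        return pd.DataFrame(
            {
                "cell_index": np.repeat(np.arange(T), J),
                "zone": np.tile(np.arange(J), T),
                "probability": self.zone_occupancy.ravel(),
            }
        )


class _ChangePointModel:
    """Shared segmentation engine; subclasses provide the cost matrix."""

    family: str = ""

    def __init__(self, min_segment_length: int, var_floor: float):
        self.min_segment_length = int(min_segment_length)
        self.var_floor = float(var_floor)

    # subclasses set self._T and implement _build_cost / _make_results

    @cached_property
    def cost_matrix(self) -> np.ndarray:
        return self._build_cost()

    @property
    def max_feasible_zones(self) -> int:
        return self._T // self.min_segment_length

    def fit(self, n_zones: int):
        taus, llf = dp.optimal_changepoints(
            self.cost_matrix, n_zones, self.min_segment_length
        )
        return self._make_results(taus, llf)

    def top_segmentations(self, n_zones: int, n_best: int):
        """The n_best most probable segmentations, best first."""
        ranked = dp.top_changepoints(
            self.cost_matrix, n_zones, n_best, self.min_segment_length
        )
        return [self._make_results(t, v, rank=i + 1) for i, (t, v) in enumerate(ranked)]

    def log_evidence(self, n_zones: int) -> float:
        """log of the likelihood summed over all feasible J-segmentations."""
        return dp.log_evidence(self.cost_matrix, n_zones, self.min_segment_length)

    def select_zones(self, max_zones: int | None = None) -> ModelSelectionResult:
        """Slope-heuristic selection of the number of zones."""
        if max_zones is None:
            max_zones = DEFAULT_MAX_ZONES[self.family]
        max_zones = min(max_zones, self.max_feasible_zones)
        if max_zones < 1:
            raise InfeasibleSegmentationError("profile shorter than one segment")
        ll = {J: self.fit(J).llf for J in range(1, max_zones + 1)}
        return slope_heuristic_select(ll, family=self.family)

    def fit_select(self, max_zones: int | None = None):
        """Fit at the number of zones chosen by the slope heuristic."""
        selection = self.select_zones(max_zones)
        results = self.fit(selection.selected)
        results.selection = selection
        return results

    def posterior_summary(
        self, n_zones: int, coverage: float = 0.95
    ) -> PosteriorSummary:
        cost, ml = self.cost_matrix, self.min_segment_length
        taus, llf = dp.optimal_changepoints(cost, n_zones, ml)
        lz = dp.log_evidence(cost, n_zones, ml)
        occ = dp.zone_occupancy(cost, n_zones, ml)
        prof = dp.max_assignment_profiles(cost, n_zones, ml)
        cps = dp.changepoint_posteriors(cost, n_zones, ml)
        intervals = []
        for j, tau in enumerate(taus):
            lo, hi = dp.credible_interval(cps[j], int(tau), coverage)
            intervals.append(
                CredibleInterval(
                    map_index=int(tau),
                    lo_index=lo,
                    hi_index=hi,
                    map_um=self._position_of(int(tau)),
                    lo_um=self._position_of(lo),
                    hi_um=self._position_of(hi),
                    coverage=coverage,
                )
            )
        return PosteriorSummary(
            n_zones=n_zones,
            log_evidence=lz,
            optimal_log_likelihood=llf,
            zone_occupancy=occ,
            segmentation_profiles=prof,
            changepoint_posteriors=cps,
            intervals=tuple(intervals),
        )

    def _position_of(self, index: int) -> float:
        raise NotImplementedError


class PiecewiseLinearModel(_ChangePointModel):
    """Heteroscedastic piecewise Gaussian linear model for one cell-length
    profile.

    Parameters
    ----------
    profile : CellLengthProfile
        Ordered positions (um) and cell lengths (um) of a single root.
    min_segment_length : int
        Minimum number of cells per developmental zone (default 4).
    var_floor : float
        Lower bound (um^2) on per-zone residual variances.
    """

    family = "linear"

    def __init__(
        self,
        profile: CellLengthProfile,
        min_segment_length: int = MIN_SEGMENT_LENGTH,
        var_floor: float = VAR_FLOOR,
    ):
        super().__init__(min_segment_length, var_floor)
        self.profile = profile
        self._T = profile.n_cells

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, root_id: str = "root", **kw):
        profile = CellLengthProfile(
            root_id=root_id,
            positions=frame["position_um"].to_numpy(float),
            lengths=frame["cell_length_um"].to_numpy(float),
        )
        return cls(profile, **kw)

    @classmethod
    def from_csv(cls, path, **kw):
        from .profiles import read_profile

        return cls(read_profile(path), **kw)

    def _build_cost(self) -> np.ndarray:
        return linear_cost_matrix(
            self.profile.positions,
            self.profile.lengths,
            self.min_segment_length,
            self.var_floor,
        )

    def fit_segment(self, start: int, end: int) -> SegmentFit:
        return fit_segment(
            self.profile, start, end, self.min_segment_length, self.var_floor
        )

    def _make_results(self, taus, llf, rank: int = 1) -> "PiecewiseLinearResults":
        bounds = [0, *taus.tolist(), self._T]
        fits = tuple(
            self.fit_segment(bounds[i], bounds[i + 1] - 1)
            for i in range(len(bounds) - 1)
        )
        return PiecewiseLinearResults(self, np.asarray(taus, int), fits, float(llf), rank)

    def _position_of(self, index: int) -> float:
        return float(self.profile.positions[index])


@dataclass
class _ResultsBase:
    model: _ChangePointModel
    change_points: np.ndarray
    segments: tuple
    llf: float
    rank: int = 1
    selection: ModelSelectionResult | None = None

    @property
    def n_zones(self) -> int:
        return len(self.segments)

    @property
    def segment_of_cell(self) -> np.ndarray:
        """Segment index of every cell under this segmentation."""
        return np.searchsorted(self.change_points, np.arange(self.model._T), "right")

    def segmentation_posterior(self) -> float:
        """Posterior weight of this segmentation among all feasible ones."""
        return float(np.exp(self.llf - self.model.log_evidence(self.n_zones)))

    def posterior_summary(self, coverage: float = 0.95) -> PosteriorSummary:
        return self.model.posterior_summary(self.n_zones, coverage)


@dataclass
class PiecewiseLinearResults(_ResultsBase):
    """Optimal (or alternative, see ``rank``) piecewise linear segmentation."""

    @property
    def profile(self) -> CellLengthProfile:
        return self.model.profile

    @property
    def limit_positions(self) -> np.ndarray:
        """Zone limits in um: the position of the first cell of each
        shootward segment."""
        return self.profile.positions[self.change_points]

    @property
    def fittedvalues(self) -> np.ndarray:
        out = np.empty(self.profile.n_cells)
        for seg in self.segments:
            sl = slice(seg.start, seg.end + 1)
            out[sl] = seg.predict(self.profile.positions[sl])
        return out

    @property
    def resid(self) -> np.ndarray:
        """Residual series: measured lengths minus the piecewise linear fit."""
        return self.profile.lengths - self.fittedvalues

    def predict(self, position) -> np.ndarray | float:
        """Piecewise linear function at arbitrary positions within the span.

        At a zone limit the shootward segment's line is used (the limit is the
        position of the first cell of the shootward zone).
        """
        pos = np.asarray(position, dtype=float)
        lo, hi = self.profile.span
        if np.any(pos < lo) or np.any(pos > hi):
            raise ValueError(f"position outside profile span [{lo}, {hi}]")
        seg_idx = np.searchsorted(self.limit_positions, pos, side="right")
        coef = np.array([(s.intercept, s.slope) for s in self.segments])
        out = coef[seg_idx, 0] + coef[seg_idx, 1] * pos
        return float(out) if np.isscalar(position) else out

    def jump_at_limit(self, j: int) -> float:
        """Signed discontinuity (um) of the piecewise linear function at
        limit j (1-based): shootward minus rootward prediction at the limit."""
        if not 1 <= j <= self.n_zones - 1:
            raise IndexError(f"limit index {j} out of range 1..{self.n_zones - 1}")
        limit = float(self.limit_positions[j - 1])
        return float(self.segments[j].predict(limit) - self.segments[j - 1].predict(limit))

    def summary(self) -> str:
        lines = [
            f"Piecewise linear model, root {self.profile.root_id!r}: "
            f"{self.n_zones} zone(s), T={self.profile.n_cells} cells",
            f"log-likelihood {self.llf:.3f}"
            + (f", segmentation rank {self.rank}" if self.rank != 1 else ""),
        ]
        if self.selection is not None:
            lines.append(
                f"slope heuristic: J*={self.selection.selected}, "
                f"weight {self.selection.weight(self.selection.selected):.3f}"
            )
        header = (
            f"{'seg':>3} {'cells':>7} {'start_um':>9} {'end_um':>9} "
            f"{'slope/mm':>9} {'r':>6} {'sd_um':>7}"
        )
        lines.append(header)
        for i, seg in enumerate(self.segments):
            p = self.profile.positions
            lines.append(
                f"{i:>3} {seg.n:>7} {p[seg.start]:>9.1f} {p[seg.end]:>9.1f} "
                f"{seg.slope_per_mm:>9.1f} {seg.correlation:>6.2f} {seg.sigma:>7.2f}"
            )
        return "\n".join(lines)


class ChangeInVarianceModel(_ChangePointModel):
    """Gaussian change-in-the-variance model for a (residual) series.

    The mean is constant across the whole series (fixed to the series average)
    while the variance is segment-specific; change points mark changes in
    dispersion only.  ``positions`` map cell indices to um so that limits are
    comparable with the piecewise linear model's.
    """

    family = "variance"

    def __init__(
        self,
        series: np.ndarray,
        positions: np.ndarray | None = None,
        min_segment_length: int = MIN_SEGMENT_LENGTH,
        var_floor: float = VAR_FLOOR,
    ):
        super().__init__(min_segment_length, var_floor)
        self.series = np.asarray(series, dtype=float)
        self._T = self.series.size
        self.positions = (
            np.asarray(positions, dtype=float)
            if positions is not None
            else np.arange(self._T, dtype=float)
        )
        if self.positions.size != self._T:
            raise ValueError("positions must match the series in length")
        self.mean = float(self.series.mean())

    def _build_cost(self) -> np.ndarray:
        cost, _ = variance_cost_matrix(
            self.series, self.min_segment_length, self.var_floor, self.mean
        )
        return cost

    def _make_results(self, taus, llf, rank: int = 1):
        bounds = [0, *np.asarray(taus, int).tolist(), self._T]
        sigmas = []
        for i in range(len(bounds) - 1):
            seg = self.series[bounds[i] : bounds[i + 1]]
            s2 = max(float(np.mean((seg - self.mean) ** 2)), self.var_floor)
            sigmas.append(np.sqrt(s2))
        return VarianceSegmentationResults(
            self, np.asarray(taus, int), tuple(sigmas), float(llf), rank
        )

    def _position_of(self, index: int) -> float:
        return float(self.positions[index])


@dataclass
class VarianceSegmentationResults(_ResultsBase):
    """Selected change-in-the-variance segmentation of a residual series."""

    @property
    def sigmas(self) -> tuple:
        return self.segments  # segments stores the per-segment sd here

    @property
    def limit_positions(self) -> np.ndarray:
        return self.model.positions[self.change_points]

    @property
    def mean(self) -> float:
        return self.model.mean

    def summary(self) -> str:
        lines = [
            f"Change-in-variance model: {self.n_zones} segment(s), "
            f"mean {self.mean:.3f} um, log-likelihood {self.llf:.3f}",
            "per-segment sd (um): "
            + ", ".join(f"{s:.2f}" for s in self.sigmas),
        ]
        if len(self.change_points):
            lines.append(
                "limits (um): "
                + ", ".join(f"{p:.0f}" for p in self.limit_positions)
            )
        return "\n".join(lines)
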