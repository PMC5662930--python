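"""Selection of the number of developmental zones by the slope heuristic.

The slope heuristic is a penalized-likelihood device: the maximum
log-likelihood l(J) grows roughly linearly in the model dimension D(J) once J
exceeds the true number of zones, so the slope s of that linear regime
estimates the unit penalty and the criterion C(J) = l(J) - 2*s*D(J) trades fit
against complexity.  Softmax weights over C(J) give posterior-like model
weights; the selected J maximises C(J).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = ["ModelSelectionResult", "model_dimension", "slope_heuristic_select"]


def model_dimension(n_zones: int, family: str = "linear") -> int:
    """Free-parameter count of a J-zone model.

    Linear family: intercept, slope and variance per zone plus J-1 change
    points -> 4J - 1.  Variance family: variance per zone, one global mean and
    J-1 change points -> 2J.
    """
    if n_zones < 1:
        raise ValueError("n_zones must be >= 1")
    if family == "linear":
        return 4 * n_zones - 1
    if family == "variance":
        return 2 * n_zones
    raise ValueError(f"unknown model family {family!r}")


@dataclass(frozen=True)
class ModelSelectionResult:
    """Slope-heuristic trace: log-likelihoods, criterion and model weights."""

    n_zones_grid: np.ndarray
    loglik: np.ndarray
    dimension: np.ndarray
    penalty_slope: float
    criterion: np.ndarray
    weights: np.ndarray
    selected: int
    family: str = "linear"
    warnings_: tuple[str, ...] = field(default=())

    def weight(self, n_zones: int) -> float:
        idx = int(np.flatnonzero(self.n_zones_grid == n_zones)[0])
        return float(self.weights[idx])

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "n_zones": self.n_zones_grid,
                "loglik": self.loglik,
                "dimension": self.dimension,
                "criterion": self.criterion,
                "weight": self.weights,
            }
        )


def slope_heuristic_select(
    loglik_by_zones: dict[int, float], family: str = "linear"
) -> ModelSelectionResult:
    """Apply the slope heuristic to optimal log-likelihoods l(J), J = 1..Jmax.

    The penalty slope is the OLS slope of l(J) on the model dimension over the
    upper half of the J grid (at least 3 points; with fewer, all J >= 2 are
    used), floored at zero.  C(J) = l(J) - 2*s*D(J); weights are the softmax
    of C; the selected J maximises C with a smallest-J tie-break.
    """
    Js = np.array(sorted(loglik_by_zones), dtype=int)
    ll = np.array([loglik_by_zones[j] for j in Js], dtype=float)
    dims = np.array([model_dimension(int(j), family) for j in Js], dtype=float)
    notes: list[str] = []
    if Js.size < 2:
        notes.append("fewer than two candidate models; selection degenerates")
        warnings.warn(notes[-1], stacklevel=2)
        return ModelSelectionResult(
            Js, ll, dims, 0.0, ll.copy(), np.ones(Js.size), int(Js[0]),
            family, tuple(notes),
        )
    pts = np.arange(Js.size)[Js.size // 2 :]
    if pts.size < 3:
        pts = np.flatnonzero(Js >= 2)
    if pts.size < 2:
        pts = np.arange(Js.size)
    d, y = dims[pts], ll[pts]
    denom = float(np.sum((d - d.mean()) ** 2))
    slope = float(np.sum((d - d.mean()) * (y - y.mean())) / denom) if denom > 0 else 0.0
    slope = max(slope, 0.0)
    criterion = ll - 2.0 * slope * dims
    weights = np.exp(criterion - criterion.max())
    weights /= weights.sum()
    selected = int(Js[int(np.argmax(criterion))])  # argmax takes the first max
    return ModelSelectionResult(
        Js, ll, dims, slope, criterion, weights, selected, family, tuple(notes)
    )
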