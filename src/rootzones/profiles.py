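"""Cell-length profile containers and CSV I/O.

A profile is the ordered series of epidermal cell lengths measured along a
root apex, each cell carrying an axial position in micrometres measured from
the root cap junction.  Profiles usually merge several cell files, so cells
are ordered by projected position, never by within-file index.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CellLengthProfile",
    "RootMetadata",
    "ProfileFormatError",
    "EmptyProfileError",
    "read_profile",
    "write_profile",
]


class ProfileFormatError(ValueError):
    """Raised when a profile CSV lacks the required columns."""


class EmptyProfileError(ValueError):
    """Raised when a profile contains no usable cells."""


@dataclass(frozen=True)
class RootMetadata:
    """Per-root descriptors measured alongside the cell-length profile.

    Parameters
    ----------
    genotype : str
        One of ``wild-type``, ``rtcs``, ``rum-1`` or ``other``.
    root_type : str
        Visual growth category: ``A`` (long, vigorous), ``A'`` (vigorous,
        emerging from a curvature), ``B`` (intermediate, decelerating),
        ``C`` (short, arrested) or ``unknown``.
    first_hair_position : float or None
        Position (um) of the most rootward cell with an incipient root hair
        bulge.
    diameters : tuple of float
        Up to two root diameter measurements (um) taken shootward of the
        first root hair.
    """

    genotype: str = "other"
    root_type: str = "unknown"
    first_hair_position: float | None = None
    diameters: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.first_hair_position is not None and self.first_hair_position <= 0:
            raise ValueError("first_hair_position must be positive")
        if any(d <= 0 for d in self.diameters):
            raise ValueError("diameters must be positive")


@dataclass(frozen=True)
class CellLengthProfile:
    """Ordered cell positions and lengths for a single root.

    ``positions`` are centre-of-cell axial coordinates in micrometres with the
    root cap junction at the origin; ``lengths`` are the corresponding cell
    lengths in micrometres.  Cells are sorted by position (stable, so tied
    positions keep input order) and lengths are strictly positive.
    """

    root_id: str
    positions: np.ndarray
    lengths: np.ndarray
    file_ids: np.ndarray | None = None
    metadata: RootMetadata = field(default_factory=RootMetadata)
    n_dropped: int = 0

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        lng = np.asarray(self.lengths, dtype=float)
        if pos.ndim != 1 or lng.ndim != 1 or pos.shape != lng.shape:
            raise ValueError("positions and lengths must be 1-D of equal length")
        if pos.size == 0:
            raise EmptyProfileError(f"profile {self.root_id!r} has no cells")
        order = np.argsort(pos, kind="stable")
        pos = pos[order]
        lng = lng[order]
        if np.any(lng <= 0):
            raise ValueError("cell lengths must be strictly positive")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "lengths", lng)
        if self.file_ids is not None:
            fid = np.asarray(self.file_ids)
            if fid.shape != pos.shape:
                raise ValueError("file_ids must match positions in length")
            object.__setattr__(self, "file_ids", fid[order])

    @property
    def n_cells(self) -> int:
        return int(self.positions.size)

    def __len__(self) -> int:
        return self.n_cells

    @property
    def span(self) -> tuple[float, float]:
        return float(self.positions[0]), float(self.positions[-1])

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(
            {"position_um": self.positions, "cell_length_um": self.lengths}
        )
        if self.file_ids is not None:
            frame["file_id"] = self.file_ids
        return frame


def read_profile(
    path,
    root_id: str | None = None,
    metadata: RootMetadata | None = None,
) -> CellLengthProfile:
    """Read a profile CSV (columns ``position_um, cell_length_um[, file_id]``).

    Rows with non-positive cell length are dropped and counted in
    ``profile.n_dropped``.  Cells are sorted by position; ties keep the input
    order (cells from different files may project to identical positions).

    Raises
    ------
    ProfileFormatError
        If a required column is missing.
    EmptyProfileError
        If no data rows survive.
    """
    frame = pd.read_csv(path, float_precision="round_trip")
    required = {"position_um", "cell_length_um"}
    missing = required - set(frame.columns)
    if missing:
        raise ProfileFormatError(
            f"{path}: missing required column(s) {sorted(missing)}"
        )
    if len(frame) == 0:
        raise EmptyProfileError(f"{path}: no data rows")
    keep = frame["cell_length_um"] > 0
    n_dropped = int((~keep).sum())
    frame = frame[keep]
    if len(frame) == 0:
        raise EmptyProfileError(f"{path}: all rows had non-positive length")
    if root_id is None:
        root_id = str(path)
    return CellLengthProfile(
        root_id=root_id,
        positions=frame["position_um"].to_numpy(float),
        lengths=frame["cell_length_um"].to_numpy(float),
        file_ids=frame["file_id"].to_numpy() if "file_id" in frame else None,
        metadata=metadata or RootMetadata(),
        n_dropped=n_dropped,
    )


def write_profile(profile: CellLengthProfile, path) -> None:
    """Write a profile back to the standard CSV layout (full float
    precision, so write-then-read round-trips exactly)."""
    profile.to_frame().to_csv(path, index=False, float_format="%.17g")
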