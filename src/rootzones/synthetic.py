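"""Synthetic cell-length profiles with known zonation ground truth.

Profiles emulate how real measurements arise: within each of a few epidermal
cell files, cells tile the axis contiguously from the root cap junction; the
expected length of the next cell follows the zone's linear trend at the
current rootward edge, the realised length is Gaussian around it with the
zone's residual sd (truncated at a small positive floor), and the recorded
position is the cell's centre.  Files are generated independently and merged
by position, reproducing the interleaving of files seen in measured profiles.

Default parameters for the presets are in the ranges of the published per-root
tables (division zone: flat ~5-7 um cells, sd 1-3; elongation zone: slope
~40-200 um/mm, sd 4-13; mature zone: long cells, sd 15-40).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .profiles import CellLengthProfile, RootMetadata

__all__ = [
    "ZoneSpec",
    "ProfileSpec",
    "GroundTruth",
    "generate_profile",
    "generate_cohort",
    "a10_like_spec",
    "single_zone_spec",
    "c_type_spec",
    "spec_from_yaml",
    "spec_to_yaml",
]


@dataclass(frozen=True)
class ZoneSpec:
    """Linear mean trend and residual spread of one zone.

    ``intercept_um`` and ``slope_per_mm`` define the mean cell length line in
    global axis coordinates (length at position p um is
    ``intercept + slope/1000 * p``); ``span_um`` is the zone's axial extent.
    """

    label: str
    span_um: float
    intercept_um: float
    slope_per_mm: float
    sd_um: float

    def mean_at(self, position_um) -> np.ndarray | float:
        return self.intercept_um + self.slope_per_mm / 1000.0 * np.asarray(
            position_um, dtype=float
        )


@dataclass(frozen=True)
class ProfileSpec:
    """Recipe for one synthetic root: ordered zones, rootward to shootward."""

    root_id: str
    zones: tuple[ZoneSpec, ...]
    n_files: int = 3
    floor_um: float = 0.5
    hair_offset_um: float = 100.0
    genotype: str = "other"
    root_type: str = "unknown"

    def __post_init__(self) -> None:
        if self.n_files < 1:
            raise ValueError("need at least one cell file")
        if not self.zones:
            raise ValueError("need at least one zone")
        start = 0.0
        for z in self.zones:
            if z.span_um <= 0:
                raise ValueError(f"zone {z.label!r}: span must be positive")
            if z.sd_um < 0:
                raise ValueError(f"zone {z.label!r}: sd must be >= 0")
            lo = min(z.mean_at(start), z.mean_at(start + z.span_um))
            if lo <= self.floor_um:
                raise ValueError(
                    f"zone {z.label!r}: mean cell length reaches the floor"
                )
            start += z.span_um

    @property
    def limits_um(self) -> np.ndarray:
        return np.cumsum([z.span_um for z in self.zones])[:-1]

    @property
    def total_span_um(self) -> float:
        return float(sum(z.span_um for z in self.zones))


@dataclass(frozen=True)
class GroundTruth:
    """What the generator actually used, in cohort-table vocabulary."""

    spec: ProfileSpec
    limits_um: np.ndarray
    first_hair_um: float | None
    cell_zones: np.ndarray = field(repr=False)

    def summary_row(self) -> dict:
        spec = self.spec
        labels = [z.label for z in spec.zones]
        dz = ez = 0.0
        if "EZ" in labels:
            i = labels.index("EZ")
            start = float(self.limits_um[i - 1]) if i > 0 else 0.0
            end = (
                float(self.limits_um[i])
                if i < len(labels) - 1
                else spec.total_span_um
            )
            ez = end - (start if "DZ" in labels else 0.0)
            if "DZ" in labels:
                dz = start
        elif "DZ" in labels:
            dz = float(self.limits_um[0]) if len(labels) > 1 else spec.total_span_um
        return {
            "root_id": spec.root_id,
            "genotype": spec.genotype,
            "root_type": spec.root_type,
            "n_zones": len(labels),
            "dz_length": dz,
            "ez_length": ez,
            "first_hair": self.first_hair_um,
            **{
                f"{z.label.lower()}_sd": z.sd_um
                for z in spec.zones
            },
        }


def _zone_at(spec: ProfileSpec, position: float) -> int:
    edges = np.cumsum([z.span_um for z in spec.zones])
    return int(np.searchsorted(edges, position, side="right").clip(0, len(edges) - 1))


def _draw_length(rng, mean: float, sd: float, floor: float) -> float:
    if sd == 0:
        return max(mean, floor)
    for _ in range(1000):
        value = rng.normal(mean, sd)
        if value > floor:
            return value
    return floor


def generate_profile(
    spec: ProfileSpec, seed: int | np.random.Generator = 0
) -> tuple[CellLengthProfile, GroundTruth]:
    """Generate one profile and its ground truth, reproducibly from ``seed``."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    positions, lengths, files, zones = [], [], [], []
    total = spec.total_span_um
    for f in range(spec.n_files):
        edge = 0.0
        while edge < total:
            zone = spec.zones[_zone_at(spec, edge)]
            length = _draw_length(rng, float(zone.mean_at(edge)), zone.sd_um, spec.floor_um)
            center = edge + length / 2.0
            positions.append(center)
            lengths.append(length)
            files.append(f)
            zones.append(_zone_at(spec, center))
            edge += length
    order = np.argsort(positions, kind="stable")
    labels = [z.label for z in spec.zones]
    hair = None
    if len(labels) >= 2 and labels[-1] == "MZ" and labels[-2] == "EZ":
        hair = max(float(spec.limits_um[-1]) + spec.hair_offset_um, spec.floor_um)
    profile = CellLengthProfile(
        root_id=spec.root_id,
        positions=np.asarray(positions)[order],
        lengths=np.asarray(lengths)[order],
        file_ids=np.asarray(files)[order],
        metadata=RootMetadata(
            genotype=spec.genotype,
            root_type=spec.root_type,
            first_hair_position=hair,
        ),
    )
    truth = GroundTruth(
        spec=spec,
        limits_um=spec.limits_um.copy(),
        first_hair_um=hair,
        cell_zones=np.asarray(zones)[order],
    )
    return profile, truth


def generate_cohort(
    specs, master_seed: int = 0
) -> tuple[list[CellLengthProfile], pd.DataFrame]:
    """Generate one profile per spec from independent seeded streams."""
    specs = list(specs)
    ids = [s.root_id for s in specs]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate root_ids in cohort specs")
    streams = np.random.SeedSequence(master_seed).spawn(len(specs))
    profiles, rows = [], []
    for spec, ss in zip(specs, streams):
        profile, truth = generate_profile(spec, np.random.default_rng(ss))
        profiles.append(profile)
        rows.append(truth.summary_row())
    return profiles, pd.DataFrame(rows)


# -- presets ---------------------------------------------------------------


def a10_like_spec(root_id: str = "synthetic-A", **kw) -> ProfileSpec:
    """Vigorous 3-zone lateral root: flat short-celled division zone to
    855 um, elongation zone rising ~7 -> 45 um by 1494 um, long-celled mature
    zone with high dispersion."""
    zones = (
        ZoneSpec("DZ", 855.0, 5.4, 0.8, 1.3),
        ZoneSpec("EZ", 639.0, 7.3 - 59.5 / 1000.0 * 855.0, 59.5, 5.5),
        ZoneSpec("MZ", 1496.0, 53.3 - 49.6 / 1000.0 * 1494.0, 49.6, 18.2),
    )
    return ProfileSpec(root_id=root_id, zones=zones, root_type="A", **kw)


def single_zone_spec(
    root_id: str = "synthetic-single",
    span_um: float = 2000.0,
    mean_um: float = 30.0,
    slope_per_mm: float = 0.0,
    sd_um: float = 8.0,
    **kw,
) -> ProfileSpec:
    """One homogeneous zone (a single linear regime)."""
    zones = (ZoneSpec("MZ", span_um, mean_um, slope_per_mm, sd_um),)
    return ProfileSpec(root_id=root_id, zones=zones, **kw)


def c_type_spec(root_id: str = "synthetic-C", **kw) -> ProfileSpec:
    """Arrested root: a single mature-like zone with a mild positive trend
    and large dispersion, as in short type C roots."""
    zones = (ZoneSpec("MZ", 2000.0, 25.0, 27.0, 13.0),)
    return ProfileSpec(root_id=root_id, zones=zones, root_type="C", **kw)


# -- YAML round trip -------------------------------------------------------


def spec_to_yaml(spec: ProfileSpec, path) -> None:
    payload = {
        "root_id": spec.root_id,
        "n_files": spec.n_files,
        "floor_um": spec.floor_um,
        "hair_offset_um": spec.hair_offset_um,
        "genotype": spec.genotype,
        "root_type": spec.root_type,
        "zones": [
            {
                "label": z.label,
                "span_um": z.span_um,
                "intercept_um": z.intercept_um,
                "slope_per_mm": z.slope_per_mm,
                "sd_um": z.sd_um,
            }
            for z in spec.zones
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def spec_from_yaml(path) -> ProfileSpec:
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    zones = tuple(ZoneSpec(**z) for z in payload.pop("zones"))
    return ProfileSpec(zones=zones, **payload)
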