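"""Packaged per-root results for the 36-root maize lateral-root cohort.

Three CSV fixtures encode the published per-root analysis of 36 lateral roots
(18 wild-type, 8 rtcs, 10 rum-1):

* ``changepoint_models.csv`` -- per root and model family (piecewise linear /
  change in the variance): residual sd per zone, zone limits with uncertainty
  intervals, first-root-hair position, segmentation/model posteriors and the
  slope-heuristic zone number;
* ``piecewise_functions.csv`` -- the retained piecewise linear function, one
  row per zone: slope (um/mm), correlation (with a non-significance flag),
  cell count and the zone's shootward end (um);
* ``predicted_lengths.csv`` -- cell lengths predicted at the two ends of each
  zone's line, plus rootward/shootward confidence intervals at each limit.

These tables drive the cohort-level reproduction tests (type means,
continuity, co-localization, hair matching, correlation structure) in the
absence of the raw cell-length series, which were never deposited.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "FixtureCorruptionError",
    "FittedTablesFixture",
    "load_table_fixtures",
]

GENOTYPES = ("wild-type", "rtcs", "rum-1")
_EXPECTED_ROOTS = {"wild-type": 18, "rtcs": 8, "rum-1": 10}


class FixtureCorruptionError(RuntimeError):
    """Packaged tables are inconsistent with their documented invariants."""


def _read(name: str) -> pd.DataFrame:
    with resources.files("rootzones.fixtures").joinpath(name).open() as fh:
        return pd.read_csv(fh)


@dataclass(frozen=True)
class FittedTablesFixture:
    """The three fixture tables plus derived per-root summaries."""

    models: pd.DataFrame
    functions: pd.DataFrame
    predictions: pd.DataFrame

    # -- derived views -----------------------------------------------------

    @property
    def linear(self) -> pd.DataFrame:
        return self.models[self.models["family"] == "linear"].set_index(
            ["genotype", "root_id"]
        )

    @property
    def variance(self) -> pd.DataFrame:
        return self.models[self.models["family"] == "variance"].set_index(
            ["genotype", "root_id"]
        )

    @property
    def n_roots(self) -> int:
        return len(self.linear)

    def zone_counts(self) -> pd.Series:
        """Retained zone count per root (from the piecewise-function block)."""
        return self.functions.groupby(["genotype", "root_id"], sort=False).size()

    @property
    def n_limits(self) -> int:
        return int((self.zone_counts() - 1).sum())

    def root_summaries(self) -> pd.DataFrame:
        """One row per root: zone lengths, limits, slopes, predicted cell
        lengths at the elongation-zone ends, residual sds, hair position.

        Absent zones contribute length 0 (a root without a division zone has
        DZ length 0), which is how cohort means are defined.
        """
        lin = self.linear
        rows = []
        fun = self.functions.set_index(["genotype", "root_id", "zone"])
        pred = self.predictions.set_index(["genotype", "root_id", "zone"])
        for (gen, rid), r in lin.iterrows():
            dzez = r["dzez_limit"]
            ezmz = r["ezmz_limit"]
            dz_len = float(dzez) if np.isfinite(dzez) else 0.0
            ez_len = (float(ezmz) - dz_len) if np.isfinite(ezmz) else 0.0
            has_ez = (gen, rid, "EZ") in fun.index
            row = {
                "genotype": gen,
                "root_id": rid,
                "root_type": r["root_type"],
                "n_zones": int(self.zone_counts()[(gen, rid)]),
                "dz_length": dz_len,
                "ez_length": ez_len if has_ez else 0.0,
                "dzez_limit": float(dzez) if np.isfinite(dzez) else np.nan,
                "ezmz_limit": float(ezmz) if np.isfinite(ezmz) else np.nan,
                "first_hair": float(r["first_hair_um"]),
                "dz_sd": float(r["dz_sd"]) if np.isfinite(r["dz_sd"]) else np.nan,
                "ez_sd": float(r["ez_sd"]) if np.isfinite(r["ez_sd"]) else np.nan,
                "mz_sd": float(r["mz_sd"]),
            }
            if has_ez:
                row["ez_slope"] = float(fun.loc[(gen, rid, "EZ"), "slope_per_mm"])
                row["ez_pred_start"] = float(pred.loc[(gen, rid, "EZ"), "pred_start_um"])
                row["ez_pred_end"] = float(pred.loc[(gen, rid, "EZ"), "pred_end_um"])
            else:
                row["ez_slope"] = np.nan
                row["ez_pred_start"] = np.nan
                row["ez_pred_end"] = np.nan
            rows.append(row)
        return pd.DataFrame(rows)

    def continuity_counts(self) -> pd.DataFrame:
        """Per genotype: limits whose rootward and shootward confidence
        intervals for the predicted mean cell length overlap (closed
        intervals), over all printed limits."""
        pred = self.predictions.dropna(subset=["ci_rootward_lo"])
        overlap = np.maximum(pred["ci_rootward_lo"], pred["ci_shootward_lo"]) <= (
            np.minimum(pred["ci_rootward_hi"], pred["ci_shootward_hi"])
        )
        out = pred.assign(overlap=overlap).groupby("genotype")["overlap"]
        return out.agg(n_overlap="sum", n_limits="count").astype(int)

    def colocalization_counts(self) -> pd.DataFrame:
        """Per genotype: linear-model limits whose uncertainty interval
        overlaps the change-in-the-variance model's interval for the same
        limit.  A limit with no variance-model counterpart does not count as
        co-localized."""
        lin, var = self.linear, self.variance
        rows = []
        for key, r in lin.iterrows():
            v = var.loc[key]
            for which in ("dzez", "ezmz"):
                if not np.isfinite(r[f"{which}_limit"]):
                    continue
                if np.isfinite(v[f"{which}_limit"]):
                    ok = max(r[f"{which}_lo"], v[f"{which}_lo"]) <= min(
                        r[f"{which}_hi"], v[f"{which}_hi"]
                    )
                else:
                    ok = False
                rows.append({"genotype": key[0], "colocalized": bool(ok)})
        frame = pd.DataFrame(rows).groupby("genotype")["colocalized"]
        return frame.agg(n_colocalized="sum", n_limits="count").astype(int)

    def hair_match_counts(self) -> pd.DataFrame:
        """Per genotype: roots whose first-root-hair position falls in the
        elongation zone or inside the EZ-MZ limit's uncertainty interval,
        over roots with at least two zones."""
        lin = self.linear.reset_index()
        lin = lin[np.isfinite(lin["ezmz_limit"])]
        match = (lin["first_hair_um"] <= lin["ezmz_limit"]) | (
            (lin["first_hair_um"] >= lin["ezmz_lo"])
            & (lin["first_hair_um"] <= lin["ezmz_hi"])
        )
        out = lin.assign(match=match).groupby("genotype")["match"]
        return out.agg(n_match="sum", n_roots="count").astype(int)


def _validate(fix: FittedTablesFixture) -> None:
    counts = fix.linear.reset_index().groupby("genotype")["root_id"].count().to_dict()
    if counts != _EXPECTED_ROOTS:
        raise FixtureCorruptionError(f"unexpected root counts {counts}")
    if len(fix.variance) != len(fix.linear):
        raise FixtureCorruptionError("linear/variance row mismatch")
    zones = fix.zone_counts()
    for (gen, rid), r in fix.linear.iterrows():
        n_limits = int(np.isfinite(r["dzez_limit"])) + int(np.isfinite(r["ezmz_limit"]))
        if zones[(gen, rid)] != n_limits + 1:
            raise FixtureCorruptionError(
                f"{gen} {rid}: {zones[(gen, rid)]} zones vs {n_limits} limits"
            )
        if n_limits == 2 and not r["dzez_limit"] < r["ezmz_limit"]:
            raise FixtureCorruptionError(f"{gen} {rid}: limits not increasing")
    for _, r in fix.models.iterrows():
        for which in ("dzez", "ezmz"):
            lo, hi, lim = r[f"{which}_lo"], r[f"{which}_hi"], r[f"{which}_limit"]
            if np.isfinite(lim) and not (lo <= hi):
                raise FixtureCorruptionError("interval with low > high")
    pred = fix.predictions
    if set(pred["zone"]) - {"DZ", "EZ", "MZ"}:
        raise FixtureCorruptionError("unexpected zone label in predictions")
    for frame in (fix.functions, fix.predictions):
        if frame.groupby(["genotype", "root_id"], sort=False).size().sum() != len(frame):
            raise FixtureCorruptionError("duplicate zone rows")


@lru_cache(maxsize=1)
def load_table_fixtures() -> FittedTablesFixture:
    """Load and validate the packaged per-root tables (36 roots)."""
    fix = FittedTablesFixture(
        models=_read("changepoint_models.csv"),
        functions=_read("piecewise_functions.csv"),
        predictions=_read("predicted_lengths.csv"),
    )
    _validate(fix)
    return fix
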