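"""Cohort-level meta-analysis: per-root summaries, type means, correlations,
and principal component analysis with supplementary variables."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .profiles import RootMetadata
from .zoning import ZonedRoot

__all__ = [
    "summarize_root",
    "cohort_table",
    "type_zone_means",
    "pairwise_correlations",
    "PCAResult",
    "run_pca",
]


def summarize_root(zoned: ZonedRoot, metadata: RootMetadata | None = None) -> dict:
    """Flatten a zoned root into the standard cohort-table row.

    DZ length is the DZ-EZ limit position (0 when the division zone is
    absent); EZ length is the distance between the zone's two limits (or from
    the origin when there is no division zone).  The two predicted cell
    lengths come from evaluating the elongation-zone line at the zone's ends.
    """
    metadata = metadata or zoned.results.profile.metadata
    labels = zoned.labels
    limits = [l.position_um for l in zoned.limits]
    positions = zoned.results.profile.positions
    # collapse a TZ into the DZ for cohort purposes
    eff = [lab if lab != "TZ" else "DZ" for lab in labels]
    dz_len = ez_len = 0.0
    dzez = ezmz = np.nan
    ez_slope = ez_start = ez_end = np.nan
    if "EZ" in eff:
        i = labels.index("EZ")
        start = limits[i - 1] if i > 0 else float(positions[0])
        end = limits[i]
        seg = zoned.results.segments[i]
        ez_len = end - (limits[i - 1] if "DZ" in eff else 0.0)
        ez_slope = seg.slope_per_mm
        ez_start, ez_end = float(seg.predict(start)), float(seg.predict(end))
        ezmz = end
        if "DZ" in eff:
            dzez = limits[i - 1]
            dz_len = dzez
    sds = {"dz_sd": np.nan, "ez_sd": np.nan, "mz_sd": np.nan}
    for lab, seg in zip(eff, zoned.results.segments):
        key = f"{lab.lower()}_sd"
        if key in sds and np.isnan(sds[key]):
            sds[key] = seg.sigma
    diam = float(np.mean(metadata.diameters)) if metadata.diameters else np.nan
    return {
        "root_id": zoned.root_id,
        "genotype": metadata.genotype,
        "root_type": metadata.root_type,
        "n_zones": len(eff),
        "dz_length": dz_len,
        "ez_length": ez_len,
        "dzez_limit": dzez,
        "ezmz_limit": ezmz,
        "first_hair": metadata.first_hair_position,
        "ez_slope": ez_slope,
        "ez_pred_start": ez_start,
        "ez_pred_end": ez_end,
        **sds,
        "mz_diameter": diam,
        "provenance": zoned.provenance,
        "hair_match": zoned.hair_match_,
    }


def cohort_table(zoned_roots, metadata_map=None) -> pd.DataFrame:
    """Stack per-root summaries into a cohort table (one row per root)."""
    rows = []
    for z in zoned_roots:
        md = (metadata_map or {}).get(z.root_id)
        rows.append(summarize_root(z, md))
    return pd.DataFrame(rows)


def type_zone_means(summaries: pd.DataFrame, root_types) -> dict:
    """Mean DZ and EZ lengths (um) over roots of the given type(s).

    Roots lacking a zone contribute length 0, so the means describe the
    type, not just the roots that possess the zone.
    """
    if isinstance(root_types, str):
        root_types = (root_types,)
    sub = summaries[summaries["root_type"].isin(root_types)]
    if len(sub) == 0:
        raise ValueError(f"no roots of type(s) {tuple(root_types)}")
    return {
        "n": int(len(sub)),
        "dz_length": float(sub["dz_length"].mean()),
        "ez_length": float(sub["ez_length"].mean()),
    }


def pairwise_correlations(summaries: pd.DataFrame, variables) -> pd.DataFrame:
    """Pearson correlation matrix of the selected summary variables."""
    if len(summaries) < 3:
        raise ValueError("need at least 3 roots")
    sub = summaries[list(variables)].astype(float)
    degenerate = [v for v in variables if sub[v].std() == 0]
    if degenerate:
        warnings.warn(f"zero-variance variable(s): {degenerate}", stacklevel=2)
    return sub.corr()


@dataclass(frozen=True)
class PCAResult:
    """Correlation-matrix PCA with supplementary-variable projections.

    ``loadings`` are correlations of the standardized active variables with
    the axes; ``supplementary`` are correlations of supplementary variables
    with the axis scores (they never influence the axes).  Axis signs are
    fixed by forcing the largest-magnitude loading per axis positive.
    """

    loadings: pd.DataFrame
    explained_variance_ratio: np.ndarray
    scores: pd.DataFrame
    supplementary: pd.DataFrame


def run_pca(
    summaries: pd.DataFrame,
    active_variables,
    supplementary_variables=(),
) -> PCAResult:
    """PCA on z-standardized active variables (eigendecomposition of their
    correlation matrix); rows with missing values are dropped with a warning."""
    active = list(active_variables)
    supp = list(supplementary_variables)
    if len(active) < 2:
        raise ValueError("need at least 2 active variables")
    data = summaries[active + supp].astype(float)
    complete = data[active].notna().all(axis=1)
    if not complete.all():
        warnings.warn(
            f"dropping {(~complete).sum()} root(s) with missing active variables",
            stacklevel=2,
        )
    data = data[complete]
    if len(data) < 3:
        raise ValueError("need at least 3 complete-case roots")
    X = data[active].to_numpy()
    Z = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    corr = Z.T @ Z / (len(Z) - 1)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = np.clip(eigval[order], 0, None), eigvec[:, order]
    # deterministic axis orientation
    for k in range(eigvec.shape[1]):
        lead = np.argmax(np.abs(eigvec[:, k]))
        if eigvec[lead, k] < 0:
            eigvec[:, k] = -eigvec[:, k]
    scores = Z @ eigvec
    axes = [f"PC{k + 1}" for k in range(len(active))]
    loadings = pd.DataFrame(
        eigvec * np.sqrt(eigval)[None, :], index=active, columns=axes
    )
    supp_rows = {}
    for v in supp:
        col = data[v].to_numpy()
        ok = np.isfinite(col)
        supp_rows[v] = [
            float(np.corrcoef(col[ok], scores[ok, k])[0, 1]) if ok.sum() > 2 else np.nan
            for k in range(len(active))
        ]
    return PCAResult(
        loadings=loadings,
        explained_variance_ratio=eigval / eigval.sum(),
        scores=pd.DataFrame(scores, index=data.index, columns=axes),
        supplementary=pd.DataFrame(supp_rows, index=axes).T,
    )
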