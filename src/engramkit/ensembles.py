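"""Engram-ensemble reactivation statistics from slice count tables.

Input is one row per brain slice with counts of DAPI+, c-Fos+, mCherry+
(learning-tagged) and double-positive cells in a region of interest of
known area.  The module computes, per slice:

* label densities (cells/mm²),
* co-localization percentage  100 · overlap / mCherry+,
* chance overlap  (cFos+/DAPI+) · (mCherry+/DAPI+),
* enrichment (overlap over chance)  (overlap/DAPI+) / chance,

then averages over slices within each animal — animals, not slices, are
the unit of downstream statistics — and derives home-cage-normalized
c-Fos fold changes and single-cell intensity summaries.

Enrichment equals 1 when c-Fos and mCherry labels are independent; values
above 1 indicate preferential reactivation of the tagged ensemble.
"""

from __future__ import annotations

import warnings
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import UndefinedStatistic

COUNT_COLUMNS = (
    "animal_id", "slice_id", "region", "area_mm2",
    "n_dapi", "n_cfos", "n_mcherry", "n_overlap",
)

#: Per-slice statistics carried into the per-animal aggregation.
SLICE_STATS = (
    "density_cfos", "density_mcherry", "coloc_pct",
    "overlap_over_dapi", "chance", "enrichment",
)


def density(count: float, area_mm2: float) -> float:
    """Cell density in cells/mm²."""
    if area_mm2 <= 0:
        raise ValueError(f"area must be > 0 mm², got {area_mm2}")
    return count / area_mm2


def reactivation_percentage(n_overlap: int, n_mcherry: int) -> float:
    """Reactivated fraction of the tagged ensemble: 100·overlap/mCherry+."""
    if n_mcherry <= 0:
        raise UndefinedStatistic("co-localization undefined: no mCherry+ cells")
    return 100.0 * n_overlap / n_mcherry


def chance_level(n_cfos: int, n_mcherry: int, n_dapi: int) -> float:
    """Expected overlap fraction under label independence.

    The product (cFos+/DAPI+)·(mCherry+/DAPI+), computed per slice.
    """
    if n_dapi <= 0:
        raise ValueError("chance level requires DAPI+ > 0")
    return (n_cfos / n_dapi) * (n_mcherry / n_dapi)


def enrichment(n_dapi: int, n_cfos: int, n_mcherry: int, n_overlap: int) -> float:
    """Overlap over chance: (overlap/DAPI+) / ((cFos+/DAPI+)·(mCherry+/DAPI+)).

    Equals 1 at chance-level reactivation.  A slice with zero chance and
    zero overlap carries no information and is undefined (excluded upstream
    with a warning); zero chance with positive overlap is impossible input.
    """
    ch = chance_level(n_cfos, n_mcherry, n_dapi)
    if ch == 0.0:
        if n_overlap > 0:
            raise ValueError("impossible counts: overlap > 0 with zero chance")
        raise UndefinedStatistic("enrichment undefined: zero chance, zero overlap")
    return (n_overlap / n_dapi) / ch


def per_slice_stats(counts: pd.DataFrame) -> pd.DataFrame:
    """Compute all per-slice statistics; undefined entries become NaN.

    Slices with zero mCherry+ (co-localization) or zero chance (enrichment)
    are flagged with a warning and left NaN so the per-animal averages
    skip them rather than imputing.
    """
    df = counts.copy()
    if (df["n_overlap"] > np.minimum(df["n_cfos"], df["n_mcherry"])).any():
        raise ValueError("invalid counts: n_overlap exceeds min(n_cfos, n_mcherry)")
    df["density_cfos"] = df["n_cfos"] / df["area_mm2"]
    df["density_mcherry"] = df["n_mcherry"] / df["area_mm2"]
    with np.errstate(divide="ignore", invalid="ignore"):
        df["coloc_pct"] = np.where(
            df["n_mcherry"] > 0, 100.0 * df["n_overlap"] / df["n_mcherry"], np.nan
        )
        df["overlap_over_dapi"] = df["n_overlap"] / df["n_dapi"]
        df["chance"] = (df["n_cfos"] / df["n_dapi"]) * (df["n_mcherry"] / df["n_dapi"])
        df["enrichment"] = np.where(
            df["chance"] > 0, df["overlap_over_dapi"] / df["chance"], np.nan
        )
    n_bad = int(df["coloc_pct"].isna().sum() + df["enrichment"].isna().sum())
    if n_bad:
        warnings.warn(
            f"{n_bad} undefined slice statistics (zero mCherry+ or zero chance) "
            "excluded from animal means",
            stacklevel=2,
        )
    return df


def aggregate_animal(
    counts: pd.DataFrame, by: tuple[str, ...] = ("animal_id", "region")
) -> pd.DataFrame:
    """Average per-slice statistics within animal (and region).

    Slices are equally weighted regardless of ROI area, matching the
    convention of averaging four to five sections per animal; undefined
    slices are skipped per statistic.  Animals with no valid slice for a
    statistic are left NaN and reported with a warning.
    """
    stats_df = per_slice_stats(counts) if "enrichment" not in counts.columns else counts
    out = stats_df.groupby(list(by), as_index=False)[list(SLICE_STATS)].mean()
    out["n_slices"] = stats_df.groupby(list(by)).size().to_numpy()
    bad = out[list(SLICE_STATS)].isna().any(axis=1)
    if bad.any():
        warnings.warn(
            f"{int(bad.sum())} animal/region groups have undefined statistics "
            "(no valid slice)",
            stacklevel=2,
        )
    return out


def fold_change_vs_homecage(
    encoding: pd.DataFrame,
    homecage: pd.DataFrame,
    value: str = "density_cfos",
    by: tuple[str, ...] = ("genotype", "region"),
) -> pd.DataFrame:
    """Normalize per-animal densities to the matched home-cage group mean.

    Both inputs are per-animal tables carrying ``value`` and the grouping
    keys (typically genotype and region).  Each encoding animal's density
    is divided by the scalar mean of its matching home-cage group; the
    output reports per-animal fold changes plus group mean ± SEM.  By
    construction the home-cage group normalized against itself has mean 1.
    """
    hc_means = homecage.groupby(list(by))[value].mean()
    if hc_means.empty or (hc_means <= 0).any():
        raise ValueError("home-cage group mean missing or non-positive")
    key = pd.MultiIndex.from_frame(encoding[list(by)])
    missing = ~key.isin(hc_means.index)
    if missing.any():
        raise ValueError(
            f"no home-cage control for groups: {sorted(set(key[missing]))}"
        )
    out = encoding.copy()
    out["fold_change"] = encoding[value].to_numpy() / hc_means.loc[key].to_numpy()
    summary = (
        out.groupby(list(by))["fold_change"]
        .agg(mean="mean", sem=lambda v: v.std(ddof=1) / np.sqrt(len(v)), n="size")
        .reset_index()
    )
    out.attrs["group_summary"] = summary
    return out


def mean_cell_intensity(
    intensities: pd.DataFrame, partition: str = "total"
) -> pd.DataFrame:
    """Per-animal mean of per-c-Fos+-cell fluorescence intensities.

    ``intensities`` is long-format (animal_id, slice_id, cell_id,
    mcherry_flag, mean_intensity).  The per-slice mean of per-cell means is
    computed first, then averaged over slices per animal — so slices are
    equally weighted regardless of cell count.  ``partition`` selects the
    cell population: ``"total"``, ``"mcherry_pos"`` or ``"mcherry_neg"``;
    slices with an empty partition are skipped with a warning.
    """
    if partition == "total":
        sub = intensities
    elif partition == "mcherry_pos":
        sub = intensities[intensities["mcherry_flag"]]
    elif partition == "mcherry_neg":
        sub = intensities[~intensities["mcherry_flag"]]
    else:
        raise ValueError(f"unknown partition {partition!r}")
    n_slices_all = intensities.groupby("animal_id")["slice_id"].nunique()
    per_slice = sub.groupby(["animal_id", "slice_id"])["mean_intensity"].mean()
    per_animal = per_slice.groupby("animal_id").mean()
    n_used = per_slice.groupby("animal_id").size()
    skipped = (n_slices_all - n_used.reindex(n_slices_all.index, fill_value=0)).sum()
    if skipped:
        warnings.warn(
            f"{int(skipped)} slices had no cells in partition {partition!r}; skipped",
            stacklevel=2,
        )
    return per_animal.rename(f"mean_intensity_{partition}").reset_index()
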