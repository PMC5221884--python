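"""Mutant / wild-type comparisons.

Ratio tracks divide a mutant's binned subcontext levels by the wild type's,
bin by bin; bins where the wild-type level is below a floor are masked to
avoid ratio blow-up. Bias summaries condense a region's subcontext levels
into two ratios:

* ``ccg_bias``  = level(CCG) / mean(level(CAG), level(CTG))
* ``chh_bias``  = mean(favored CHH set) / mean(remaining CHH set)

Heterochromatin maintained by chromomethyltransferases shows ccg_bias < 1
and chh_bias > 1; RdDM-dominated euchromatin shows both near 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .context import CHH_SUBCONTEXTS
from .methylome import RegionSpec, SubcontextTrack, region_level

DEFAULT_WT_FLOOR = 0.01

# Favored CHH subcontext sets by species-style; the favored set is the one
# the heterochromatic chromomethyltransferase pathway preferentially targets.
FAVORED_CHH_SETS = {
    "arabidopsis": ("CAA", "CTA"),
    "maize": ("CAA", "CTA"),
    "tomato": ("CAA", "CAT"),
    "rice": ("CTA",),
}


@dataclass
class RatioTrack:
    """Per-bin mutant/wt level ratios; see ``ratio_track``."""

    data: pd.DataFrame
    bin_size: int
    wt_floor: float
    mutant_label: str = "mutant"
    wt_label: str = "wt"


def ratio_track(
    mutant: SubcontextTrack,
    wt: SubcontextTrack,
    wt_floor: float = DEFAULT_WT_FLOOR,
    mutant_label: str = "mutant",
    wt_label: str = "wt",
) -> RatioTrack:
    """Elementwise mutant/wt ratio of binned subcontext levels.

    Both tracks must share binning and estimator. Bins whose wild-type level
    is missing or below ``wt_floor`` get a NaN ratio.
    """
    if mutant.bin_size != wt.bin_size:
        raise ValueError("mismatched bin sizes")
    if mutant.estimator != wt.estimator:
        raise ValueError("mismatched estimators")
    keys = ["contig", "bin_start", "bin_end", "subcontext"]
    if not mutant.data[keys].equals(wt.data[keys]):
        raise ValueError("mismatched binning (contig/bin grids differ)")
    merged = mutant.data[keys + ["level", "n_sites"]].merge(
        wt.data[keys + ["level", "n_sites"]],
        on=keys, suffixes=("_mut", "_wt"),
    )
    wt_level = merged["level_wt"].to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(
            np.isfinite(wt_level) & (wt_level >= wt_floor),
            merged["level_mut"].to_numpy() / wt_level,
            np.nan,
        )
    merged["ratio"] = ratio
    return RatioTrack(merged, mutant.bin_size, wt_floor, mutant_label, wt_label)


@dataclass
class BiasSummary:
    region: str
    genotype: str
    ccg_bias: float
    chh_bias: float
    reason: str | None = None


def bias_summary(
    levels: Mapping[str, float],
    favored_set: tuple[str, ...] = ("CAA", "CTA"),
    region: str = "",
    genotype: str = "",
) -> BiasSummary:
    """Subcontext-bias ratios from a mapping subcontext -> level.

    Both biases are scale-invariant: multiplying every level by c > 0
    leaves them unchanged.
    """
    reason = None

    def _mean(keys):
        vals = [levels[k] for k in keys if k in levels and np.isfinite(levels[k])]
        return float(np.mean(vals)) if vals else np.nan

    chg_denom = _mean(["CAG", "CTG"])
    ccg = levels.get("CCG", np.nan)
    if not np.isfinite(chg_denom) or chg_denom == 0 or not np.isfinite(ccg):
        ccg_bias, reason = np.nan, "undefined CAG/CTG denominator"
    else:
        ccg_bias = float(ccg / chg_denom)

    other = [k for k in CHH_SUBCONTEXTS if k not in favored_set]
    fav, oth = _mean(favored_set), _mean(other)
    if not np.isfinite(oth) or oth == 0 or not np.isfinite(fav):
        chh_bias = np.nan
        reason = reason or "undefined CHH denominator"
    else:
        chh_bias = float(fav / oth)
    return BiasSummary(region, genotype, ccg_bias, chh_bias, reason)


def region_levels_map(region_table: pd.DataFrame, region: str) -> dict[str, float]:
    """Extract {subcontext: level} for one region from a region_level table."""
    sel = region_table[
        (region_table["region"] == region) & (region_table["kind"] == "subcontext")
    ]
    return dict(zip(sel["key"], sel["level"]))


def genotype_effect_table(
    genotype_sites: Mapping[str, pd.DataFrame],
    regions: RegionSpec,
    estimator: str = "site_mean",
    min_depth: int = 1,
    favored_set: tuple[str, ...] = ("CAA", "CTA"),
) -> pd.DataFrame:
    """Long-form (genotype, region, subcontext) level table with wt ratios.

    ``genotype_sites`` maps genotype label -> CX site DataFrame and must
    include "wt". Each row carries the level, the ratio to the wild type in
    the same cell, and the region's chh_bias for its genotype (repeated per
    row, for convenience in downstream qualitative calls).
    """
    if "wt" not in genotype_sites:
        raise ValueError('genotype map must include "wt"')
    tables = {
        g: region_level(df, regions, estimator=estimator, min_depth=min_depth)
        for g, df in genotype_sites.items()
    }
    wt = tables["wt"].set_index(["region", "kind", "key"])["level"]
    rows = []
    for genotype, table in tables.items():
        biases = {
            region: bias_summary(
                region_levels_map(table, region), favored_set, region, genotype
            ).chh_bias
            for region in regions.names()
        }
        for row in table.itertuples(index=False):
            wt_level = wt.get((row.region, row.kind, row.key), np.nan)
            ratio = (
                row.level / wt_level
                if np.isfinite(wt_level) and wt_level > 0 and np.isfinite(row.level)
                else np.nan
            )
            rows.append(
                {"genotype": genotype, "region": row.region, "kind": row.kind,
                 "key": row.key, "n_sites": row.n_sites, "level": row.level,
                 "ratio_vs_wt": ratio, "chh_bias": biases[row.region]}
            )
    return pd.DataFrame(rows)


def bootstrap_bias_ci(
    track: SubcontextTrack,
    favored_set: tuple[str, ...] = ("CAA", "CTA"),
    n_boot: int = 200,
    seed: int = 0,
    alpha: float = 0.05,
) -> dict[str, tuple[float, float]]:
    """Bootstrap CIs for the two bias ratios over genomic bins.

    Optional descriptive extra (the bias differences themselves are reported
    without a test); resamples bins with replacement.
    """
    rng = np.random.default_rng(seed)
    pivot = track.data.pivot_table(
        index=["contig", "bin_start"], columns="subcontext", values="level"
    )
    stats = {"ccg_bias": [], "chh_bias": []}
    n = len(pivot)
    for _ in range(n_boot):
        sample = pivot.iloc[rng.integers(0, n, n)]
        levels = sample.mean(skipna=True).to_dict()
        b = bias_summary(levels, favored_set)
        stats["ccg_bias"].append(b.ccg_bias)
        stats["chh_bias"].append(b.chh_bias)
    out = {}
    for key, vals in stats.items():
        vals = np.asarray(vals, dtype=float)
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            out[key] = (np.nan, np.nan)
        else:
            out[key] = (
                float(np.quantile(vals, alpha / 2)),
                float(np.quantile(vals, 1 - alpha / 2)),
            )
    return out
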