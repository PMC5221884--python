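"""Per-site and binned subcontext methylation statistics.

The central quantity is the methylation level of a cytosine, the fraction of
methylated calls mC/(mC+C). Two aggregate estimators are always computed:

* ``pooled``: sum of methylated calls over sum of all calls (coverage-weighted);
* ``site_mean``: unweighted mean of per-site levels over qualifying sites.

"Qualifying" means coverage >= ``min_depth``. The default reported estimator
is ``site_mean`` with ``min_depth=1``, reading "non-weighted" levels as sites
not weighted by their coverage; the pooled estimator is stored alongside.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .context import CONTEXT_CLASS, SUBCONTEXTS

HISTOGRAM_BINS = 50  # equal bins on [0,1], right-closed last bin

# Default region boundaries for an A. thaliana-like chromosome 1:
# pericentric heterochromatin 13-16 Mb, arms 0-10 and 20-30 Mb.
ARABIDOPSIS_CHR1_REGIONS = {
    "pericentromere": [("chr1", 13_000_000, 16_000_000)],
    "arms": [("chr1", 0, 10_000_000), ("chr1", 20_000_000, 30_000_000)],
}


@dataclass
class RegionSpec:
    """Named unions of 0-based half-open intervals, per contig."""

    regions: dict[str, list[tuple[str, int, int]]]

    def __post_init__(self) -> None:
        for name, ivs in self.regions.items():
            by_contig: dict[str, list[tuple[int, int]]] = {}
            for contig, start, end in ivs:
                if start >= end:
                    raise ValueError(f"{name}: empty interval [{start},{end})")
                by_contig.setdefault(contig, []).append((start, end))
            for contig, spans in by_contig.items():
                spans.sort()
                for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
                    if s2 < e1:
                        raise ValueError(
                            f"{name}: overlapping intervals on {contig}"
                        )

    def names(self) -> list[str]:
        return list(self.regions)

    def mask(self, sites: pd.DataFrame, name: str) -> np.ndarray:
        """Boolean mask of sites (1-based pos) inside the named region."""
        mask = np.zeros(len(sites), dtype=bool)
        pos0 = sites["pos"].to_numpy() - 1
        contigs = sites["contig"].to_numpy()
        for contig, start, end in self.regions[name]:
            mask |= (contigs == contig) & (pos0 >= start) & (pos0 < end)
        return mask


@dataclass
class SubcontextTrack:
    """Binned per-subcontext methylation levels along contigs.

    ``data`` columns: contig, bin_start, bin_end, subcontext, n_sites,
    n_meth_calls, n_total_calls, level_pooled, level_site_mean, level
    (the selected estimator). Bins tile each contig contiguously; the last
    bin may be short.
    """

    data: pd.DataFrame
    bin_size: int
    estimator: str
    min_depth: int


def site_level(n_meth, n_unmeth):
    """mC/(mC+C); NaN where coverage is zero. Works on scalars and arrays."""
    n_meth = np.asarray(n_meth, dtype=float)
    n_unmeth = np.asarray(n_unmeth, dtype=float)
    cov = n_meth + n_unmeth
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(cov > 0, n_meth / np.where(cov > 0, cov, 1), np.nan)
    if out.ndim == 0:
        return float(out)
    return out


def correct_nonconversion(level, epsilon: float):
    """Remove the upward bias from bisulfite conversion failure.

    With failure rate ``epsilon`` an unmethylated call reads as methylated
    with probability epsilon, so observed = m + (1-m)*epsilon; this inverts
    that relation. Results are clipped to [0, 1].
    """
    if not 0 <= epsilon < 1:
        raise ValueError("epsilon must be in [0, 1)")
    return np.clip((np.asarray(level, dtype=float) - epsilon) / (1 - epsilon), 0, 1)


def _aggregate(group: pd.DataFrame) -> pd.Series:
    levels = group["level"].to_numpy()
    total = group["cov"].sum()
    return pd.Series(
        {
            "n_sites": len(group),
            "n_meth_calls": group["n_meth"].sum(),
            "n_total_calls": total,
            "level_pooled": group["n_meth"].sum() / total if total else np.nan,
            "level_site_mean": float(np.mean(levels)) if len(levels) else np.nan,
        }
    )


def _qualify(sites: pd.DataFrame, min_depth: int) -> pd.DataFrame:
    df = sites.copy()
    df["cov"] = df["n_meth"] + df["n_unmeth"]
    df = df[df["cov"] >= max(min_depth, 1)]
    df["level"] = df["n_meth"] / df["cov"]
    return df


def bin_track(
    sites: pd.DataFrame,
    genome_lengths: dict[str, int],
    bin_size: int,
    estimator: str = "site_mean",
    min_depth: int = 1,
) -> SubcontextTrack:
    """Binned subcontext methylation along each contig.

    ``sites`` is a CX-report DataFrame (see ``io.load_cx_report``). Both
    estimators are computed and stored; ``estimator`` selects the ``level``
    column. Every (bin, subcontext) cell is emitted, with NaN levels where no
    site qualifies, so bins tile each contig contiguously.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    if estimator not in {"pooled", "site_mean"}:
        raise ValueError(f"unknown estimator {estimator!r}")

    df = _qualify(sites, min_depth)
    df["bin_start"] = (df["pos"] - 1) // bin_size * bin_size
    agg = (
        df.groupby(["contig", "bin_start", "subcontext"])
        .apply(_aggregate, include_groups=False)
        .reset_index()
    )

    # complete grid: every bin x subcontext for every contig
    frames = []
    for contig, length in genome_lengths.items():
        starts = np.arange(0, length, bin_size)
        grid = pd.MultiIndex.from_product(
            [[contig], starts, SUBCONTEXTS],
            names=["contig", "bin_start", "subcontext"],
        ).to_frame(index=False)
        frames.append(grid)
    grid = pd.concat(frames, ignore_index=True)
    out = grid.merge(agg, on=["contig", "bin_start", "subcontext"], how="left")
    for col in ("n_sites", "n_meth_calls", "n_total_calls"):
        out[col] = out[col].fillna(0).astype(np.int64)
    out["bin_end"] = np.minimum(
        out["bin_start"] + bin_size,
        out["contig"].map(genome_lengths).astype(np.int64),
    )
    out["level"] = out[f"level_{estimator}"]
    cols = ["contig", "bin_start", "bin_end", "subcontext", "n_sites",
            "n_meth_calls", "n_total_calls", "level_pooled",
            "level_site_mean", "level"]
    return SubcontextTrack(out[cols], bin_size, estimator, min_depth)


def region_level(
    sites: pd.DataFrame,
    regions: RegionSpec,
    estimator: str = "site_mean",
    min_depth: int = 1,
) -> pd.DataFrame:
    """Per-region, per-subcontext levels plus CG/CHG/CHH class aggregates.

    Returns one row per (region, subcontext) and per (region, class), with
    n_sites, n_meth_calls, n_total_calls, level_pooled, level_site_mean and
    the selected ``level``. Class aggregates pool all sites of the class
    (site_mean averages over all sites of the class, not over subcontext
    means).
    """
    if estimator not in {"pooled", "site_mean"}:
        raise ValueError(f"unknown estimator {estimator!r}")
    df = _qualify(sites, min_depth)
    rows = []
    for name in regions.names():
        sub = df[regions.mask(df, name)]
        if sub.empty:
            import warnings

            warnings.warn(f"region {name!r} contains no qualifying sites",
                          stacklevel=2)
        for key, group in sub.groupby("subcontext"):
            rec = _aggregate(group)
            rows.append({"region": name, "key": key, "kind": "subcontext", **rec})
        for cls in ("CG", "CHG", "CHH"):
            group = sub[sub["subcontext"].map(CONTEXT_CLASS) == cls]
            if len(group):
                rec = _aggregate(group)
                rows.append({"region": name, "key": cls, "kind": "class", **rec})
    out = pd.DataFrame(rows)
    if not out.empty:
        out["level"] = out[f"level_{estimator}"]
    return out


def per_site_density(
    sites: pd.DataFrame,
    regions: RegionSpec,
    min_depth: int = 8,
    n_hist_bins: int = HISTOGRAM_BINS,
) -> pd.DataFrame:
    """Histograms of per-site methylation levels per region and subcontext.

    Only sites with coverage >= ``min_depth`` contribute (the well-covered
    sites whose level estimates resolve bimodality). Returns one row per
    (region, subcontext, histogram bin) with bin edges and count.
    """
    if min_depth < 1:
        raise ValueError("min_depth must be >= 1")
    df = _qualify(sites, min_depth)
    edges = np.linspace(0, 1, n_hist_bins + 1)
    rows = []
    for name in regions.names():
        sub = df[regions.mask(df, name)]
        for key, group in sub.groupby("subcontext"):
            counts, _ = np.histogram(group["level"].to_numpy(), bins=edges)
            for i, c in enumerate(counts):
                rows.append(
                    {"region": name, "subcontext": key,
                     "bin_low": edges[i], "bin_high": edges[i + 1],
                     "count": int(c)}
                )
    return pd.DataFrame(rows)


def bimodality_summary(density: pd.DataFrame) -> pd.DataFrame:
    """Mass below 0.2, above 0.8, and in between, per region and subcontext."""
    rows = []
    for (region, key), group in density.groupby(["region", "subcontext"]):
        total = group["count"].sum()
        low = group.loc[group["bin_high"] <= 0.2, "count"].sum()
        high = group.loc[group["bin_low"] >= 0.8, "count"].sum()
        rows.append(
            {"region": region, "subcontext": key, "n_sites": int(total),
             "mass_low": low / total if total else np.nan,
             "mass_high": high / total if total else np.nan,
             "mass_mid": (total - low - high) / total if total else np.nan}
        )
    return pd.DataFrame(rows)


@dataclass
class ConversionRate:
    """Bisulfite conversion rate from an unmethylated control contig."""

    overall: float
    per_subcontext: pd.DataFrame  # subcontext, n_meth, n_total, rate
    n_calls: int


def conversion_rate(sites: pd.DataFrame, control_contig: str) -> ConversionRate:
    """1 - pooled methylation over all cytosines of the control contig.

    The per-subcontext breakdown is the control that apparent subcontext
    bias is absent on unmethylated DNA.
    """
    sub = sites[sites["contig"] == control_contig]
    total = int((sub["n_meth"] + sub["n_unmeth"]).sum())
    if sub.empty or total == 0:
        raise ValueError(f"no covered control sites on {control_contig!r}")
    overall = 1.0 - sub["n_meth"].sum() / total
    rows = []
    for key, group in sub.groupby("subcontext"):
        t = int((group["n_meth"] + group["n_unmeth"]).sum())
        rows.append(
            {"subcontext": key, "n_meth": int(group["n_meth"].sum()),
             "n_total": t, "rate": 1.0 - group["n_meth"].sum() / t if t else np.nan}
        )
    return ConversionRate(float(overall), pd.DataFrame(rows), total)
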