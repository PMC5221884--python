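"""Feature-anchored average methylation profiles (metagene / meta-transposon).

Each feature body is rescaled to a fixed number of bins; fixed-width flanks
are added on both sides. Minus-strand features are flipped so that bin 0 is
always 5'-most. Within a position bin, levels are pooled across features
(coverage-weighted counts), since per-(feature, bin) site counts are tiny.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .context import CONTEXT_CLASS, SUBCONTEXTS
from .io import FeatureRecord

_SUB_INDEX = {k: i for i, k in enumerate(SUBCONTEXTS)}


@dataclass
class MetaProfile:
    """Average subcontext methylation over scaled feature bodies plus flanks.

    ``data`` columns: bin (0-based along the profile), segment (upstream /
    body / downstream), subcontext, n_pairs (contributing (site, feature)
    pairs), n_meth_calls, n_total_calls, level_pooled, level_site_mean,
    level. Bin 0 is the 5'-most upstream flank bin.
    """

    data: pd.DataFrame
    flank_bp: int
    n_flank_bins: int
    n_body_bins: int
    feature_set: str = ""
    n_features: int = 0
    n_skipped_short: int = 0

    @property
    def n_bins(self) -> int:
        return 2 * self.n_flank_bins + self.n_body_bins

    def body_bins(self) -> pd.DataFrame:
        return self.data[self.data["segment"] == "body"]


def meta_profile(
    sites: pd.DataFrame,
    features: list[FeatureRecord],
    flank_bp: int = 1000,
    n_flank_bins: int = 20,
    n_body_bins: int = 40,
    estimator: str = "pooled",
    min_depth: int = 1,
    min_feature_length: int = 200,
    feature_set: str = "",
) -> MetaProfile:
    """Average subcontext methylation over a feature set.

    Flanks are split into ``n_flank_bins`` windows of ``flank_bp /
    n_flank_bins`` bases; the body into ``n_body_bins`` equal fractions.
    A site overlapped by two features contributes to both. Features shorter
    than ``min_feature_length`` are skipped and counted.
    """
    if not features:
        raise ValueError("empty feature set")
    if min_feature_length < n_body_bins:
        raise ValueError("min_feature_length must be >= n_body_bins")
    if estimator not in {"pooled", "site_mean"}:
        raise ValueError(f"unknown estimator {estimator!r}")

    n_bins = 2 * n_flank_bins + n_body_bins
    n_sub = len(SUBCONTEXTS)
    meth = np.zeros((n_bins, n_sub))
    total = np.zeros((n_bins, n_sub))
    level_sum = np.zeros((n_bins, n_sub))
    pairs = np.zeros((n_bins, n_sub), dtype=np.int64)

    # per-contig sorted site arrays
    by_contig: dict[str, dict[str, np.ndarray]] = {}
    df = sites.copy()
    df["cov"] = df["n_meth"] + df["n_unmeth"]
    df = df[df["cov"] >= max(min_depth, 1)]
    for contig, group in df.groupby("contig"):
        group = group.sort_values("pos")
        by_contig[contig] = {
            "pos0": group["pos"].to_numpy() - 1,
            "n_meth": group["n_meth"].to_numpy(),
            "cov": group["cov"].to_numpy(),
            "sub": group["subcontext"].map(_SUB_INDEX).to_numpy(),
        }

    flank_bin_bp = flank_bp / n_flank_bins
    n_skipped = 0
    n_used = 0
    for feat in features:
        if feat.length < min_feature_length:
            n_skipped += 1
            continue
        arrs = by_contig.get(feat.contig)
        n_used += 1
        if arrs is None:
            continue
        lo, hi = feat.start - flank_bp, feat.end + flank_bp
        i0, i1 = np.searchsorted(arrs["pos0"], [lo, hi])
        if i0 == i1:
            continue
        pos0 = arrs["pos0"][i0:i1]
        rel = pos0 - feat.start
        bins = np.empty(pos0.size, dtype=np.int64)
        in_body = (rel >= 0) & (pos0 < feat.end)
        upstream = rel < 0
        downstream = pos0 >= feat.end
        bins[upstream] = n_flank_bins + np.floor(rel[upstream] / flank_bin_bp)
        frac = rel[in_body] / feat.length
        bins[in_body] = n_flank_bins + np.minimum(
            (frac * n_body_bins).astype(np.int64), n_body_bins - 1
        )
        bins[downstream] = (
            n_flank_bins + n_body_bins
            + np.minimum(((pos0[downstream] - feat.end) / flank_bin_bp)
                         .astype(np.int64), n_flank_bins - 1)
        )
        keep = (bins >= 0) & (bins < n_bins)
        bins, subi = bins[keep], arrs["sub"][i0:i1][keep]
        if feat.orientation == "-":
            bins = n_bins - 1 - bins
        nm = arrs["n_meth"][i0:i1][keep]
        cv = arrs["cov"][i0:i1][keep]
        np.add.at(meth, (bins, subi), nm)
        np.add.at(total, (bins, subi), cv)
        np.add.at(level_sum, (bins, subi), nm / cv)
        np.add.at(pairs, (bins, subi), 1)

    if n_used == 0:
        raise ValueError("all features shorter than min_feature_length")

    with np.errstate(invalid="ignore", divide="ignore"):
        pooled = np.where(total > 0, meth / np.where(total > 0, total, 1), np.nan)
        site_mean = np.where(pairs > 0, level_sum / np.where(pairs > 0, pairs, 1),
                             np.nan)

    segments = (["upstream"] * n_flank_bins + ["body"] * n_body_bins
                + ["downstream"] * n_flank_bins)
    rows = []
    for b in range(n_bins):
        for s, key in enumerate(SUBCONTEXTS):
            rows.append(
                {"bin": b, "segment": segments[b], "subcontext": key,
                 "n_pairs": int(pairs[b, s]),
                 "n_meth_calls": int(meth[b, s]),
                 "n_total_calls": int(total[b, s]),
                 "level_pooled": pooled[b, s],
                 "level_site_mean": site_mean[b, s]}
            )
    data = pd.DataFrame(rows)
    data["level"] = data[f"level_{estimator}"]
    return MetaProfile(data, flank_bp, n_flank_bins, n_body_bins,
                       feature_set, n_used, n_skipped)


def profile_by_family(
    sites: pd.DataFrame,
    features: list[FeatureRecord],
    min_family_count: int = 5,
    **kwargs,
) -> dict[str, MetaProfile]:
    """Independent profile per feature family; small families are dropped."""
    families: dict[str, list[FeatureRecord]] = {}
    for f in features:
        if f.family is not None:
            families.setdefault(f.family, []).append(f)
    out = {}
    for family, feats in sorted(families.items()):
        if len(feats) < min_family_count:
            warnings.warn(
                f"family {family!r} has {len(feats)} feature(s) "
                f"(< {min_family_count}); dropped", stacklevel=2,
            )
            continue
        out[family] = meta_profile(sites, feats, feature_set=family, **kwargs)
    return out


@dataclass
class SignatureStats:
    """Summary of a profile's chromomethyltransferase-vs-RdDM character.

    ``body_bias`` is the mean level of the favored CHH subcontexts over the
    mean of the remaining CHH subcontexts across body bins (> 1 indicates a
    chromomethyltransferase-like, subcontext-biased body). ``edge_enrichment``
    is the mean all-CHH level in the first and last body bins over the mean
    across the central body bins (> 1 indicates edge-localised,
    RdDM-like methylation).
    """

    body_bias: float
    edge_enrichment: float
    reason: str | None = None


def signature_stats(
    profile: MetaProfile,
    favored: tuple[str, ...] = ("CAA", "CTA"),
    n_edge_bins: int = 1,
) -> SignatureStats:
    body = profile.body_bins()
    chh = body[body["subcontext"].map(CONTEXT_CLASS) == "CHH"]
    favored_levels = chh.loc[chh["subcontext"].isin(favored), "level"]
    other_levels = chh.loc[~chh["subcontext"].isin(favored), "level"]
    fav = np.nanmean(favored_levels) if favored_levels.notna().any() else np.nan
    oth = np.nanmean(other_levels) if other_levels.notna().any() else np.nan
    if not np.isfinite(oth) or oth == 0:
        body_bias, reason = np.nan, "undefined denominator in body_bias"
    else:
        body_bias, reason = float(fav / oth), None

    # all-CHH pooled level per body bin
    bins = sorted(chh["bin"].unique())
    per_bin = (
        chh.groupby("bin")[["n_meth_calls", "n_total_calls"]].sum(min_count=1)
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        bin_level = per_bin["n_meth_calls"] / per_bin["n_total_calls"]
    edge_idx = bins[:n_edge_bins] + bins[-n_edge_bins:]
    central_idx = bins[n_edge_bins:-n_edge_bins]
    edge = np.nanmean(bin_level.reindex(edge_idx))
    central = np.nanmean(bin_level.reindex(central_idx))
    if not np.isfinite(central) or central == 0:
        edge_enr = np.nan
        reason = reason or "undefined denominator in edge_enrichment"
    else:
        edge_enr = float(edge / central)
    return SignatureStats(body_bias, edge_enr, reason)
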