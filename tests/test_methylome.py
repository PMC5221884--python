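"""Binned and per-site methylation statistics: estimators, densities,
conversion-rate control."""

import numpy as np
import pandas as pd
import pytest

from methylctx import methylome
from methylctx.methylome import RegionSpec

from conftest import make_sites


def test_site_level_worked_examples():
    assert methylome.site_level(3, 1) == 0.75
    assert np.isnan(methylome.site_level(0, 0))
    assert methylome.site_level(0, 5) == 0.0


def test_bin_track_symmetric_counts():
    sites = make_sites([
        ("c", 10, "+", 3, 1, "CAA"),
        ("c", 20, "+", 1, 3, "CAA"),
    ])
    track = methylome.bin_track(sites, {"c": 100}, bin_size=100)
    row = track.data[(track.data["subcontext"] == "CAA")].iloc[0]
    assert row["level_pooled"] == pytest.approx(0.5)
    assert row["level_site_mean"] == pytest.approx(0.5)


def test_bin_track_estimator_divergence():
    """Pooled weighs calls; site_mean weighs sites: (3,1)+(0,5)."""
    sites = make_sites([
        ("c", 10, "+", 3, 1, "CAA"),
        ("c", 20, "+", 0, 5, "CAA"),
    ])
    track = methylome.bin_track(sites, {"c": 100}, bin_size=100)
    row = track.data[(track.data["subcontext"] == "CAA")].iloc[0]
    assert row["level_pooled"] == pytest.approx(3 / 9)
    assert row["level_site_mean"] == pytest.approx(0.375)


def test_bin_track_rejects_bad_bin_size():
    with pytest.raises(ValueError):
        methylome.bin_track(make_sites([]), {"c": 10}, bin_size=0)


def test_bin_track_count_conservation(rng):
    """Sum of per-bin total calls equals total input coverage (min_depth=1)."""
    n = 100_000
    sites = pd.DataFrame({
        "contig": "c", "pos": np.arange(1, n + 1), "strand": "+",
        "n_meth": rng.integers(0, 4, n), "n_unmeth": rng.integers(0, 4, n),
        "context": "CHH",
        "subcontext": rng.choice(["CAA", "CTA", "CCC"], n),
    })
    track = methylome.bin_track(sites, {"c": n}, bin_size=7919)
    assert track.data["n_total_calls"].sum() == (
        sites["n_meth"].sum() + sites["n_unmeth"].sum()
    )
    assert track.data["n_sites"].sum() == ((sites["n_meth"] + sites["n_unmeth"]) > 0).sum()
    # bins tile the contig contiguously
    bins = track.data[["bin_start", "bin_end"]].drop_duplicates().sort_values("bin_start")
    assert (bins["bin_start"].iloc[1:].to_numpy()
            == bins["bin_end"].iloc[:-1].to_numpy()).all()


def test_pooled_invariant_to_splitting_site_records():
    """Splitting a site's calls into duplicates preserves pooled but not
    site_mean."""
    whole = make_sites([("c", 10, "+", 4, 0, "CAA"), ("c", 20, "+", 1, 3, "CAA")])
    split = make_sites([
        ("c", 10, "+", 2, 0, "CAA"), ("c", 10, "+", 2, 0, "CAA"),
        ("c", 20, "+", 1, 3, "CAA"),
    ])
    t1 = methylome.bin_track(whole, {"c": 100}, 100)
    t2 = methylome.bin_track(split, {"c": 100}, 100)
    r1 = t1.data[t1.data["subcontext"] == "CAA"].iloc[0]
    r2 = t2.data[t2.data["subcontext"] == "CAA"].iloc[0]
    assert r1["level_pooled"] == pytest.approx(r2["level_pooled"])
    assert r1["level_site_mean"] != pytest.approx(r2["level_site_mean"])


def test_min_depth_monotonicity(rng):
    n = 2000
    sites = pd.DataFrame({
        "contig": "c", "pos": np.arange(1, n + 1), "strand": "+",
        "n_meth": rng.poisson(2, n), "n_unmeth": rng.poisson(2, n),
        "context": "CHH", "subcontext": "CAA",
    })
    n_sites = [
        methylome.bin_track(sites, {"c": n}, n, min_depth=d).data["n_sites"].sum()
        for d in (1, 2, 4, 8)
    ]
    assert n_sites == sorted(n_sites, reverse=True)


def test_region_level_consistent_with_bin():
    sites = make_sites([
        ("c", 10, "+", 3, 1, "CAA"),
        ("c", 20, "+", 0, 4, "CAA"),
    ])
    track = methylome.bin_track(sites, {"c": 100}, 100)
    regions = RegionSpec({"all": [("c", 0, 100)]})
    rl = methylome.region_level(sites, regions)
    row = rl[(rl["key"] == "CAA") & (rl["kind"] == "subcontext")].iloc[0]
    bin_row = track.data[track.data["subcontext"] == "CAA"].iloc[0]
    assert row["level_pooled"] == pytest.approx(bin_row["level_pooled"])
    assert row["level_site_mean"] == pytest.approx(bin_row["level_site_mean"])


def test_region_level_disjoint_union_equals_concatenation(rng):
    n = 3000
    sites = pd.DataFrame({
        "contig": "c", "pos": np.arange(1, n + 1), "strand": "+",
        "n_meth": rng.integers(0, 5, n), "n_unmeth": rng.integers(0, 5, n),
        "context": "CHH", "subcontext": rng.choice(["CAA", "CCC"], n),
    })
    union = RegionSpec({"u": [("c", 0, 1000), ("c", 2000, 3000)]})
    rl = methylome.region_level(sites, union)
    # oracle: concatenate the two pieces and recompute pooled by hand
    piece = sites[((sites["pos"] - 1 < 1000) | (sites["pos"] - 1 >= 2000))
                  & (sites["subcontext"] == "CAA")]
    piece = piece[(piece["n_meth"] + piece["n_unmeth"]) > 0]
    expected = piece["n_meth"].sum() / (piece["n_meth"] + piece["n_unmeth"]).sum()
    row = rl[(rl["key"] == "CAA") & (rl["kind"] == "subcontext")].iloc[0]
    assert row["level_pooled"] == pytest.approx(expected)


def test_class_aggregate_is_count_weighted_combination(rng):
    """The CHH class aggregate equals the count-weighted combination of its
    subcontext aggregates."""
    n = 2000
    sites = pd.DataFrame({
        "contig": "c", "pos": np.arange(1, n + 1), "strand": "+",
        "n_meth": rng.integers(0, 5, n), "n_unmeth": rng.integers(1, 5, n),
        "context": "CHH",
        "subcontext": rng.choice(["CAA", "CTA", "CCC"], n),
    })
    rl = methylome.region_level(sites, RegionSpec({"all": [("c", 0, n)]}))
    subs = rl[rl["kind"] == "subcontext"]
    cls = rl[(rl["kind"] == "class") & (rl["key"] == "CHH")].iloc[0]
    pooled = subs["n_meth_calls"].sum() / subs["n_total_calls"].sum()
    site_mean = (
        (subs["level_site_mean"] * subs["n_sites"]).sum() / subs["n_sites"].sum()
    )
    assert cls["level_pooled"] == pytest.approx(pooled)
    assert cls["level_site_mean"] == pytest.approx(site_mean)


def test_empty_region_warns():
    sites = make_sites([("c", 10, "+", 1, 1, "CAA")])
    with pytest.warns(UserWarning, match="no qualifying sites"):
        methylome.region_level(sites, RegionSpec({"empty": [("c", 50, 60)]}))


def test_overlapping_region_intervals_rejected():
    with pytest.raises(ValueError, match="overlapping"):
        RegionSpec({"r": [("c", 0, 100), ("c", 50, 150)]})


# ---------------------------------------------------------------------------
# per-site density


def test_per_site_density_fully_methylated_sites():
    sites = make_sites([("c", i, "+", 8, 0, "CAG") for i in range(1, 6)])
    dens = methylome.per_site_density(
        sites, RegionSpec({"all": [("c", 0, 100)]}), min_depth=8
    )
    top = dens[dens["bin_high"] == 1.0]
    assert top["count"].sum() == 5
    assert dens["count"].sum() == 5


def test_per_site_density_depth_filter_excludes_shallow_sites():
    sites = make_sites([
        ("c", 1, "+", 4, 3, "CAG"),  # depth 7 < 8
        ("c", 2, "+", 8, 0, "CAG"),
    ])
    dens = methylome.per_site_density(
        sites, RegionSpec({"all": [("c", 0, 100)]}), min_depth=8
    )
    assert dens["count"].sum() == 1


def test_bimodality_summary_masses():
    sites = make_sites(
        [("c", i, "+", 8, 0, "CAG") for i in range(1, 7)]
        + [("c", i, "+", 0, 8, "CAG") for i in range(10, 14)]
        + [("c", 20, "+", 4, 4, "CAG")]
    )
    dens = methylome.per_site_density(
        sites, RegionSpec({"all": [("c", 0, 100)]}), min_depth=8
    )
    summ = methylome.bimodality_summary(dens).iloc[0]
    assert summ["n_sites"] == 11
    assert summ["mass_high"] == pytest.approx(6 / 11)
    assert summ["mass_low"] == pytest.approx(4 / 11)
    assert summ["mass_mid"] == pytest.approx(1 / 11)


# ---------------------------------------------------------------------------
# conversion rate


def test_conversion_rate_worked_example():
    sites = make_sites([("pt", 1, "+", 5, 995, "CAA")])
    cr = methylome.conversion_rate(sites, "pt")
    assert cr.overall == pytest.approx(0.995)
    assert cr.n_calls == 1000


def test_conversion_rate_requires_control_sites():
    sites = make_sites([("chr1", 1, "+", 5, 5, "CAA")])
    with pytest.raises(ValueError, match="control"):
        methylome.conversion_rate(sites, "pt")


def test_correct_nonconversion_inverts_bias():
    true = np.array([0.0, 0.02, 0.375, 1.0])
    eps = 0.005
    observed = true + (1 - true) * eps
    back = methylome.correct_nonconversion(observed, eps)
    assert np.allclose(back, true)
    with pytest.raises(ValueError):
        methylome.correct_nonconversion(0.5, 1.5)
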