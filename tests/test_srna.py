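"""Small-RNA size profiles, normalization and differential test."""

import numpy as np
import pandas as pd
import pytest

from methylctx import simulate, srna
from methylctx.io import SrnaLocusTable


def _table(loci_rows, counts, conditions):
    loci = pd.DataFrame(
        loci_rows, columns=["locus_id", "contig", "start", "end", "size_class"]
    )
    counts = pd.DataFrame(counts, index=loci["locus_id"])
    return SrnaLocusTable(loci, counts, conditions)


# ---------------------------------------------------------------------------
# size profile


def test_size_profile_fractions():
    counts = pd.DataFrame({"s1": {21: 50, 24: 50}})
    prof = srna.size_profile(counts)
    assert np.allclose(prof["fraction"], 0.5)
    single = srna.size_profile(pd.DataFrame({"s": {24: 7}}))
    assert single["fraction"].iloc[0] == 1.0


def test_size_profile_rejects_empty_sample():
    with pytest.raises(ValueError, match="zero total"):
        srna.size_profile(pd.DataFrame({"s1": {21: 0, 24: 0}}))


def test_size_profile_recovers_simulated_24nt_loss():
    """An nrpd1-like sample (23-24-nt mass cut 90%) shows the expected
    24-nt fraction within multinomial sampling error."""
    config = simulate.arabidopsis_like(5, chrom_length=100_000)
    counts = simulate.simulate_size_counts(
        config, {"wt_1": 1.0, "nrpd1_1": 0.1}, n_reads=200_000
    )
    prof = srna.size_profile(counts)
    for sample, mult in (("wt_1", 1.0), ("nrpd1_1", 0.1)):
        frac = prof[(prof["sample"] == sample) & (prof["length"] == 24)][
            "fraction"].iloc[0]
        expected = simulate.expected_size_fraction(mult, 24)
        sd = np.sqrt(expected * (1 - expected) / 200_000)
        assert abs(frac - expected) < 4 * sd
    # the reduction is dramatic: wt ~44%, mutant <10%
    assert prof[(prof["sample"] == "nrpd1_1") & (prof["length"] == 24)][
        "fraction"].iloc[0] < 0.1


# ---------------------------------------------------------------------------
# size factors


def test_size_factors_proportional_samples():
    table = _table(
        [("l1", "c", 0, 10, "20-22"), ("l2", "c", 20, 30, "20-22")],
        {"a": [10, 30], "b": [20, 60]},
        {"a": "wt", "b": "mutant"},
    )
    f = srna.size_factors_from_small_loci(table)
    assert f["b"] / f["a"] == pytest.approx(2.0)


def test_size_factors_single_locus():
    table = _table([("l1", "c", 0, 10, "20-22")], {"a": [10], "b": [10]},
                   {"a": "wt", "b": "mutant"})
    f = srna.size_factors_from_small_loci(table)
    assert np.allclose(f, 1.0)


def brute_force_median_of_ratios(counts):
    """Oracle written independently of the implementation: loop over loci,
    geometric mean per locus, per-sample ratio, median."""
    import math
    ratios_per_sample = {s: [] for s in counts.columns}
    for _, row in counts.iterrows():
        if (row <= 0).any():
            continue
        geo = math.exp(sum(math.log(v) for v in row) / len(row))
        for s in counts.columns:
            ratios_per_sample[s].append(row[s] / geo)
    return {s: float(np.median(v)) for s, v in ratios_per_sample.items()}


def test_size_factors_match_brute_force_oracle(rng):
    counts = pd.DataFrame(
        rng.integers(1, 200, size=(5, 3)), columns=["s1", "s2", "s3"]
    )
    table = _table(
        [(f"l{i}", "c", i * 10, i * 10 + 5, "20-22") for i in range(5)],
        counts.to_dict("list"),
        {"s1": "wt", "s2": "wt", "s3": "mutant"},
    )
    f = srna.size_factors_from_small_loci(table)
    oracle = brute_force_median_of_ratios(counts)
    for s in counts.columns:
        assert f[s] == pytest.approx(oracle[s], rel=1e-12)


def test_size_factors_ignore_large_loci(rng):
    """Rescaling a 23-24-nt locus leaves factors unchanged."""
    small = [(f"s{i}", "c", i * 10, i * 10 + 5, "20-22") for i in range(4)]
    large = [("big", "c", 900, 950, "23-24")]
    counts = {"a": [10, 20, 30, 40, 5], "b": [12, 18, 33, 44, 5000]}
    t1 = _table(small + large, counts, {"a": "wt", "b": "mutant"})
    counts2 = dict(counts, b=[12, 18, 33, 44, 1])
    t2 = _table(small + large, counts2, {"a": "wt", "b": "mutant"})
    pd.testing.assert_series_equal(
        srna.size_factors_from_small_loci(t1),
        srna.size_factors_from_small_loci(t2),
    )


def test_size_factors_require_positive_locus():
    table = _table([("l1", "c", 0, 10, "20-22")], {"a": [0], "b": [10]},
                   {"a": "wt", "b": "mutant"})
    with pytest.raises(ValueError, match="pseudo-reference"):
        srna.size_factors_from_small_loci(table)


# ---------------------------------------------------------------------------
# BH adjustment


def test_bh_hand_checked_example():
    assert np.allclose(srna.bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])


def test_bh_edge_cases():
    assert srna.bh_adjust([0.2]) == pytest.approx([0.2])
    assert np.allclose(srna.bh_adjust([1.0, 1.0, 1.0]), 1.0)
    with pytest.raises(ValueError):
        srna.bh_adjust([1.5])


def test_bh_monotone_and_capped(rng):
    p = np.sort(rng.random(50))
    adj = srna.bh_adjust(p)
    assert (np.diff(adj) >= -1e-12).all()
    assert (adj <= 1.0).all()
    assert (adj >= p - 1e-12).all()


def test_bh_matches_statsmodels(rng):
    from statsmodels.stats.multitest import multipletests

    p = rng.random(200)
    _, expected, _, _ = multipletests(p, method="fdr_bh")
    assert np.allclose(srna.bh_adjust(p), expected)


# ---------------------------------------------------------------------------
# differential test


def test_extreme_locus_called_down():
    small = [(f"s{i}", "c", i * 10, i * 10 + 5, "20-22") for i in range(3)]
    large = [("dead", "c", 900, 950, "23-24")]
    counts = {
        "wt_1": [50, 60, 70, 100], "wt_2": [55, 58, 72, 100],
        "m_1": [50, 60, 70, 0], "m_2": [52, 61, 69, 0],
    }
    cond = {"wt_1": "wt", "wt_2": "wt", "m_1": "mutant", "m_2": "mutant"}
    table = _table(small + large, counts, cond)
    results, summary = srna.differential_loci(table)
    assert results.iloc[0]["call"] == "down"
    assert summary.frac_down == 1.0
    # adjusted p never smaller than raw p
    assert (results["p_adj"].dropna() >= results["p_value"].dropna() - 1e-12).all()


def test_differential_requires_two_conditions():
    table = _table([("l", "c", 0, 5, "23-24")], {"a": [5], "b": [5]},
                   {"a": "wt", "b": "wt"})
    with pytest.raises(ValueError, match="two conditions"):
        srna.differential_loci(table, factors=pd.Series([1.0, 1.0],
                                                        index=["a", "b"]))


def test_insufficient_count_filter_excludes_low_loci():
    small = [(f"s{i}", "c", i * 10, i * 10 + 5, "20-22") for i in range(3)]
    large = [("low", "c", 900, 950, "23-24"), ("ok", "c", 960, 990, "23-24")]
    counts = {
        "wt_1": [50, 60, 70, 1, 100], "wt_2": [50, 60, 70, 0, 100],
        "m_1": [50, 60, 70, 1, 90], "m_2": [50, 60, 70, 0, 110],
    }
    cond = {"wt_1": "wt", "wt_2": "wt", "m_1": "mutant", "m_2": "mutant"}
    results, summary = srna.differential_loci(_table(small + large, counts, cond))
    assert summary.n_tested == 1
    assert not results[results["locus_id"] == "low"]["tested"].iloc[0]


def test_single_replicate_uses_prior_and_flags():
    small = [("s0", "c", 0, 5, "20-22")]
    large = [("l0", "c", 900, 950, "23-24")]
    counts = {"wt_1": [50, 100], "m_1": [50, 100]}
    cond = {"wt_1": "wt", "m_1": "mutant"}
    results, summary = srna.differential_loci(_table(small + large, counts, cond))
    assert summary.single_replicate
    assert results["dispersion"].iloc[0] == srna.SINGLE_REPLICATE_DISPERSION


def test_null_simulation_is_calibrated():
    """With no true signal, BH keeps the significant fraction near zero
    (<= 0.07 allowing Monte-Carlo slack)."""
    plan = simulate.SrnaPlan(n_small_loci=100, n_large_loci=2000,
                             fraction_down=0.0)
    config = simulate.arabidopsis_like(17, chrom_length=100_000, srna=plan)
    table = simulate.simulate_srna_counts(config)
    results, summary = srna.differential_loci(table)
    frac_sig = (summary.n_down + summary.n_up) / summary.n_tested
    assert frac_sig <= 0.07


def test_recovery_of_down_fraction():
    """70% of 23-24-nt loci down 8-fold at n=2, NB dispersion 0.2:
    the recovered down fraction lands within 5 points."""
    plan = simulate.SrnaPlan(n_small_loci=200, n_large_loci=1000,
                             fraction_down=0.70, fold_change=8.0)
    config = simulate.arabidopsis_like(23, chrom_length=100_000, srna=plan)
    table = simulate.simulate_srna_counts(config)
    results, summary = srna.differential_loci(table)
    assert abs(summary.frac_down - 0.70) < 0.05
    # called-down loci overwhelmingly belong to the true down set
    called = set(results.loc[results["call"] == "down", "locus_id"])
    assert len(called - table.true_down) / max(len(called), 1) < 0.05
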