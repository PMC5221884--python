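#!/usr/bin/env python
"""Small-RNA locus differential analysis.

For each simulated mutant table (Pol IV-like with 72% of 23-24-nt loci
down-regulated, Pol V-like with 13%): compute median-of-ratios size factors
from the 20-22-nt loci, test the 23-24-nt loci with the negative-binomial
Wald test, BH-adjust, and report the fractions called down/up at adjusted
p < 0.05 among loci with sufficient counts.
"""

from pathlib import Path

from methylctx import simulate, srna
from methylctx.io import read_srna_table

DATA = Path(__file__).resolve().parent.parent / "results" / "synthetic"
OUT = DATA.parent / "srna"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    for label, configured_down in (("nrpd1", 0.72), ("nrpe1", 0.13)):
        conditions = {f"wt_{i}": "wt" for i in (1, 2)}
        conditions.update({f"{label}_{i}": "mutant" for i in (1, 2)})
        table = read_srna_table(DATA / f"srna_counts_{label}.tsv", conditions)
        factors = srna.size_factors_from_small_loci(table)
        results, summary = srna.differential_loci(table, factors)
        results.to_csv(OUT / f"differential_{label}.tsv", sep="\t",
                       index=False)
        print(f"{label}: size factors "
              + ", ".join(f"{s}={v:.2f}" for s, v in factors.items()))
        print(f"  {summary.n_tested} loci tested: "
              f"{summary.frac_down:.1%} down (configured "
              f"{configured_down:.0%}), {summary.frac_up:.2%} up, "
              f"{summary.frac_ns:.1%} unchanged")

    counts = simulate.simulate_size_counts(
        simulate.arabidopsis_like(2024, chrom_length=100_000),
        {"wt_1": 1.0, "wt_2": 1.0, "nrpd1_1": 0.1, "nrpe1_1": 1.0},
    )
    prof = srna.size_profile(counts)
    prof.to_csv(OUT / "size_profile.tsv", sep="\t", index=False)
    frac24 = prof[prof["length"] == 24].set_index("sample")["fraction"]
    print("\n24-nt read fraction per sample: "
          + ", ".join(f"{s}={v:.1%}" for s, v in frac24.items()))
    print("(dramatic 24-nt collapse in the Pol IV-like mutant only)")
    print(f"tables in {OUT}")


if __name__ == "__main__":
    main()
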