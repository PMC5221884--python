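#!/usr/bin/env python
"""Generate the synthetic study dataset.

Builds the A. thaliana-like methylome preset — a 2-Mb chromosome whose
central 20% is pericentric heterochromatin, an unmethylated control contig,
transposon and gene annotations — and writes cytosine reports for the wild
type and the two mutant genotypes (cmt2-like, nrpe1-like), plus the
small-RNA locus count tables for Pol IV-like and Pol V-like mutants.

Outputs land in results/synthetic/.
"""

from pathlib import Path

import yaml

from methylctx import simulate
from methylctx.io import (
    frame_to_sites,
    write_cx_report,
    write_fasta,
    write_features_bed,
    write_srna_table,
)

SEED = 2024
OUT = Path(__file__).resolve().parent.parent / "results" / "synthetic"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    config = simulate.arabidopsis_like(SEED)
    genome, features, regions = simulate.simulate_genome(config)
    write_fasta(genome, OUT / "genome.fa")
    write_features_bed(features, OUT / "features.bed")
    with open(OUT / "regions.yaml", "w") as fh:
        yaml.safe_dump({name: [list(iv) for iv in ivs]
                        for name, ivs in regions.regions.items()}, fh)

    for genotype in ("wt", "cmt2", "nrpe1"):
        sites = simulate.simulate_methylome(genome, features, config, genotype)
        write_cx_report(frame_to_sites(sites), OUT / f"cx_{genotype}.txt")
        print(f"{genotype}: {len(sites):,} cytosines "
              f"(mean coverage {config.coverage_lambda})")

    for frac_down, label in ((0.72, "nrpd1"), (0.13, "nrpe1")):
        plan = simulate.SrnaPlan(fraction_down=frac_down)
        cfg = simulate.arabidopsis_like(SEED, chrom_length=100_000, srna=plan)
        table = simulate.simulate_srna_counts(cfg, mutant_label=label)
        write_srna_table(table, OUT / f"srna_counts_{label}.tsv")
        print(f"sRNA table {label}: {len(table.loci)} loci, "
              f"{frac_down:.0%} of 23-24-nt loci down-regulated")
    print(f"dataset written to {OUT}")


if __name__ == "__main__":
    main()
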