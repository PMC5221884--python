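import numpy as np
import pandas as pd
import pytest

from methylctx import simulate
from methylctx.io import GenomeSequence


def make_sites(rows):
    """CX-style site DataFrame from (contig, pos, strand, n_meth, n_unmeth,
    subcontext) tuples."""
    from methylctx.context import CONTEXT_CLASS

    df = pd.DataFrame(
        rows, columns=["contig", "pos", "strand", "n_meth", "n_unmeth",
                       "subcontext"]
    )
    df["context"] = df["subcontext"].map(CONTEXT_CLASS)
    return df[["contig", "pos", "strand", "n_meth", "n_unmeth", "context",
               "subcontext"]]


def random_genome(rng, length, gc=0.4, alphabet="ACGT"):
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list(alphabet), size=length, p=probs))


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture(scope="session")
def ath_small():
    """Small A. thaliana-like simulated dataset (wt only) for unit tests."""
    config = simulate.arabidopsis_like(11, chrom_length=400_000,
                                       control_length=40_000)
    genome, features, regions = simulate.simulate_genome(config)
    sites = simulate.simulate_methylome(genome, features, config, "wt")
    return {"config": config, "genome": genome, "features": features,
            "regions": regions, "sites": sites}


@pytest.fixture(scope="session")
def ath_full():
    """Desk-scale study conditions: 2-Mb chromosome, coverage 10, three
    genotypes. Shared by the parameter-recovery acceptance tests."""
    config = simulate.arabidopsis_like(101)
    genome, features, regions = simulate.simulate_genome(config)
    sites = {
        g: simulate.simulate_methylome(genome, features, config, g)
        for g in ("wt", "cmt2", "nrpe1")
    }
    return {"config": config, "genome": genome, "features": features,
            "regions": regions, "sites": sites}
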