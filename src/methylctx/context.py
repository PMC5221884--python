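"""Strand-aware trinucleotide subcontext classification.

Every cytosine in a genome belongs to one of 16 trinucleotide subcontexts:
the 3-mer starting at the C and reading 5'->3' on the cytosine's own strand.
The classical context classes partition these as

* CG  (4): CGA, CGT, CGC, CGG        — third base after the CG dyad
* CHG (3): CAG, CTG, CCG             — H is A, C or T
* CHH (9): C + {A,C,T} + {A,C,T}

A 3-mer containing N, or running off the contig end, is unclassifiable and
excluded from all downstream tallies.
"""

from __future__ import annotations

from collections.abc import Iterator
from typing import NamedTuple

import numpy as np
import pandas as pd

from .io import FeatureRecord, GenomeSequence

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

CG_SUBCONTEXTS = ("CGA", "CGT", "CGC", "CGG")
CHG_SUBCONTEXTS = ("CAG", "CTG", "CCG")
CHH_SUBCONTEXTS = ("CAA", "CAT", "CAC", "CTA", "CTT", "CTC", "CCA", "CCT", "CCC")
SUBCONTEXTS: tuple[str, ...] = CG_SUBCONTEXTS + CHG_SUBCONTEXTS + CHH_SUBCONTEXTS

CONTEXT_CLASS: dict[str, str] = {}
for _k in CG_SUBCONTEXTS:
    CONTEXT_CLASS[_k] = "CG"
for _k in CHG_SUBCONTEXTS:
    CONTEXT_CLASS[_k] = "CHG"
for _k in CHH_SUBCONTEXTS:
    CONTEXT_CLASS[_k] = "CHH"


def context_class(subcontext: str) -> str:
    """Context class (CG/CHG/CHH) of a trinucleotide subcontext."""
    try:
        return CONTEXT_CLASS[subcontext]
    except KeyError:
        raise ValueError(f"not a cytosine subcontext: {subcontext!r}") from None


def reverse_complement(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


class CytosinePosition(NamedTuple):
    contig: str
    pos: int  # 1-based
    strand: str
    subcontext: str


def classify_site(
    genome: GenomeSequence, contig: str, pos_1based: int, strand: str
) -> str | None:
    """Subcontext of the cytosine at ``pos_1based`` on ``strand``.

    On the + strand this is the top-strand 3-mer starting at the position; on
    the - strand it is the reverse complement of the top-strand 3-mer ending
    at the position. Returns ``None`` when the 3-mer contains an N or runs
    off the contig end.

    Raises
    ------
    ValueError
        If the base at the position on the requested strand is not a cytosine
        (i.e. top-strand C for +, top-strand G for -).
    """
    seq = genome.contigs[contig]
    i = pos_1based - 1
    if not 0 <= i < len(seq):
        raise ValueError(f"position {pos_1based} outside contig {contig}")
    if strand == "+":
        if seq[i] != "C":
            raise ValueError(f"not a cytosine: {contig}:{pos_1based}:{strand}")
        tri = seq[i : i + 3]
    elif strand == "-":
        if seq[i] != "G":
            raise ValueError(f"not a cytosine: {contig}:{pos_1based}:{strand}")
        if i < 2:
            return None
        tri = reverse_complement(seq[i - 2 : i + 1])
    else:
        raise ValueError(f"invalid strand {strand!r}")
    if len(tri) < 3 or "N" in tri:
        return None
    return tri


# Base encoding used by the vectorised scan: A=0, C=1, G=2, T=3, other=4.
_BASE_CODE = np.full(256, 4, dtype=np.int8)
for _b, _c in zip(b"ACGT", range(4)):
    _BASE_CODE[_b] = _c

_TRI_BY_CODE = np.array(
    ["".join(("ACGT"[a], "ACGT"[b], "ACGT"[c]))
     for a in range(4) for b in range(4) for c in range(4)],
    dtype=object,
)


def _contig_site_table(name: str, seq: str) -> pd.DataFrame:
    """All classifiable cytosines of one contig, both strands, as a table."""
    codes = _BASE_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    n = codes.size
    out = []

    # + strand: C at i with full 3-mer i..i+2
    plus = np.flatnonzero(codes[: max(n - 2, 0)] == 1)
    if plus.size:
        c0, c1, c2 = codes[plus], codes[plus + 1], codes[plus + 2]
        ok = (c1 < 4) & (c2 < 4)
        plus = plus[ok]
        tri_code = 16 + 4 * c1[ok] + c2[ok]  # first base is C (=1)
        out.append((plus + 1, "+", tri_code))

    # - strand: G at i; 3-mer is revcomp of top strand i-2..i
    minus = np.flatnonzero(codes == 2)
    minus = minus[minus >= 2]
    if minus.size:
        c1, c2 = codes[minus - 1], codes[minus - 2]
        ok = (c1 < 4) & (c2 < 4)
        minus = minus[ok]
        # complement of code for ACGT is 3 - code
        tri_code = 16 + 4 * (3 - c1[ok]) + (3 - c2[ok])
        out.append((minus + 1, "-", tri_code))

    if not out:
        return pd.DataFrame(
            {"contig": pd.Series(dtype=object), "pos": pd.Series(dtype=np.int64),
             "strand": pd.Series(dtype=object), "subcontext": pd.Series(dtype=object)}
        )

    pos = np.concatenate([o[0] for o in out])
    strand = np.concatenate([np.full(o[0].size, o[1], dtype=object) for o in out])
    tri = _TRI_BY_CODE[np.concatenate([o[2] for o in out])]
    # order by position, + before - at the same position
    order = np.lexsort((strand == "-", pos))
    return pd.DataFrame(
        {"contig": name, "pos": pos[order].astype(np.int64),
         "strand": strand[order], "subcontext": tri[order]}
    )


def cytosine_table(genome: GenomeSequence) -> pd.DataFrame:
    """DataFrame of every classifiable cytosine on both strands.

    Columns: contig, pos (1-based), strand, subcontext, context (class).
    Ordered by (contig in genome order, pos, + before -).
    """
    parts = [_contig_site_table(name, seq) for name, seq in genome.contigs.items()]
    df = pd.concat(parts, ignore_index=True) if parts else _contig_site_table("", "")
    df["context"] = df["subcontext"].map(CONTEXT_CLASS)
    return df


def enumerate_cytosines(genome: GenomeSequence) -> Iterator[CytosinePosition]:
    """Yield every classifiable cytosine as (contig, pos, strand, subcontext)."""
    df = cytosine_table(genome)
    for row in df.itertuples(index=False):
        yield CytosinePosition(row.contig, int(row.pos), row.strand, row.subcontext)


def motif_density(
    genome: GenomeSequence,
    bin_size: int,
    regions: list[FeatureRecord] | None = None,
) -> pd.DataFrame:
    """Occurrence counts and per-kb densities of each subcontext motif.

    Counts motifs on both strands (each classifiable cytosine is one motif
    occurrence), serving as the control that subcontext methylation biases
    are not explained by motif abundance.

    Without ``regions``: one row per (contig, bin_start, subcontext) with
    ``count`` and ``per_kb``. With ``regions``: counts aggregated per
    feature_type over the supplied intervals, with per-kb densities relative
    to the total interval length of each class.
    """
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    sites = cytosine_table(genome)

    if regions is None:
        sites["bin_start"] = (sites["pos"] - 1) // bin_size * bin_size
        counts = (
            sites.groupby(["contig", "bin_start", "subcontext"], sort=True)
            .size().rename("count").reset_index()
        )
        def _width(row):
            length = genome.lengths[row["contig"]]
            return min(bin_size, length - row["bin_start"])
        counts["per_kb"] = counts["count"] / (counts.apply(_width, axis=1) / 1000.0)
        return counts

    rows = []
    for ftype in sorted({f.feature_type for f in regions}):
        feats = [f for f in regions if f.feature_type == ftype]
        total_bp = sum(f.end - f.start for f in feats)
        mask = np.zeros(len(sites), dtype=bool)
        for f in feats:
            mask |= (
                (sites["contig"] == f.contig).to_numpy()
                & (sites["pos"].to_numpy() - 1 >= f.start)
                & (sites["pos"].to_numpy() - 1 < f.end)
            )
        sub = sites[mask].groupby("subcontext").size()
        for key in SUBCONTEXTS:
            c = int(sub.get(key, 0))
            rows.append(
                {"feature_type": ftype, "subcontext": key, "count": c,
                 "per_kb": c / (total_bp / 1000.0) if total_bp else np.nan}
            )
    return pd.DataFrame(rows)
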