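"""Readers and writers for the formats the pipeline touches.

Internal coordinate convention is 0-based half-open for all intervals.
``CytosineSite`` keeps the cytosine report's 1-based position, converted at
the boundary wherever intervals are involved. Contig names are matched by
exact string equality; an alias map handles "Chr1" vs "chr1" style drift.
"""

from __future__ import annotations

import gzip
import warnings
from collections.abc import Iterable, Iterator, Mapping
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO

import numpy as np
import pandas as pd
from Bio import SeqIO

VALID_BASES = set("ACGTN")
CX_COLUMNS = ["contig", "pos", "strand", "n_meth", "n_unmeth", "context", "subcontext"]


class FormatError(ValueError):
    """A file does not conform to its declared format."""


@dataclass
class GenomeSequence:
    """Ordered contig name -> uppercase nucleotide string (A,C,G,T,N)."""

    contigs: dict[str, str]

    def __post_init__(self) -> None:
        for name, seq in self.contigs.items():
            bad = set(seq) - VALID_BASES
            if bad:
                raise FormatError(
                    f"contig {name!r} contains illegal characters: {sorted(bad)}"
                )

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.contigs.items()}


@dataclass(frozen=True)
class CytosineSite:
    """One cytosine: 1-based position on its contig, strand, call counts."""

    contig: str
    pos: int
    strand: str
    n_meth: int
    n_unmeth: int
    context_class: str
    subcontext: str

    @property
    def coverage(self) -> int:
        return self.n_meth + self.n_unmeth


@dataclass(frozen=True)
class FeatureRecord:
    """Genomic feature with a 0-based half-open interval.

    ``strand`` "." is treated as "+" for orientation purposes.
    """

    contig: str
    start: int
    end: int
    strand: str = "+"
    feature_type: str = "other"
    family: str | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty interval [{self.start}, {self.end})")

    @property
    def orientation(self) -> str:
        return "-" if self.strand == "-" else "+"

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class SrnaLocusTable:
    """Small-RNA loci with per-sample counts and condition labels.

    loci: DataFrame with columns locus_id, contig, start, end, size_class
          (size_class in {"20-22", "23-24"}).
    counts: DataFrame indexed by locus_id, one integer column per sample.
    conditions: sample name -> condition label (e.g. "wt" / "mutant").
    """

    loci: pd.DataFrame
    counts: pd.DataFrame
    conditions: dict[str, str]

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        bad = set(self.loci["size_class"]) - {"20-22", "23-24"}
        if bad:
            raise ValueError(f"unknown size classes: {sorted(bad)}")
        missing = set(self.counts.columns) - set(self.conditions)
        if missing:
            raise ValueError(f"samples without condition: {sorted(missing)}")

    def subset(self, size_class: str) -> "SrnaLocusTable":
        loci = self.loci[self.loci["size_class"] == size_class]
        return SrnaLocusTable(
            loci.reset_index(drop=True),
            self.counts.loc[loci["locus_id"]],
            self.conditions,
        )


def _open_text(path: str | Path, mode: str = "rt") -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def apply_aliases(name: str, aliases: Mapping[str, str] | None) -> str:
    return aliases.get(name, name) if aliases else name


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> GenomeSequence:
    """Read a (optionally gzipped) FASTA file; sequences are uppercased."""
    contigs: dict[str, str] = {}
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            if rec.id in contigs:
                raise FormatError(f"duplicate contig name {rec.id!r}")
            seq = str(rec.seq).upper()
            bad = set(seq) - VALID_BASES
            if bad:
                raise FormatError(
                    f"illegal character(s) {sorted(bad)} in contig {rec.id!r}"
                )
            contigs[rec.id] = seq
    if not contigs:
        raise FormatError(f"no sequences in {path}")
    return GenomeSequence(contigs)


def write_fasta(genome: GenomeSequence, path: str | Path, width: int = 70) -> None:
    with _open_text(path, "wt") as fh:
        for name, seq in genome.contigs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Bismark-style genome-wide cytosine report (CX), 7 tab-separated columns:
# contig, 1-based position, strand, count methylated, count unmethylated,
# context class, trinucleotide.


def read_cx_report(
    path: str | Path,
    genome: GenomeSequence | None = None,
    aliases: Mapping[str, str] | None = None,
) -> Iterator[CytosineSite]:
    """Stream cytosine sites from a CX report, optionally validated.

    When ``genome`` is supplied, each site's trinucleotide is cross-checked
    against the strand-aware reference 3-mer; the first mismatch raises a
    ``FormatError`` naming the line.
    """
    from .context import classify_site  # local import: io must not cycle at import

    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 7:
                raise FormatError(
                    f"{path}:{lineno}: expected 7 columns, got {len(fields)}"
                )
            contig, pos_s, strand, nm_s, nu_s, ctx, sub = fields
            contig = apply_aliases(contig, aliases)
            try:
                pos, n_meth, n_unmeth = int(pos_s), int(nm_s), int(nu_s)
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-integer field") from None
            if n_meth < 0 or n_unmeth < 0:
                raise ValueError(f"{path}:{lineno}: negative count")
            if strand not in "+-":
                raise FormatError(f"{path}:{lineno}: bad strand {strand!r}")
            if genome is not None:
                expected = classify_site(genome, contig, pos, strand)
                if expected != sub:
                    raise FormatError(
                        f"{path}:{lineno}: trinucleotide {sub!r} does not match "
                        f"reference ({expected!r}) at {contig}:{pos}:{strand}"
                    )
            yield CytosineSite(contig, pos, strand, n_meth, n_unmeth, ctx, sub)


def write_cx_report(sites: Iterable[CytosineSite], path: str | Path) -> None:
    """Write sites in the 7-column CX dialect; input must be sorted.

    Sort order: contig blocks must not interleave; within a contig positions
    ascend with + before - at equal positions.
    """
    seen: list[str] = []
    prev_key: tuple[int, int] | None = None
    with _open_text(path, "wt") as fh:
        for s in sites:
            if not seen or s.contig != seen[-1]:
                if s.contig in seen:
                    raise ValueError(f"interleaved contig blocks at {s.contig!r}")
                seen.append(s.contig)
                prev_key = None
            key = (s.pos, 0 if s.strand == "+" else 1)
            if prev_key is not None and key < prev_key:
                raise ValueError(
                    f"unsorted sites at {s.contig}:{s.pos}:{s.strand}"
                )
            prev_key = key
            fh.write(
                f"{s.contig}\t{s.pos}\t{s.strand}\t{s.n_meth}\t{s.n_unmeth}"
                f"\t{s.context_class}\t{s.subcontext}\n"
            )


def load_cx_report(
    path: str | Path, aliases: Mapping[str, str] | None = None
) -> pd.DataFrame:
    """Load a whole CX report as a DataFrame (bulk counterpart of the stream).

    Columns: contig, pos, strand, n_meth, n_unmeth, context, subcontext.
    """
    df = pd.read_csv(
        path, sep="\t", header=None, names=CX_COLUMNS,
        dtype={"contig": str, "pos": np.int64, "strand": str,
               "n_meth": np.int64, "n_unmeth": np.int64,
               "context": str, "subcontext": str},
    )
    if (df[["n_meth", "n_unmeth"]].to_numpy() < 0).any():
        raise ValueError(f"{path}: negative counts")
    if aliases:
        df["contig"] = df["contig"].map(lambda c: apply_aliases(c, aliases))
    return df


def sites_to_frame(sites: Iterable[CytosineSite]) -> pd.DataFrame:
    rows = [(s.contig, s.pos, s.strand, s.n_meth, s.n_unmeth, s.context_class,
             s.subcontext) for s in sites]
    return pd.DataFrame(rows, columns=CX_COLUMNS)


def frame_to_sites(df: pd.DataFrame) -> Iterator[CytosineSite]:
    for row in df.itertuples(index=False):
        yield CytosineSite(row.contig, int(row.pos), row.strand,
                           int(row.n_meth), int(row.n_unmeth),
                           row.context, row.subcontext)


# ---------------------------------------------------------------------------
# Feature annotations (BED6 / GFF3)

_GFF_TRANSPOSON_TYPES = {
    "transposable_element", "transposon", "repeat_region",
    "transposable_element_gene", "transposon_fragment", "LTR_retrotransposon",
}


def read_features(
    path: str | Path,
    format: str,
    feature_type: str | None = None,
    aliases: Mapping[str, str] | None = None,
) -> list[FeatureRecord]:
    """Read BED6 or GFF3 features into 0-based half-open records.

    BED is 0-based half-open already; GFF3 start/end (1-based inclusive) are
    converted. The BED name column becomes ``family``; ``feature_type``, if
    given, overrides type inference. Invalid records are dropped with a
    single summary warning.
    """
    fmt = format.upper()
    if fmt not in {"BED", "GFF3"}:
        raise ValueError(f"unknown annotation format {format!r}")
    records: list[FeatureRecord] = []
    n_bad = 0
    with _open_text(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("track"):
                continue
            f = line.split("\t")
            try:
                if fmt == "BED":
                    contig, start, end = f[0], int(f[1]), int(f[2])
                    family = f[3] if len(f) > 3 and f[3] not in (".", "") else None
                    strand = f[5] if len(f) > 5 else "."
                    ftype = feature_type or "transposon"
                else:
                    if len(f) < 8:
                        raise ValueError("short GFF3 line")
                    contig, source, gff_type = f[0], f[1], f[2]
                    start, end = int(f[3]) - 1, int(f[4])
                    strand = f[6]
                    if feature_type:
                        ftype = feature_type
                    elif gff_type == "gene":
                        ftype = "gene"
                    elif gff_type in _GFF_TRANSPOSON_TYPES:
                        ftype = "transposon"
                    else:
                        ftype = "other"
                    family = None
                    if len(f) > 8:
                        attrs = dict(
                            kv.split("=", 1) for kv in f[8].split(";") if "=" in kv
                        )
                        family = attrs.get("family") or attrs.get("Alias")
                records.append(
                    FeatureRecord(apply_aliases(contig, aliases), start, end,
                                  strand, ftype, family)
                )
            except (ValueError, IndexError):
                n_bad += 1
    if n_bad:
        warnings.warn(f"{path}: dropped {n_bad} invalid record(s)", stacklevel=2)
    return records


def write_features_bed(features: Iterable[FeatureRecord], path: str | Path) -> None:
    with _open_text(path, "wt") as fh:
        for f in features:
            name = f.family if f.family else f.feature_type
            fh.write(f"{f.contig}\t{f.start}\t{f.end}\t{name}\t.\t{f.strand}\n")


# ---------------------------------------------------------------------------
# bedGraph output of binned tracks


def write_bedgraph(
    track,
    subcontext: str,
    path: str | Path,
    drop_missing: bool = False,
    header_lines: Iterable[str] = (),
) -> None:
    """Write one subcontext's binned levels as 4-column bedGraph.

    Bins with no informative site are written with ``nan`` unless
    ``drop_missing`` — "no data" is distinct from 0% methylation.
    """
    from .context import SUBCONTEXTS

    if subcontext not in SUBCONTEXTS:
        raise ValueError(f"unknown subcontext {subcontext!r}")
    df = track.data
    sel = df[df["subcontext"] == subcontext]
    with _open_text(path, "wt") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write(f'track type=bedGraph name="{subcontext}"\n')
        for row in sel.itertuples(index=False):
            level = row.level
            if np.isnan(level) and drop_missing:
                continue
            text = "nan" if np.isnan(level) else f"{level:.6g}"
            fh.write(f"{row.contig}\t{row.bin_start}\t{row.bin_end}\t{text}\n")


# ---------------------------------------------------------------------------
# sRNA locus count tables (tab-delimited, one header line)


def read_srna_table(
    path: str | Path, conditions: Mapping[str, str]
) -> SrnaLocusTable:
    """Read a locus table: locus_id, contig, start, end, size_class, <samples...>."""
    df = pd.read_csv(path, sep="\t")
    required = ["locus_id", "contig", "start", "end", "size_class"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    samples = [c for c in df.columns if c not in required]
    if not samples:
        raise FormatError(f"{path}: no sample count columns")
    counts = df[samples].astype(np.int64)
    counts.index = df["locus_id"]
    return SrnaLocusTable(df[required].copy(), counts, dict(conditions))


def write_srna_table(table: SrnaLocusTable, path: str | Path) -> None:
    out = table.loci.merge(
        table.counts, left_on="locus_id", right_index=True, how="left"
    )
    out.to_csv(path, sep="\t", index=False)
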