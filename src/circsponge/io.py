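"""Plain-text format readers and writers used throughout the pipeline.

All genomic coordinates are 0-based half-open (BED convention) in memory;
1-based coordinates appear only in human-readable reports.  Every writer in
this module is paired with a reader such that write -> read is the identity
on the record level.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


class FormatError(ValueError):
    """A file does not conform to its declared format; message names the line."""


# ---------------------------------------------------------------------------
# core record types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExonModel:
    """Exon structure of one transcript.

    ``exons`` is a list of ``(start, end)`` intervals, 0-based half-open,
    sorted by start and non-overlapping.  ``strand`` is ``"+"`` or ``"-"``.
    """

    gene_id: str
    tx_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r} for {self.tx_id}")
        prev_end = -1
        for start, end in self.exons:
            if end <= start:
                raise ValueError(f"{self.tx_id}: exon end {end} <= start {start}")
            if start < prev_end:
                raise ValueError(f"{self.tx_id}: exons unsorted or overlapping")
            prev_end = end

    @property
    def tx_start(self) -> int:
        return self.exons[0][0]

    @property
    def tx_end(self) -> int:
        return self.exons[-1][1]

    @property
    def n_exons(self) -> int:
        return len(self.exons)


@dataclass(frozen=True)
class SampleMeta:
    """Per-sample metadata: group label, cell background and mapping stats."""

    sample_id: str
    group: str        # "resistant" | "sensitive"
    background: str   # cell-line background, e.g. "MCF" | "MDA"
    total_mapped_reads: int
    read_length: int

    def __post_init__(self) -> None:
        if self.group not in ("resistant", "sensitive"):
            raise ValueError(f"unknown group {self.group!r} for {self.sample_id}")
        if self.total_mapped_reads <= 0:
            raise ValueError(f"{self.sample_id}: total_mapped_reads must be > 0")
        if self.read_length <= 0:
            raise ValueError(f"{self.sample_id}: read_length must be > 0")


@dataclass(frozen=True)
class GeneSet:
    """A named gene set (one GMT row)."""

    set_id: str
    name: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"gene set {self.set_id} is empty")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into ``{id: uppercase sequence}`` (order preserved)."""
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seqs[rec.id] = str(rec.seq).upper()
    return seqs


def write_fasta(path: str | Path, seqs: Mapping[str, str], width: int = 70) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# refFlat annotation
# ---------------------------------------------------------------------------

_REFFLAT_COLS = 11  # geneName txName chrom strand txStart txEnd cdsStart cdsEnd exonCount exonStarts exonEnds


def read_refflat(path: str | Path) -> list[ExonModel]:
    """Parse refFlat exon models.

    Raises :class:`FormatError` (naming the line) when the exon count does not
    match the exon start/end lists or coordinates are malformed.
    """
    models: list[ExonModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != _REFFLAT_COLS:
                raise FormatError(f"{path}:{lineno}: expected {_REFFLAT_COLS} columns, got {len(parts)}")
            gene, tx, chrom, strand = parts[0], parts[1], parts[2], parts[3]
            try:
                n_exons = int(parts[8])
                starts = [int(x) for x in parts[9].rstrip(",").split(",")]
                ends = [int(x) for x in parts[10].rstrip(",").split(",")]
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            if len(starts) != n_exons or len(ends) != n_exons:
                raise FormatError(
                    f"{path}:{lineno}: exonCount {n_exons} does not match "
                    f"{len(starts)} starts / {len(ends)} ends"
                )
            try:
                model = ExonModel(gene, tx, chrom, strand, tuple(zip(starts, ends)))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            models.append(model)
    return models


def write_refflat(path: str | Path, models: Iterable[ExonModel]) -> None:
    with open(path, "w") as fh:
        for m in models:
            starts = ",".join(str(s) for s, _ in m.exons) + ","
            ends = ",".join(str(e) for _, e in m.exons) + ","
            fh.write(
                "\t".join(
                    [m.gene_id, m.tx_id, m.chrom, m.strand,
                     str(m.tx_start), str(m.tx_end),
                     str(m.tx_start), str(m.tx_end),
                     str(m.n_exons), starts, ends]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# sample metadata
# ---------------------------------------------------------------------------

_SAMPLE_COLS = ["sample", "group", "background", "total_mapped_reads", "read_length"]


def read_samples(path: str | Path) -> list[SampleMeta]:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _SAMPLE_COLS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    out = []
    for _, row in df.iterrows():
        out.append(
            SampleMeta(
                sample_id=str(row["sample"]),
                group=str(row["group"]),
                background=str(row["background"]),
                total_mapped_reads=int(row["total_mapped_reads"]),
                read_length=int(row["read_length"]),
            )
        )
    return out


def write_samples(path: str | Path, samples: Iterable[SampleMeta]) -> None:
    rows = [
        {
            "sample": s.sample_id,
            "group": s.group,
            "background": s.background,
            "total_mapped_reads": s.total_mapped_reads,
            "read_length": s.read_length,
        }
        for s in samples
    ]
    pd.DataFrame(rows, columns=_SAMPLE_COLS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# count matrices and generic TSV tables
# ---------------------------------------------------------------------------

def read_tsv_matrix(path: str | Path) -> pd.DataFrame:
    """Read a feature x sample TSV matrix (first column = feature id).

    Missing cells are an error naming the offending row and column.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.isna().any().any():
        mask = df.isna()
        row = mask.any(axis=1).idxmax()
        col = mask.loc[row].idxmax()
        raise FormatError(f"{path}: missing value at row {row!r}, column {col!r}")
    return df


def write_tsv_matrix(path: str | Path, df: pd.DataFrame, index_label: str = "id") -> None:
    df.to_csv(path, sep="\t", index_label=index_label)


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> list[GeneSet]:
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: GMT rows need id, description and >=1 gene")
            sets.append(GeneSet(parts[0], parts[1], frozenset(g for g in parts[2:] if g)))
    return sets


def write_gmt(path: str | Path, sets: Iterable[GeneSet]) -> None:
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.set_id, s.name, *sorted(s.genes)]) + "\n")


# ---------------------------------------------------------------------------
# BED / cytoband
# ---------------------------------------------------------------------------

_CYTOBAND_COLS = ["chrom", "start", "end", "band", "stain"]


def read_cytoband(path: str | Path) -> pd.DataFrame:
    """Read a UCSC-style 5-column cytoband file into a sorted DataFrame."""
    df = pd.read_csv(path, sep="\t", names=_CYTOBAND_COLS, header=None)
    if df[["start", "end"]].isna().any().any():
        raise FormatError(f"{path}: malformed cytoband coordinates")
    df = df.astype({"start": int, "end": int})
    if (df["end"] <= df["start"]).any():
        bad = df.index[df["end"] <= df["start"]][0]
        raise FormatError(f"{path}: row {bad + 1}: end <= start")
    return df.sort_values(["chrom", "start"]).reset_index(drop=True)


def write_cytoband(path: str | Path, df: pd.DataFrame) -> None:
    df[_CYTOBAND_COLS].to_csv(path, sep="\t", header=False, index=False)


def read_bed(path: str | Path, n_fields: int = 3) -> pd.DataFrame:
    """Read a BED-like file; first three columns chrom/start/end, rest kept raw."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            if len(parts) < n_fields:
                raise FormatError(f"{path}:{lineno}: expected >= {n_fields} columns")
            try:
                rows.append([parts[0], int(parts[1]), int(parts[2]), *parts[3:]])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    n_extra = max((len(r) - 3 for r in rows), default=0)
    cols = ["chrom", "start", "end"] + [f"field{i + 4}" for i in range(n_extra)]
    for r in rows:
        r.extend([None] * (len(cols) - len(r)))
    return pd.DataFrame(rows, columns=cols)


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())
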