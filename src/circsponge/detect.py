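"""Back-splice junction detection, exonic annotation and SRPBM quantification.

Detection here is a desk-scale exact-match split aligner: a read supports a
back-splice junction iff it can be split into two segments, each at least
``anchor_min`` nt, that both match the genome exactly on the same strand with
the left read-segment mapping *downstream* of the right one (the out-of-order
signature of a circular junction), and with both breakpoints inside the span
of one annotated gene.  Genome-scale callers' output can be ingested from
BED-like junction files instead.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from intervaltree import IntervalTree

from .io import ExonModel, FormatError, SampleMeta, reverse_complement


class StateError(RuntimeError):
    """Operation attempted before required state (e.g. genome index) exists."""


@dataclass(frozen=True)
class BackspliceJunction:
    """A back-splice junction: circle boundaries in genomic coordinates.

    ``acceptor_pos`` is the circle's leftmost (5' on +) genomic boundary and
    ``donor_pos`` the rightmost; ``donor_pos > acceptor_pos`` always holds.
    ``counts`` maps sample id to the number of unique supporting reads.
    """

    chrom: str
    acceptor_pos: int
    donor_pos: int
    strand: str
    counts: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.donor_pos <= self.acceptor_pos:
            raise ValueError(
                f"donor {self.donor_pos} <= acceptor {self.acceptor_pos} on {self.chrom}"
            )
        if any(c < 0 for c in self.counts.values()):
            raise ValueError("negative junction read count")

    @property
    def key(self) -> tuple[str, int, int, str]:
        return (self.chrom, self.acceptor_pos, self.donor_pos, self.strand)


@dataclass
class CircRNACall:
    """An exonic circRNA call with per-sample counts and SRPBM."""

    circ_id: str
    junction: BackspliceJunction
    gene_id: str
    tx_id: str
    exon_run: tuple[int, int]        # inclusive indices into the transcript's exons
    spliced_length: int
    counts: dict[str, int]
    srpbm: dict[str, float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# split alignment
# ---------------------------------------------------------------------------

class GenomeIndex:
    """Exact-substring lookup over both strands via a fixed-length k-mer index."""

    def __init__(self, genome: Mapping[str, str], k: int = 10):
        self.k = k
        self.genome = {c: s.upper() for c, s in genome.items()}
        self._index: dict[str, list[tuple[str, int]]] = defaultdict(list)
        for chrom, seq in self.genome.items():
            for i in range(len(seq) - k + 1):
                self._index[seq[i:i + k]].append((chrom, i))

    def find(self, segment: str) -> list[tuple[str, int]]:
        """All exact occurrences of ``segment`` on the forward strand."""
        if len(segment) < self.k:
            raise StateError(f"segment shorter than index k={self.k}")
        hits = []
        for chrom, pos in self._index.get(segment[: self.k], ()):
            if self.genome[chrom][pos:pos + len(segment)] == segment:
                hits.append((chrom, pos))
        return hits


def _gene_span_trees(annotation: Sequence[ExonModel]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for m in annotation:
        trees[m.chrom].addi(m.tx_start, m.tx_end, m)
    return dict(trees)


def _junctions_in_read(
    seq: str, index: GenomeIndex, trees: Mapping[str, IntervalTree], anchor_min: int
) -> set[tuple[str, int, int, str]]:
    """All back-splice junctions a single read supports (either orientation)."""
    found: set[tuple[str, int, int, str]] = set()
    for oriented, strand in ((seq, "+"), (reverse_complement(seq), "-")):
        L = len(oriented)
        for k in range(anchor_min, L - anchor_min + 1):
            left, right = oriented[:k], oriented[k:]
            left_hits = index.find(left)
            if not left_hits:
                continue
            right_hits = index.find(right)
            for lchrom, lpos in left_hits:
                for rchrom, rpos in right_hits:
                    if lchrom != rchrom or lpos <= rpos:
                        continue  # in-order or cross-chromosome: not a back-splice
                    donor = lpos + len(left)
                    acceptor = rpos
                    if donor <= acceptor:
                        continue
                    tree = trees.get(lchrom)
                    if tree is None:
                        continue
                    for iv in tree[acceptor]:
                        model: ExonModel = iv.data
                        if model.strand == strand and acceptor >= model.tx_start and donor <= model.tx_end:
                            found.add((lchrom, acceptor, donor, strand))
                            break
    return found


def split_align_backsplice(
    reads: Mapping[str, Iterable[tuple[str, str]]],
    genome: Mapping[str, str],
    annotation: Sequence[ExonModel],
    anchor_min: int = 10,
    index: GenomeIndex | None = None,
) -> list[BackspliceJunction]:
    """Detect back-splice junctions from per-sample reads.

    ``reads`` maps sample id to ``(read_id, sequence)`` pairs.  Reads with an
    identical sequence are counted once per sample ("unique" back-spliced
    reads).  Empty input yields an empty result.
    """
    if anchor_min < 8:
        raise ValueError(f"anchor_min must be >= 8, got {anchor_min}")
    if index is None:
        index = GenomeIndex(genome, k=anchor_min)
    elif index.k > anchor_min:
        raise StateError(f"genome index k={index.k} exceeds anchor_min={anchor_min}")
    trees = _gene_span_trees(annotation)

    counts: dict[tuple[str, int, int, str], dict[str, int]] = defaultdict(dict)
    junction_cache: dict[str, set] = {}
    for sample_id, sample_reads in reads.items():
        unique_seqs = {s.upper() for _, s in sample_reads}
        for seq in unique_seqs:
            if seq not in junction_cache:
                junction_cache[seq] = _junctions_in_read(seq, index, trees, anchor_min)
            for key in junction_cache[seq]:
                counts[key][sample_id] = counts[key].get(sample_id, 0) + 1
    return [
        BackspliceJunction(chrom, acc, don, strand, dict(c))
        for (chrom, acc, don, strand), c in sorted(counts.items())
    ]


# ---------------------------------------------------------------------------
# junction-file ingestion
# ---------------------------------------------------------------------------

def ingest_junctions(path: str | Path) -> list[BackspliceJunction]:
    """Read junctions from a BED-like file.

    Columns: chrom, acceptor(start), donor(end), name, strand, then
    ``sample:count`` tokens.  Coordinates must already be 0-based half-open.
    Malformed rows raise :class:`FormatError` naming the row.
    """
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split()
            if len(parts) < 5:
                raise FormatError(f"{path}:{lineno}: expected >= 5 fields")
            chrom, strand = parts[0], parts[4]
            try:
                acceptor, donor = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            if donor <= acceptor:
                raise FormatError(f"{path}:{lineno}: donor {donor} <= acceptor {acceptor}")
            counts = {}
            for tok in parts[5:]:
                if ":" not in tok:
                    raise FormatError(f"{path}:{lineno}: bad sample:count token {tok!r}")
                sample, value = tok.rsplit(":", 1)
                try:
                    counts[sample] = int(value)
                except ValueError as exc:
                    raise FormatError(f"{path}:{lineno}: {exc}") from exc
            out.append(BackspliceJunction(chrom, acceptor, donor, strand, counts))
    return out


def write_junctions(path: str | Path, junctions: Iterable[BackspliceJunction]) -> None:
    with open(path, "w") as fh:
        for j in junctions:
            toks = [f"{s}:{c}" for s, c in sorted(j.counts.items())]
            fh.write(
                "\t".join([j.chrom, str(j.acceptor_pos), str(j.donor_pos), ".", j.strand, *toks]) + "\n"
            )


# ---------------------------------------------------------------------------
# exonic annotation
# ---------------------------------------------------------------------------

def annotate_exonic(
    junctions: Sequence[BackspliceJunction],
    annotation: Sequence[ExonModel],
    boundary_tol: int = 0,
) -> list[CircRNACall]:
    """Keep junctions whose ends coincide with exon boundaries of one transcript.

    The acceptor must match an exon start and the donor an exon end of the
    *same* transcript within ``boundary_tol`` nt; matched junctions are
    snapped to the exact annotated boundaries and the exon run is every
    transcript exon between the matched pair.  Junctions matching no
    transcript are dropped (the exonic-only rule).  When several transcripts
    match, the one with the fewest exons in the run wins; ties break on
    lexicographic transcript id.
    """
    by_chrom: dict[str, list[ExonModel]] = defaultdict(list)
    for m in annotation:
        by_chrom[m.chrom].append(m)

    calls: list[CircRNACall] = []
    n = 0
    for j in junctions:
        candidates = []
        for model in by_chrom.get(j.chrom, ()):
            if model.strand != j.strand:
                continue
            first = next(
                (i for i, (s, _) in enumerate(model.exons) if abs(s - j.acceptor_pos) <= boundary_tol),
                None,
            )
            last = next(
                (i for i, (_, e) in enumerate(model.exons) if abs(e - j.donor_pos) <= boundary_tol),
                None,
            )
            if first is None or last is None or last < first:
                continue
            candidates.append((last - first + 1, model.tx_id, model, first, last))
        if not candidates:
            continue
        candidates.sort(key=lambda c: (c[0], c[1]))
        _, _, model, first, last = candidates[0]
        run = model.exons[first:last + 1]
        n += 1
        snapped = BackspliceJunction(
            j.chrom, run[0][0], run[-1][1], j.strand, dict(j.counts)
        )
        calls.append(
            CircRNACall(
                circ_id=f"circ_{j.chrom}_{run[0][0]}_{run[-1][1]}_{j.strand}",
                junction=snapped,
                gene_id=model.gene_id,
                tx_id=model.tx_id,
                exon_run=(first, last),
                spliced_length=sum(e - s for s, e in run),
                counts=dict(j.counts),
            )
        )
    return calls


# ---------------------------------------------------------------------------
# filtering and quantification
# ---------------------------------------------------------------------------

def filter_high_confidence(
    calls: Sequence[CircRNACall], min_reads: int = 2, min_samples: int = 2
) -> list[CircRNACall]:
    """High-confidence rule: >= ``min_reads`` unique reads in >= ``min_samples`` samples."""
    kept = []
    for call in calls:
        n_ok = sum(1 for c in call.counts.values() if c >= min_reads)
        if n_ok >= min_samples:
            kept.append(call)
    return kept


def compute_srpbm(
    calls: Sequence[CircRNACall], meta: Sequence[SampleMeta]
) -> list[CircRNACall]:
    """Spliced reads per billion mappings.

    ``SRPBM_s = count_s / (total_mapped_reads_s * read_length_s) * 1e9`` --
    junction reads per billion mapped bases.  Samples absent from a call's
    count dict quantify as 0.
    """
    by_id = {m.sample_id: m for m in meta}
    for m in meta:
        if m.total_mapped_reads == 0:
            raise ZeroDivisionError(f"sample {m.sample_id}: total_mapped_reads is 0")
    out = []
    for call in calls:
        srpbm = {}
        for m in meta:
            c = call.counts.get(m.sample_id, 0)
            srpbm[m.sample_id] = c / (m.total_mapped_reads * m.read_length) * 1e9
        call.srpbm = srpbm
        out.append(call)
    return out


# ---------------------------------------------------------------------------
# circular sequence extraction
# ---------------------------------------------------------------------------

def circ_sequence(
    call: CircRNACall, genome: Mapping[str, str], annotation: Sequence[ExonModel]
) -> str:
    """Spliced circular sequence: exons concatenated in transcript order.

    For minus-strand genes the result is the reverse complement of the
    concatenated genomic exon sequence.  Downstream consumers treat the
    sequence as circular (windows may wrap the back-splice junction).
    """
    model = next(m for m in annotation if m.tx_id == call.tx_id)
    return _spliced_seq(genome, model, call.exon_run)


def circ_sequence_from_truth(truth, genome: Mapping[str, str], annotation: Sequence[ExonModel]) -> str:
    model = next(m for m in annotation if m.tx_id == truth.tx_id)
    return _spliced_seq(genome, model, truth.exon_run)


def _spliced_seq(genome: Mapping[str, str], model: ExonModel, run: tuple[int, int]) -> str:
    chrom_seq = genome[model.chrom]
    first, last = run
    pieces = []
    for s, e in model.exons[first:last + 1]:
        if e > len(chrom_seq):
            raise IndexError(f"exon ({s},{e}) beyond end of {model.chrom}")
        pieces.append(chrom_seq[s:e])
    seq = "".join(pieces)
    return reverse_complement(seq) if model.strand == "-" else seq
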