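"""Synthetic data with planted ground truth for every pipeline stage.

The generator emulates the study design this pipeline targets: 12 RNA-seq
samples (2 cell backgrounds x sensitive/resistant groups x 3 replicates) over
a small multi-gene genome.  Exonic circRNAs are planted as contiguous exon
runs and emit back-spliced junction reads at controlled depths; miRNA counts
are negative-binomially distributed with planted log2 fold-changes; miRNA
seed-match sites (MREs) are planted into circRNA sequences; and a CNV
"amplified" segment is planted over a resistant-specific circRNA locus,
mimicking a multi-level RNA/DNA hotspot.

Everything is deterministic under a fixed seed: one global seed fans out to
independent per-component streams so that changing one generator's request
does not shift the draws of another.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    ExonModel,
    GeneSet,
    SampleMeta,
    reverse_complement,
    write_cytoband,
    write_fasta,
    write_gmt,
    write_refflat,
    write_samples,
    write_tsv_matrix,
)

BASES = "ACGT"

GROUPS = ("sensitive", "resistant")
BACKGROUNDS = ("MCF", "MDA")


class ConfigError(ValueError):
    """Simulation configuration violates an invariant."""


class SizingError(ConfigError):
    """Genome too small to place the requested genes."""


class CapacityError(ConfigError):
    """More planted entities requested than the annotation can host."""


class PlacementError(ConfigError):
    """A sequence is too short to host a planted site."""


@dataclass
class SimConfig:
    """All knobs of the synthetic study, with the 12-sample design as default.

    Ranges are inclusive ``(low, high)`` tuples.  ``anchor`` is the minimum
    exact-match segment a back-spliced read carries on each side of the
    junction, matching the detector's default evidence requirement.
    """

    seed: int = 0
    n_chromosomes: int = 2
    chromosome_length: int = 150_000
    n_genes: int = 20
    exons_per_gene: tuple[int, int] = (4, 8)
    exon_length: tuple[int, int] = (100, 400)
    intron_length: tuple[int, int] = (200, 800)
    gene_gap: tuple[int, int] = (300, 1200)
    n_circ_planted: int = 12
    n_samples_per_group: int = 3          # replicates per group per background
    read_length: int = 100
    anchor: int = 10
    depth_per_junction: tuple[int, int] = (3, 8)
    sample_dropout: float = 0.15          # chance a sample misses an expressed circle
    n_linear_reads_per_sample: int = 300
    n_mirna: int = 300
    n_mirna_de: int = 30
    mirna_length: tuple[int, int] = (21, 22)
    mirna_mean: tuple[float, float] = (100.0, 2000.0)
    planted_lfc: float = 2.0
    nb_dispersion: float = 0.05
    n_mre_planted: int = 12
    n_eligible_planted: int = 8
    n_reported: int = 40
    n_pathway_genes: int = 200

    def validate(self) -> None:
        positive = {
            "n_chromosomes": self.n_chromosomes,
            "chromosome_length": self.chromosome_length,
            "n_genes": self.n_genes,
            "n_samples_per_group": self.n_samples_per_group,
            "read_length": self.read_length,
            "anchor": self.anchor,
            "n_mirna": self.n_mirna,
        }
        for name, value in positive.items():
            if value <= 0:
                raise ConfigError(f"{name} must be positive, got {value}")
        if self.nb_dispersion <= 0:
            raise ConfigError("nb_dispersion must be > 0")
        if self.read_length < 2 * self.anchor:
            raise ConfigError(
                f"read_length {self.read_length} < 2 x anchor {self.anchor}: "
                "back-spliced reads could not carry both anchors"
            )
        if self.n_mirna_de > self.n_mirna:
            raise ConfigError("n_mirna_de exceeds n_mirna")
        if self.exon_length[0] < self.read_length:
            raise ConfigError(
                "min exon length must be >= read_length so junction reads map "
                "contiguously within flanking exons"
            )
        # worst-case space one gene can need, plus gap
        span = (
            self.exons_per_gene[1] * self.exon_length[1]
            + (self.exons_per_gene[1] - 1) * self.intron_length[1]
            + self.gene_gap[1]
        )
        genes_per_chrom = -(-self.n_genes // self.n_chromosomes)
        if genes_per_chrom * span > self.chromosome_length:
            raise SizingError(
                f"chromosome_length {self.chromosome_length} cannot hold "
                f"{genes_per_chrom} genes of worst-case span {span}"
            )

    def streams(self) -> dict[str, np.random.Generator]:
        """Independent named RNG streams fanned out from the global seed."""
        names = ["genome", "circ", "reads", "mirna", "mre", "fixtures"]
        root = np.random.SeedSequence(self.seed)
        children = root.spawn(len(names))
        return {n: np.random.default_rng(c) for n, c in zip(names, children)}

    @property
    def sample_ids(self) -> list[str]:
        return [
            f"{bg}_{'RES' if grp == 'resistant' else 'SEN'}_{r + 1}"
            for bg in BACKGROUNDS
            for grp in GROUPS
            for r in range(self.n_samples_per_group)
        ]

    def sample_table(self) -> list[tuple[str, str, str]]:
        """(sample_id, group, background) triples in stable order."""
        out = []
        for bg in BACKGROUNDS:
            for grp in GROUPS:
                for r in range(self.n_samples_per_group):
                    out.append((f"{bg}_{'RES' if grp == 'resistant' else 'SEN'}_{r + 1}", grp, bg))
        return out


@dataclass
class CircTruth:
    """One planted circRNA and its per-sample junction-read counts."""

    circ_id: str
    gene_id: str
    tx_id: str
    chrom: str
    strand: str
    exon_run: tuple[int, int]             # inclusive (first, last) exon indices
    start: int                            # genomic acceptor (leftmost) boundary
    end: int                              # genomic donor (rightmost) boundary
    spliced_length: int
    specificity: str                      # "resistant" | "sensitive" | "none"
    backgrounds: tuple[str, ...]          # cell backgrounds expressing it
    counts: dict[str, int] = field(default_factory=dict)

    @property
    def junction_key(self) -> tuple[str, int, int, str]:
        return (self.chrom, self.start, self.end, self.strand)


@dataclass
class MreTruth:
    circ_id: str
    mirna_id: str
    position: int          # start of the seed core on the circular sequence
    site_type: str         # 6mer / 7mer-A1 / 7mer-m8 / 8mer


@dataclass
class TruthSet:
    """Ground truth for every planted entity, serializable to truth.json."""

    circ_truth: list[CircTruth] = field(default_factory=list)
    mirna_de_truth: dict[str, float] = field(default_factory=dict)
    mre_truth: list[MreTruth] = field(default_factory=list)
    eligible_truth: list[str] = field(default_factory=list)
    enriched_pathway: str = ""
    cnv_truth: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "circ_truth": [asdict(c) for c in self.circ_truth],
            "mirna_de_truth": self.mirna_de_truth,
            "mre_truth": [asdict(m) for m in self.mre_truth],
            "eligible_truth": self.eligible_truth,
            "enriched_pathway": self.enriched_pathway,
            "cnv_truth": self.cnv_truth,
        }
        Path(path).write_text(json.dumps(payload, indent=1))


# ---------------------------------------------------------------------------
# genome and annotation
# ---------------------------------------------------------------------------

def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list(BASES))[rng.integers(0, 4, size=length)])


def make_genome_and_annotation(
    cfg: SimConfig, rng: np.random.Generator | None = None
) -> tuple[dict[str, str], list[ExonModel]]:
    """Generate a random genome and non-overlapping multi-exon gene models.

    Genes are laid out left to right with random gaps, alternating strands,
    split round-robin across chromosomes.  Raises :class:`SizingError` when a
    gene does not fit on its chromosome.
    """
    cfg.validate()
    if rng is None:
        rng = cfg.streams()["genome"]
    chrom_names = [f"chr{i + 1}" for i in range(cfg.n_chromosomes)]
    genome = {c: _random_seq(rng, cfg.chromosome_length) for c in chrom_names}

    models: list[ExonModel] = []
    cursors = {c: 0 for c in chrom_names}
    for g in range(cfg.n_genes):
        chrom = chrom_names[g % cfg.n_chromosomes]
        n_ex = int(rng.integers(cfg.exons_per_gene[0], cfg.exons_per_gene[1] + 1))
        gap = int(rng.integers(cfg.gene_gap[0], cfg.gene_gap[1] + 1))
        start = cursors[chrom] + gap
        exons = []
        pos = start
        for e in range(n_ex):
            length = int(rng.integers(cfg.exon_length[0], cfg.exon_length[1] + 1))
            exons.append((pos, pos + length))
            pos += length
            if e < n_ex - 1:
                pos += int(rng.integers(cfg.intron_length[0], cfg.intron_length[1] + 1))
        if pos > cfg.chromosome_length:
            raise SizingError(
                f"gene {g} would end at {pos} beyond chromosome_length "
                f"{cfg.chromosome_length} on {chrom}"
            )
        strand = "+" if g % 2 == 0 else "-"
        gene_id = f"GENE{g + 1:03d}"
        models.append(ExonModel(gene_id, f"TX{g + 1:03d}", chrom, strand, tuple(exons)))
        cursors[chrom] = pos
    return genome, models


# ---------------------------------------------------------------------------
# circRNA planting
# ---------------------------------------------------------------------------

def plant_circrnas(
    annotation: list[ExonModel],
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
) -> list[CircTruth]:
    """Plant exonic circRNAs as contiguous exon runs of distinct genes.

    Roughly a third of the circles are resistant-specific, a third
    sensitive-specific and a third shared; one planted circle is forced to be
    a single-exon circle (back-splice of one exon's own boundaries).  A
    quarter of the circles (rounded down) are restricted to a single cell
    background so that the cross-background shared fraction is informative.
    """
    if cfg.n_circ_planted == 0:
        return []
    if rng is None:
        rng = cfg.streams()["circ"]
    hosts = [m for m in annotation if m.n_exons >= 2]
    if cfg.n_circ_planted > len(hosts):
        raise CapacityError(
            f"{cfg.n_circ_planted} circles requested but only {len(hosts)} "
            "genes with >=2 exons are available (one circle per gene)"
        )
    chosen = rng.choice(len(hosts), size=cfg.n_circ_planted, replace=False)
    specs = [GROUPS[1], GROUPS[0], "none"] * (cfg.n_circ_planted // 3 + 1)
    n_single_bg = cfg.n_circ_planted // 4
    truths: list[CircTruth] = []
    for i, host_idx in enumerate(sorted(chosen)):
        model = hosts[host_idx]
        if i == 0:
            # single-exon circle: the 5' and 3' boundaries of one exon
            first = last = int(rng.integers(0, model.n_exons))
        else:
            first = int(rng.integers(0, model.n_exons - 1))
            last = int(rng.integers(first, model.n_exons))
        run = model.exons[first:last + 1]
        spliced_length = sum(e - s for s, e in run)
        backgrounds = (
            (BACKGROUNDS[i % 2],) if i < n_single_bg else tuple(BACKGROUNDS)
        )
        truths.append(
            CircTruth(
                circ_id=f"circ.{i + 1:04d}",
                gene_id=model.gene_id,
                tx_id=model.tx_id,
                chrom=model.chrom,
                strand=model.strand,
                exon_run=(first, last),
                start=run[0][0],
                end=run[-1][1],
                spliced_length=spliced_length,
                specificity=specs[i],
                backgrounds=backgrounds,
            )
        )
    return truths


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------

def _junction_read(genome: dict[str, str], truth: CircTruth, annotation_by_tx, k: int,
                   read_length: int) -> str:
    """A read straddling the back-splice with k bases on the donor side.

    In transcript orientation the read is (last k nt of the circle) followed
    by (first read_length - k nt of the circle); because flanking exons are at
    least read_length long, both pieces are contiguous genomic substrings.
    """
    model = annotation_by_tx[truth.tx_id]
    first, last = truth.exon_run
    chrom_seq = genome[truth.chrom]
    first_exon = model.exons[first]
    last_exon = model.exons[last]
    if truth.strand == "+":
        donor_side = chrom_seq[last_exon[1] - k:last_exon[1]]
        acceptor_side = chrom_seq[first_exon[0]:first_exon[0] + read_length - k]
        return donor_side + acceptor_side
    # minus strand: circle RNA is the reverse complement; its 3' end is the
    # genomic start of the leftmost exon
    donor_side = reverse_complement(chrom_seq[first_exon[0]:first_exon[0] + k])
    acceptor_side = reverse_complement(
        chrom_seq[last_exon[1] - (read_length - k):last_exon[1]]
    )
    return donor_side + acceptor_side


def simulate_backspliced_reads(
    genome: dict[str, str],
    annotation: list[ExonModel],
    circ_truth: list[CircTruth],
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[dict[str, list[tuple[str, str]]], list[SampleMeta]]:
    """Emit per-sample reads (junction + linear background) and sample metadata.

    Planted per-sample junction-read counts are recorded back into
    ``circ_truth[i].counts``.  Each junction read is unique within its sample
    (distinct split positions), so the detector's unique-read counts equal the
    planted counts exactly.
    """
    cfg.validate()
    if rng is None:
        rng = cfg.streams()["reads"]
    annotation_by_tx = {m.tx_id: m for m in annotation}
    k_lo, k_hi = cfg.anchor, cfg.read_length - cfg.anchor
    max_depth = k_hi - k_lo + 1
    if cfg.depth_per_junction[1] > max_depth:
        raise ConfigError(
            f"depth_per_junction max {cfg.depth_per_junction[1]} exceeds the "
            f"{max_depth} distinct split positions available"
        )

    reads: dict[str, list[tuple[str, str]]] = {}
    metas: list[SampleMeta] = []
    for sample_id, group, background in cfg.sample_table():
        sample_reads: list[tuple[str, str]] = []
        for truth in circ_truth:
            expressed = (
                (truth.specificity in ("none", group))
                and background in truth.backgrounds
            )
            if expressed and rng.random() < cfg.sample_dropout:
                expressed = False
            count = (
                int(rng.integers(cfg.depth_per_junction[0], cfg.depth_per_junction[1] + 1))
                if expressed
                else 0
            )
            truth.counts[sample_id] = count
            if count:
                ks = rng.choice(np.arange(k_lo, k_hi + 1), size=count, replace=False)
                for j, k in enumerate(sorted(int(k) for k in ks)):
                    seq = _junction_read(genome, truth, annotation_by_tx, k, cfg.read_length)
                    sample_reads.append((f"{sample_id}:{truth.circ_id}:bsj{j}", seq))
        # linear background: contiguous genomic fragments from random exons
        exonic = [
            (m.chrom, s, e) for m in annotation for s, e in m.exons
            if e - s >= cfg.read_length
        ]
        for j in range(cfg.n_linear_reads_per_sample):
            chrom, s, e = exonic[int(rng.integers(0, len(exonic)))]
            off = int(rng.integers(s, e - cfg.read_length + 1))
            seq = genome[chrom][off:off + cfg.read_length]
            if rng.random() < 0.5:
                seq = reverse_complement(seq)
            sample_reads.append((f"{sample_id}:lin{j}", seq))
        reads[sample_id] = sample_reads
        metas.append(
            SampleMeta(
                sample_id=sample_id,
                group=group,
                background=background,
                total_mapped_reads=len(sample_reads),
                read_length=cfg.read_length,
            )
        )
    # drop-out can leave an expressed circle below the high-confidence filter
    # or absent from one of its groups (which would flip a shared circle to
    # group-specific); top up counts so the planted truth is recoverable:
    # >=2 samples with >=2 reads overall, and >=1 expressed sample in every
    # group the circle belongs to.
    def top_up(truth: CircTruth, sid: str, n: int) -> None:
        truth.counts[sid] = n
        for j, k in enumerate(range(k_lo, k_lo + n)):
            seq = _junction_read(genome, truth, annotation_by_tx, k, cfg.read_length)
            reads[sid].append((f"{sid}:{truth.circ_id}:bsjx{j}", seq))

    for truth in circ_truth:
        required_groups = list(GROUPS) if truth.specificity == "none" else [truth.specificity]
        for group in required_groups:
            in_group = [
                sid for sid, grp, bg in cfg.sample_table()
                if grp == group and bg in truth.backgrounds
            ]
            if not any(truth.counts.get(s, 0) >= 1 for s in in_group):
                top_up(truth, in_group[0], cfg.depth_per_junction[0])
        have = [s for s, c in truth.counts.items() if c >= 2]
        if len(have) < 2:
            eligible = [
                sid for sid, grp, bg in cfg.sample_table()
                if (truth.specificity in ("none", grp)) and bg in truth.backgrounds
                and sid not in have
            ]
            for sid in eligible[: 2 - len(have)]:
                top_up(truth, sid, max(2, cfg.depth_per_junction[0]))
    metas = [
        SampleMeta(m.sample_id, m.group, m.background, len(reads[m.sample_id]), m.read_length)
        for m in metas
    ]
    return reads, metas


# ---------------------------------------------------------------------------
# miRNA counts and sequences
# ---------------------------------------------------------------------------

def mirna_ids(cfg: SimConfig) -> list[str]:
    arms = ("-5p", "-3p")
    return [f"miR-{i + 1}{arms[i % 2]}" for i in range(cfg.n_mirna)]


def make_mirnas(cfg: SimConfig, rng: np.random.Generator | None = None) -> dict[str, str]:
    """Random mature miRNA sequences (RNA alphabet, 21-22 nt)."""
    if rng is None:
        rng = cfg.streams()["mirna"]
    out = {}
    for mid in mirna_ids(cfg):
        length = int(rng.integers(cfg.mirna_length[0], cfg.mirna_length[1] + 1))
        out[mid] = _random_seq(rng, length).replace("T", "U")
    return out


def simulate_mirna_counts(
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
    de_ids: list[str] | None = None,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """NB-distributed miRNA count matrix with planted log2 fold-changes.

    The first half of the DE miRNAs are up in the resistant group, the second
    half down, each by ``2**planted_lfc``.  Returns the integer count matrix
    (miRNA x 12 samples) and ``{mirna_id: signed lfc}``.
    """
    cfg.validate()
    if rng is None:
        rng = cfg.streams()["mirna"]
        rng = np.random.default_rng(rng.integers(2**31))  # decouple from make_mirnas
    ids = mirna_ids(cfg)
    if de_ids is None:
        de_idx = rng.choice(cfg.n_mirna, size=cfg.n_mirna_de, replace=False)
        de_ids = [ids[i] for i in sorted(de_idx)]
    de_truth = {
        mid: (cfg.planted_lfc if i < len(de_ids) // 2 else -cfg.planted_lfc)
        for i, mid in enumerate(de_ids)
    }
    lo, hi = np.log(cfg.mirna_mean[0]), np.log(cfg.mirna_mean[1])
    base_mean = np.exp(rng.uniform(lo, hi, size=cfg.n_mirna))
    table = cfg.sample_table()
    r = 1.0 / cfg.nb_dispersion
    counts = np.zeros((cfg.n_mirna, len(table)), dtype=np.int64)
    for j, (_, group, _) in enumerate(table):
        mu = base_mean.copy()
        for i, mid in enumerate(ids):
            if mid in de_truth and group == "resistant":
                mu[i] *= 2.0 ** de_truth[mid]
        p = r / (r + mu)
        counts[:, j] = rng.negative_binomial(r, p)
    df = pd.DataFrame(counts, index=ids, columns=[t[0] for t in table])
    return df, de_truth


# ---------------------------------------------------------------------------
# MRE planting
# ---------------------------------------------------------------------------

_RNA_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}


def _rna_revcomp(seq: str) -> str:
    return "".join(_RNA_COMPLEMENT[b] for b in reversed(seq))


def _seed_core(mirna_seq: str) -> str:
    """Reverse complement of miRNA positions 2-7: the 6mer core a target carries."""
    return _rna_revcomp(mirna_seq[1:7])


def plant_mre_sites(
    circ_seqs: dict[str, str],
    mirnas: dict[str, str],
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
    panel: list[str] | None = None,
    clean_for: list[str] | None = None,
) -> tuple[dict[str, str], list[MreTruth]]:
    """Plant miRNA binding sites into circRNA sequences (DNA space).

    Each planted site is the full reverse complement of the miRNA's positions
    2..end written into the target, with the nucleotide opposite position 1
    set to A for 7mer-A1/8mer types -- so the seed scanner finds it with the
    intended type and the complementarity aligner scores it highly (two
    independent predictors fire, giving a consensus vote of 2).

    After planting, accidental seed cores of every miRNA in
    ``panel + clean_for`` are destroyed by point mutations outside planted
    windows (rejection/repair sampling), so truth recovery is exact for those
    miRNAs.  Sequences are circular: the repair pass also checks windows that
    wrap the back-splice junction.
    """
    if rng is None:
        rng = cfg.streams()["mre"]
    if panel is None:
        panel = list(mirnas)[: cfg.n_mre_planted]
    protect_ids = list(dict.fromkeys(list(panel) + list(clean_for or [])))

    site_types = ["8mer", "7mer-m8", "7mer-A1", "6mer"]
    seqs = {cid: s.upper().replace("U", "T") for cid, s in circ_seqs.items()}
    truths: list[MreTruth] = []
    protected: dict[str, list[tuple[int, int]]] = {cid: [] for cid in seqs}

    circ_ids = sorted(seqs)
    for i, mirna_id in enumerate(panel):
        m = mirnas[mirna_id]
        circ_id = circ_ids[i % len(circ_ids)]
        seq = seqs[circ_id]
        site = list(_rna_revcomp(m[1:]))        # pairs miRNA positions 2..L; last 6 = seed core
        site_type = site_types[i % len(site_types)]
        pos1_nt = "A" if site_type in ("8mer", "7mer-A1") else (
            "G" if _RNA_COMPLEMENT[m[0]] != "G" else "C"   # deliberately non-pairing, non-A
        )
        if site_type in ("7mer-A1", "6mer"):
            # break the position-8 pairing (the base just 5' of the core)
            m8 = _RNA_COMPLEMENT[m[7]]
            site[-7] = "C" if m8 != "C" else "G"
        insert = "".join(site) + pos1_nt
        core_offset = len(site) - 6
        insert_dna = insert.replace("U", "T")
        if len(seq) < len(insert_dna) + 2:
            raise PlacementError(
                f"{circ_id} ({len(seq)} nt) too short for a planted site of "
                f"{len(insert_dna)} nt"
            )
        # non-overlapping placement away from already-planted windows
        for _ in range(200):
            pos = int(rng.integers(0, len(seq) - len(insert_dna)))
            if all(pos + len(insert_dna) <= s or pos >= e for s, e in protected[circ_id]):
                break
        else:
            raise PlacementError(f"could not place site {i} on {circ_id}")
        seq = seq[:pos] + insert_dna + seq[pos + len(insert_dna):]
        seqs[circ_id] = seq
        protected[circ_id].append((pos, pos + len(insert_dna)))
        truths.append(MreTruth(circ_id, mirna_id, pos + core_offset, site_type))

    # repair pass: destroy accidental seed cores of protected miRNAs.  Cores
    # that fall entirely inside a *different* miRNA's planted window cannot be
    # mutated without damaging that site; they are left alone -- a lone
    # seed-scanner hit carries one predictor vote and never reaches the >=2
    # consensus, so planted-truth recovery is unaffected.
    cores = {mid: _seed_core(mirnas[mid]).replace("U", "T") for mid in protect_ids}
    planted_cores = {(t.circ_id, t.mirna_id): t.position for t in truths}
    for cid in circ_ids:
        for _ in range(300):
            seq = seqs[cid]
            doubled = seq + seq
            dirty = None
            for mid, core in cores.items():
                start = 0
                while dirty is None:
                    j = doubled.find(core, start)
                    if j < 0 or j >= len(seq):
                        break
                    start = j + 1
                    if planted_cores.get((cid, mid)) == j:
                        continue
                    if any(s <= j < e for s, e in protected[cid]):
                        continue  # inside a planted window: benign, see above
                    dirty = j
                if dirty is not None:
                    break
            if dirty is None:
                break
            old = seq[dirty]
            new = BASES[(BASES.index(old) + 1 + int(rng.integers(0, 3))) % 4]
            seqs[cid] = seq[:dirty] + new + seq[dirty + 1:]
        else:
            raise PlacementError(f"repair pass did not converge on {cid}")
    return seqs, truths


# ---------------------------------------------------------------------------
# fixture lists: Reported.miR, miRNA->gene mapping, gene sets, CNV, cytobands
# ---------------------------------------------------------------------------

def make_cytobands(cfg: SimConfig) -> pd.DataFrame:
    """A fixed banding pattern: 3 p-arm and 4 q-arm bands per chromosome."""
    labels = ["p13", "p12", "p11", "q11", "q21.1", "q21.2", "q22"]
    stains = ["gneg", "gpos50", "gneg", "gneg", "gpos25", "gneg", "gpos50"]
    rows = []
    for i in range(cfg.n_chromosomes):
        chrom = f"chr{i + 1}"
        width = cfg.chromosome_length // len(labels)
        for b, label in enumerate(labels):
            start = b * width
            end = (b + 1) * width if b < len(labels) - 1 else cfg.chromosome_length
            rows.append((chrom, start, end, label, stains[b]))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "band", "stain"])


def make_fixture_lists(
    cfg: SimConfig,
    de_truth: dict[str, float],
    mre_panel: list[str],
    circ_truth: list[CircTruth],
    rng: np.random.Generator | None = None,
) -> dict:
    """Literature list, miRNA->gene mapping, gene sets, CNV segments, loci.

    Construction guarantees a known three-way structure: the planted eligible
    miRNAs are DE, literature-reported and MRE-planted; a further slice of DE
    miRNAs is reported but not predicted (a realistic partial overlap);
    and the remaining reported miRNAs are neither.  One gene set consists
    entirely of target genes of the eligible miRNAs (k = K enrichment); one
    CNV amplification covers a resistant-specific planted circRNA, and
    concordant up-regulated mRNA/lncRNA loci are placed in the same band.
    """
    if rng is None:
        rng = cfg.streams()["fixtures"]
    eligible = list(mre_panel[: cfg.n_eligible_planted])
    de_not_predicted = [m for m in de_truth if m not in mre_panel]
    n_extra_de = min(len(de_not_predicted), max(0, cfg.n_reported // 3))
    reported = list(eligible) + de_not_predicted[:n_extra_de]
    all_ids = mirna_ids(cfg)
    fill = [m for m in all_ids if m not in set(reported) | set(de_truth) | set(mre_panel)]
    reported += fill[: max(0, cfg.n_reported - len(reported))]

    genes = [f"g{i + 1:03d}" for i in range(cfg.n_pathway_genes)]
    mapping: dict[str, list[str]] = {}
    # eligible miRNAs draw targets from a dedicated block so the planted
    # pathway can be made from them exactly
    block = genes[: 5 * len(eligible)]
    for i, mid in enumerate(eligible):
        mapping[mid] = block[5 * i: 5 * i + 5]
    others = [m for m in reported if m not in mapping]
    for mid in others:
        picks = rng.choice(len(genes), size=5, replace=False)
        mapping[mid] = [genes[int(p)] for p in picks]

    pooled = sorted({g for mid in eligible for g in mapping[mid]})
    enriched_genes = [pooled[int(i)] for i in rng.choice(len(pooled), size=min(10, len(pooled)), replace=False)]
    gene_sets = [GeneSet("path001", "planted_enriched_pathway", frozenset(enriched_genes))]
    for s in range(19):
        picks = rng.choice(len(genes), size=15, replace=False)
        gene_sets.append(
            GeneSet(f"path{s + 2:03d}", f"decoy_pathway_{s + 2}", frozenset(genes[int(p)] for p in picks))
        )

    # CNV hotspot over a resistant-specific circle
    hot = next(c for c in circ_truth if c.specificity == "resistant")
    pad = 2000
    cnv_rows = []
    for cell in BACKGROUNDS:
        cnv_rows.append((hot.chrom, max(0, hot.start - pad), hot.end + pad, cell, "amplification"))
    # decoy segments elsewhere
    other_chrom = f"chr{cfg.n_chromosomes}" if hot.chrom != f"chr{cfg.n_chromosomes}" else "chr1"
    cnv_rows.append((other_chrom, 1000, 6000, BACKGROUNDS[0], "deletion"))
    cnv_rows.append((other_chrom, 20000, 26000, BACKGROUNDS[1], "deletion"))
    cnv = pd.DataFrame(cnv_rows, columns=["chrom", "start", "end", "cell_line", "state"])

    cytobands = make_cytobands(cfg)
    in_band = cytobands[
        (cytobands.chrom == hot.chrom)
        & (cytobands.start <= hot.start)
        & (cytobands.end > hot.start)
    ].iloc[0]

    # multi-level RNA features: concordant up mRNA + lncRNA in the hot band,
    # sparse scattered features elsewhere (at most one class per decoy band)
    loci_rows = [
        (hot.circ_id, "circRNA", hot.chrom, hot.start, hot.end, "specific-resistant"),
        ("mRNA_hot", "mRNA", hot.chrom, int(in_band.start) + 100,
         int(in_band.start) + 1600, "up"),
        ("lnc_hot", "lncRNA", hot.chrom, int(in_band.end) - 1800,
         int(in_band.end) - 300, "up"),
    ]
    decoy_bands = cytobands[~((cytobands.chrom == hot.chrom) & (cytobands.band == in_band.band))]
    directions = ["up", "down", "down", "up"]
    classes = ["mRNA", "lncRNA", "miRNA", "mRNA"]
    for i, (_, band) in enumerate(decoy_bands.iloc[:8].iterrows()):
        start = int(band.start) + 500
        loci_rows.append(
            (f"decoy_{i}", classes[i % 4], band.chrom, start, start + 1200, directions[i % 4])
        )
    feature_loci = pd.DataFrame(
        loci_rows, columns=["feature", "rna_class", "chrom", "start", "end", "direction"]
    )

    return {
        "reported": reported,
        "mir2gene": mapping,
        "gene_sets": gene_sets,
        "cnv": cnv,
        "cytobands": cytobands,
        "feature_loci": feature_loci,
        "eligible": eligible,
        "enriched_pathway": "path001",
        "hot_band": {"chrom": hot.chrom, "band": str(in_band.band),
                     "circ_id": hot.circ_id, "start": int(hot.start), "end": int(hot.end)},
    }


# ---------------------------------------------------------------------------
# one-call driver
# ---------------------------------------------------------------------------

def simulate_all(cfg: SimConfig, outdir: str | Path | None = None):
    """Generate the complete synthetic study; optionally write all files.

    Returns ``(bundle, truth)`` where ``bundle`` is a dict of in-memory
    objects (genome, annotation, reads, samples, counts, mirnas, circ_seqs,
    fixtures) and ``truth`` the :class:`TruthSet`.
    """
    from .detect import circ_sequence_from_truth  # local import to avoid cycle

    cfg.validate()
    streams = cfg.streams()
    genome, annotation = make_genome_and_annotation(cfg, streams["genome"])
    circ_truth = plant_circrnas(annotation, cfg, streams["circ"])
    reads, samples = simulate_backspliced_reads(genome, annotation, circ_truth, cfg, streams["reads"])

    mirna_rng = streams["mirna"]
    mirnas = make_mirnas(cfg, mirna_rng)
    # choose the MRE panel from the DE miRNAs so eligible = DE & reported & predicted
    count_rng = np.random.default_rng(mirna_rng.integers(2**31))
    ids = mirna_ids(cfg)
    de_idx = count_rng.choice(cfg.n_mirna, size=cfg.n_mirna_de, replace=False)
    de_ids = [ids[i] for i in sorted(de_idx)]
    counts, de_truth = simulate_mirna_counts(cfg, count_rng, de_ids=de_ids)

    mre_panel = de_ids[: cfg.n_mre_planted]
    # plant sites on the group-specific circles (the sponge candidates)
    cand = [c for c in circ_truth if c.specificity != "none"] or circ_truth
    circ_seqs = {c.circ_id: circ_sequence_from_truth(c, genome, annotation) for c in cand}
    fixtures_rng = streams["fixtures"]
    fixtures = make_fixture_lists(cfg, de_truth, mre_panel, circ_truth, fixtures_rng)
    circ_seqs, mre_truth = plant_mre_sites(
        circ_seqs, mirnas, cfg, streams["mre"],
        panel=mre_panel, clean_for=fixtures["reported"],
    )

    truth = TruthSet(
        circ_truth=circ_truth,
        mirna_de_truth=de_truth,
        mre_truth=mre_truth,
        eligible_truth=fixtures["eligible"],
        enriched_pathway=fixtures["enriched_pathway"],
        cnv_truth=fixtures["hot_band"],
    )
    bundle = {
        "genome": genome,
        "annotation": annotation,
        "reads": reads,
        "samples": samples,
        "mirna_counts": counts,
        "mirnas": mirnas,
        "circ_seqs": circ_seqs,
        "fixtures": fixtures,
        "config": cfg,
    }
    if outdir is not None:
        _write_bundle(bundle, truth, Path(outdir))
    return bundle, truth


def _write_bundle(bundle: dict, truth: TruthSet, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(outdir / "genome.fa", bundle["genome"])
    write_refflat(outdir / "annotation.refflat", bundle["annotation"])
    for sample_id, sample_reads in bundle["reads"].items():
        write_fasta(outdir / f"reads_{sample_id}.fa", dict(sample_reads))
    write_samples(outdir / "samples.tsv", bundle["samples"])
    write_tsv_matrix(outdir / "mirna_counts.tsv", bundle["mirna_counts"], index_label="miRNA")
    write_fasta(outdir / "mirna.fa", bundle["mirnas"])
    write_fasta(outdir / "circ_seqs.fa", bundle["circ_seqs"])
    fixtures = bundle["fixtures"]
    pd.DataFrame({"miRNA": fixtures["reported"]}).to_csv(
        outdir / "reported_mir.tsv", sep="\t", index=False
    )
    rows = [(m, g) for m, gs in fixtures["mir2gene"].items() for g in gs]
    pd.DataFrame(rows, columns=["miRNA", "gene"]).to_csv(
        outdir / "mir2gene.tsv", sep="\t", index=False
    )
    write_gmt(outdir / "genesets.gmt", fixtures["gene_sets"])
    fixtures["cnv"].to_csv(outdir / "cnv.bed", sep="\t", header=False, index=False)
    write_cytoband(outdir / "cytoband.txt", fixtures["cytobands"])
    fixtures["feature_loci"].to_csv(outdir / "feature_loci.tsv", sep="\t", index=False)
    truth.to_json(outdir / "truth.json")
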