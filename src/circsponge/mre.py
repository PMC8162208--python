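"""miRNA response element (MRE) prediction and >=2-of-k consensus voting.

Two simplified predictors are implemented natively:

* a canonical seed-match scanner (6mer / 7mer-A1 / 7mer-m8 / 8mer classes),
* a local complementarity aligner with 5'-weighted duplex scoring.

Outputs of external thermodynamics-based predictors enter through TSV
ingestion.  The consensus rule is the pair-level vote: a (circRNA, miRNA)
pair is a candidate sponge interaction when at least ``min_votes`` distinct
predictors each report at least one site for it, regardless of whether the
sites coincide positionally.

Circular sequences are handled by scanning the doubled sequence and
deduplicating positions modulo the length, so sites spanning the back-splice
junction are found exactly once.
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import FormatError

RNA = set("ACGU")
_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}
SITE_TYPES = ("6mer", "7mer-A1", "7mer-m8", "8mer")


def to_rna(seq: str) -> str:
    """Uppercase and transcribe a DNA/RNA string to the RNA alphabet."""
    s = seq.upper().replace("T", "U")
    bad = set(s) - RNA
    if bad:
        raise ValueError(f"non-nucleotide characters {sorted(bad)} in sequence")
    return s


def rna_revcomp(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


@dataclass(frozen=True)
class MatureMiRNA:
    mirna_id: str
    sequence: str                  # RNA, 5'->3'

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", to_rna(self.sequence))
        if len(self.sequence) < 15:
            raise ValueError(f"{self.mirna_id}: mature miRNA shorter than 15 nt")

    @property
    def seed(self) -> str:
        """Positions 2-8 (1-based), the pairing-critical 5' region."""
        return self.sequence[1:8]


@dataclass(frozen=True)
class MRESite:
    circ_id: str
    mirna_id: str
    start: int                     # seed-core start on the circular sequence
    site_type: str
    predictor: str
    score: float = 0.0

    def __post_init__(self) -> None:
        if self.site_type not in SITE_TYPES:
            raise ValueError(f"unknown site type {self.site_type!r}")


@dataclass(frozen=True)
class ConsensusTarget:
    circ_id: str
    mirna_id: str
    votes: int
    predictors: frozenset[str]

    def __post_init__(self) -> None:
        if self.votes != len(self.predictors) or self.votes < 1:
            raise ValueError("votes must equal the number of distinct predictors (>= 1)")


# ---------------------------------------------------------------------------
# predictor 1: canonical seed scanner
# ---------------------------------------------------------------------------

def scan_seed_sites(circ_id: str, circ_seq: str, mirna: MatureMiRNA) -> list[MRESite]:
    """All canonical seed-match sites of one miRNA on one circular sequence.

    The target site layout (5'->3' on the target) is ``[m8][core 7..2][A1]``
    where the 6mer core is the reverse complement of miRNA positions 2-7.
    A match extended by complementarity to position 8 is 7mer-m8, by an
    adenine opposite position 1 is 7mer-A1, and by both is 8mer.  The
    reported ``start`` is the core start modulo the circle length.
    """
    s = to_rna(circ_seq)
    m = mirna.sequence
    L = len(s)
    if L < 7:
        return []
    core = rna_revcomp(m[1:7])
    m8_nt = _COMPLEMENT[m[7]]
    doubled = s + s
    sites = []
    for i in range(L):
        if doubled[i:i + 6] != core:
            continue
        has_m8 = doubled[i - 1] == m8_nt if i > 0 else s[-1] == m8_nt
        has_a1 = doubled[i + 6] == "A"
        if has_m8 and has_a1:
            site_type, score = "8mer", 8.0
        elif has_m8:
            site_type, score = "7mer-m8", 7.0
        elif has_a1:
            site_type, score = "7mer-A1", 7.0
        else:
            site_type, score = "6mer", 6.0
        sites.append(MRESite(circ_id, mirna.mirna_id, i, site_type, "seedscan", score))
    return sites


# ---------------------------------------------------------------------------
# predictor 2: local complementarity aligner
# ---------------------------------------------------------------------------

MATCH = 5.0
WOBBLE = 1.0
MISMATCH = -3.0
GAP = -8.0
SEED_WEIGHT = 2.0   # multiplier for miRNA positions 2-8


def _pair_score(t: str, m: str) -> float:
    """Duplex pair score for a target base vs a miRNA base (antiparallel)."""
    if _COMPLEMENT[m] == t:
        return MATCH
    if (m, t) in (("G", "U"), ("U", "G")):
        return WOBBLE
    return MISMATCH


def align_complementarity(
    circ_id: str,
    circ_seq: str,
    mirna: MatureMiRNA,
    score_threshold: float = 80.0,
) -> list[MRESite]:
    """Smith-Waterman-style local duplex alignment on the doubled sequence.

    The miRNA is aligned 3'->5' against the target 5'->3'; Watson-Crick pairs
    score +5, G:U wobbles +1, mismatches -3, gaps -8, and pairs involving
    miRNA seed positions 2-8 are doubled in weight.  Each local optimum with
    score >= ``score_threshold`` is reported once per circular position.
    """
    if score_threshold <= 0:
        raise ValueError("score_threshold must be positive")
    s = to_rna(circ_seq)
    L = len(s)
    if L == 0:
        return []
    doubled = s + s
    m = mirna.sequence[::-1]               # 3'->5', aligned left to right
    n_m = len(m)
    seed_positions = {len(mirna.sequence) - 1 - i for i in range(1, 8)}  # indices into m

    n_t = len(doubled)
    t_codes = np.fromiter(("ACGU".index(t) for t in doubled), dtype=np.int64, count=n_t)
    H = np.zeros((n_t + 1, n_m + 1))
    idx = np.arange(1, n_t + 1)
    for j in range(1, n_m + 1):
        w = SEED_WEIGHT if (j - 1) in seed_positions else 1.0
        col_scores = np.array([w * _pair_score(t, m[j - 1]) for t in "ACGU"])
        pair = col_scores[t_codes]
        # candidates not involving a vertical (target) gap, vectorized over i
        M = np.maximum(0.0, np.maximum(H[:-1, j - 1] + pair, H[1:, j - 1] + GAP))
        # vertical gaps: H[i,j] = max_{k<=i} M[k] + (i-k)*GAP, a prefix-max scan
        H[1:, j] = np.maximum.accumulate(M - idx * GAP) + idx * GAP
        np.maximum(H[1:, j], 0.0, out=H[1:, j])

    # best score whose alignment *ends* at target position i-1
    best_per_end = H.max(axis=1)
    sites: dict[int, tuple[float, int]] = {}
    for i in range(1, n_t + 1):
        score = best_per_end[i]
        if score < score_threshold:
            continue
        start = max(0, i - n_m)            # approximate alignment start
        pos = start % L
        if start >= L:                     # purely in the second copy: duplicate
            continue
        if pos not in sites or score > sites[pos][0]:
            sites[pos] = (score, start)
    out = []
    for pos, (score, _) in sorted(sites.items()):
        site_type = _classify_region(s, pos, mirna)
        out.append(MRESite(circ_id, mirna.mirna_id, pos, site_type, "compalign", float(score)))
    return _collapse_runs(out)


def _classify_region(s: str, pos: int, mirna: MatureMiRNA) -> str:
    """Best canonical class found near an alignment start, else 6mer."""
    window = (s + s)[pos:pos + len(mirna.sequence) + 2]
    hits = scan_seed_sites("_", window, mirna) if len(window) >= 8 else []
    order = {t: i for i, t in enumerate(SITE_TYPES)}
    if hits:
        return max(hits, key=lambda h: order[h.site_type]).site_type
    return "6mer"


def _collapse_runs(sites: list[MRESite]) -> list[MRESite]:
    """Merge adjacent-position reports of the same interaction, keep the best."""
    out: list[MRESite] = []
    for site in sites:
        if out and site.start - out[-1].start <= 2 and site.mirna_id == out[-1].mirna_id:
            if site.score > out[-1].score:
                out[-1] = site
        else:
            out.append(site)
    return out


# ---------------------------------------------------------------------------
# external predictor ingestion
# ---------------------------------------------------------------------------

def ingest_predictor_output(
    path: str | Path,
    predictor_name: str,
    known_circ: set[str] | None = None,
    known_mirna: set[str] | None = None,
) -> list[MRESite]:
    """Load an external predictor's TSV: circ id, miRNA id, position, score.

    Unknown circ/miRNA ids (against the optional known-id sets) are rejected
    with their row number; exact duplicate rows are collapsed with a warning.
    """
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["circ_id", "mirna_id", "position", "score"], comment="#")
    sites = []
    seen = set()
    n_dup = 0
    for row_no, row in enumerate(df.itertuples(index=False), 1):
        if known_circ is not None and row.circ_id not in known_circ:
            raise FormatError(f"{path}: row {row_no}: unknown circRNA id {row.circ_id!r}")
        if known_mirna is not None and row.mirna_id not in known_mirna:
            raise FormatError(f"{path}: row {row_no}: unknown miRNA id {row.mirna_id!r}")
        key = (row.circ_id, row.mirna_id, int(row.position), float(row.score))
        if key in seen:
            n_dup += 1
            continue
        seen.add(key)
        sites.append(
            MRESite(row.circ_id, row.mirna_id, int(row.position), "6mer",
                    predictor_name, float(row.score))
        )
    if n_dup:
        warnings.warn(f"{path}: collapsed {n_dup} duplicate rows", stacklevel=2)
    return sites


# ---------------------------------------------------------------------------
# consensus and network
# ---------------------------------------------------------------------------

def consensus_vote(
    site_lists: Mapping[str, Sequence[MRESite]], min_votes: int = 2
) -> list[ConsensusTarget]:
    """Pair-level consensus: keep pairs reported by >= ``min_votes`` predictors."""
    if min_votes > len(site_lists):
        raise ValueError(
            f"min_votes={min_votes} exceeds the {len(site_lists)} predictors supplied"
        )
    votes: dict[tuple[str, str], set[str]] = defaultdict(set)
    for predictor, sites in site_lists.items():
        for site in sites:
            votes[(site.circ_id, site.mirna_id)].add(predictor)
    out = [
        ConsensusTarget(circ, mirna, len(preds), frozenset(preds))
        for (circ, mirna), preds in sorted(votes.items())
        if len(preds) >= min_votes
    ]
    return out


def build_network(
    consensus: Sequence[ConsensusTarget], path: str | Path | None = None
) -> pd.DataFrame:
    """Edge table (circ, miRNA, votes) for the sponge interaction network."""
    df = pd.DataFrame(
        [(c.circ_id, c.mirna_id, c.votes, ",".join(sorted(c.predictors))) for c in consensus],
        columns=["circ_id", "mirna_id", "votes", "predictors"],
    )
    if path is not None:
        df.to_csv(path, sep="\t", index=False)
    return df
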