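"""Three-way evidence integration and pathway enrichment.

A miRNA is *eligible* as a sponge target when three independent lines of
evidence coincide: it is significantly differentially expressed (SDE)
between resistant and sensitive cells, it is literature-reported as
chemotherapy-associated (the Reported list), and it is consensus-predicted
(>= 2 predictors) to bind at least one candidate circRNA.  Target genes of
the eligible miRNAs are then tested for pathway enrichment with the
upper-tail hypergeometric test, BH-corrected across the tested sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import GeneSet
from .mre import ConsensusTarget


class IntegrityError(RuntimeError):
    """Cross-table inconsistency (e.g. an eligible miRNA missing from DE)."""


@dataclass
class EvidenceRecord:
    mirna_id: str
    in_sde: bool
    in_reported: bool
    predicted_circ_targets: frozenset[str]
    eligible: bool


@dataclass(frozen=True)
class EnrichmentRecord:
    pathway_id: str
    name: str
    k: int       # overlap
    n: int       # query size (within universe)
    K: int       # set size (within universe)
    N: int       # universe size
    p_value: float
    q_value: float


def normalize_mirna_id(mirna_id: str) -> str:
    """Exact-string matching after lowercasing and trimming the 'hsa-' prefix.

    Arm suffixes (-3p/-5p) are significant and never collapsed.
    """
    s = mirna_id.strip().lower()
    if s.startswith("hsa-"):
        s = s[4:]
    return s


def _dedup(ids: Iterable[str], label: str) -> list[str]:
    norm = [normalize_mirna_id(i) for i in ids]
    if len(set(norm)) != len(norm):
        warnings.warn(f"duplicate miRNA ids in {label} set; deduplicated", stacklevel=3)
    return sorted(set(norm))


def three_way_overlap(
    sde_set: Iterable[str],
    reported_set: Iterable[str],
    predicted_pairs: Iterable[tuple[str, str]] | Mapping[str, Iterable[str]],
) -> tuple[dict[str, int], list[EvidenceRecord]]:
    """All 7 Venn region counts plus one EvidenceRecord per miRNA.

    ``predicted_pairs`` is either an iterable of (mirna, circ) pairs or a
    mapping mirna -> circ ids.  Eligibility is the triple intersection.
    """
    sde = set(_dedup(sde_set, "SDE"))
    reported = set(_dedup(reported_set, "Reported"))
    pred_map: dict[str, set[str]] = {}
    if isinstance(predicted_pairs, Mapping):
        items = [(m, c) for m, cs in predicted_pairs.items() for c in cs]
    else:
        items = list(predicted_pairs)
    for mirna, circ in items:
        pred_map.setdefault(normalize_mirna_id(mirna), set()).add(circ)
    predicted = set(pred_map)

    venn = {
        "sde_only": len(sde - reported - predicted),
        "reported_only": len(reported - sde - predicted),
        "predicted_only": len(predicted - sde - reported),
        "sde_reported": len((sde & reported) - predicted),
        "sde_predicted": len((sde & predicted) - reported),
        "reported_predicted": len((reported & predicted) - sde),
        "triple": len(sde & reported & predicted),
    }
    records = [
        EvidenceRecord(
            mirna_id=m,
            in_sde=m in sde,
            in_reported=m in reported,
            predicted_circ_targets=frozenset(pred_map.get(m, ())),
            eligible=(m in sde and m in reported and m in pred_map),
        )
        for m in sorted(sde | reported | predicted)
    ]
    return venn, records


def eligible_table(
    evidence: Sequence[EvidenceRecord],
    de: pd.DataFrame,
    consensus: Sequence[ConsensusTarget],
) -> pd.DataFrame:
    """Report table for eligible miRNAs: log2FC, P and circRNA targets.

    Rows are sorted by |log2FC| descending.  Raises
    :class:`IntegrityError` when an eligible miRNA is missing from the DE
    table or its DE record is not flagged significant.
    """
    de_norm = de.copy()
    de_norm.index = [normalize_mirna_id(i) for i in de.index]
    targets: dict[str, set[str]] = {}
    for c in consensus:
        targets.setdefault(normalize_mirna_id(c.mirna_id), set()).add(c.circ_id)
    rows = []
    for rec in evidence:
        if not rec.eligible:
            continue
        if rec.mirna_id not in de_norm.index:
            raise IntegrityError(f"eligible miRNA {rec.mirna_id} missing from DE table")
        hit = de_norm.loc[rec.mirna_id]
        if "sde" in de_norm.columns and not bool(hit["sde"]):
            raise IntegrityError(
                f"eligible miRNA {rec.mirna_id} is not flagged SDE in the DE table"
            )
        rows.append(
            {
                "miRNA": rec.mirna_id,
                "log2FC": float(hit["log2FoldChange"]),
                "pvalue": float(hit["pvalue"]),
                "circRNA_targets": ",".join(sorted(targets.get(rec.mirna_id, rec.predicted_circ_targets))),
            }
        )
    df = pd.DataFrame(rows, columns=["miRNA", "log2FC", "pvalue", "circRNA_targets"])
    if len(df):
        df = df.reindex(df["log2FC"].abs().sort_values(ascending=False).index)
    return df.reset_index(drop=True)


def mirna_target_genes(
    eligible: Iterable[str], mapping: Mapping[str, Iterable[str]] | pd.DataFrame
) -> tuple[dict[str, list[str]], set[str], list[str]]:
    """Per-miRNA target gene lists and the pooled unique query set.

    ``mapping`` is either miRNA -> genes or a two-column (miRNA, gene)
    DataFrame.  Eligible miRNAs absent from the mapping are excluded with a
    warning and returned in the third element.
    """
    if isinstance(mapping, pd.DataFrame):
        mp: dict[str, list[str]] = {}
        for mirna, gene in mapping.itertuples(index=False):
            mp.setdefault(normalize_mirna_id(str(mirna)), []).append(str(gene))
    else:
        mp = {normalize_mirna_id(m): list(gs) for m, gs in mapping.items()}
    per_mirna: dict[str, list[str]] = {}
    missing: list[str] = []
    for m in eligible:
        key = normalize_mirna_id(m)
        if key in mp:
            per_mirna[key] = sorted(set(mp[key]))
        else:
            missing.append(key)
    if missing:
        warnings.warn(f"eligible miRNAs absent from target mapping: {missing}", stacklevel=2)
    pooled = {g for gs in per_mirna.values() for g in gs}
    return per_mirna, pooled, missing


def hypergeom_enrich(
    query_genes: Iterable[str],
    gene_sets: Sequence[GeneSet],
    universe: Iterable[str] | None = None,
    q_thresh: float = 0.01,
) -> pd.DataFrame:
    """Upper-tail hypergeometric pathway enrichment with BH correction.

    ``P = P[X >= k]`` for ``X ~ Hypergeom(N, K, n)`` where N is the universe
    size, K the set size within the universe, n the query size within the
    universe and k the overlap.  The universe defaults to all genes appearing
    in the gene-set collection; sets and query are intersected with it.
    Records with ``k = 0`` get P = 1.
    """
    if universe is None:
        uni = {g for s in gene_sets for g in s.genes}
    else:
        uni = set(universe)
    if not uni:
        raise ValueError("empty gene universe")
    query = set(query_genes) & uni
    records = []
    for s in gene_sets:
        members = s.genes & uni
        k = len(query & members)
        K, n, N = len(members), len(query), len(uni)
        p = 1.0 if k == 0 else float(stats.hypergeom.sf(k - 1, N, K, n))
        records.append((s.set_id, s.name, k, n, K, N, p))
    df = pd.DataFrame(
        records, columns=["pathway_id", "name", "k", "n", "K", "N", "p_value"]
    )
    df["q_value"] = bh_adjust_series(df["p_value"])
    df["significant"] = df["q_value"] < q_thresh
    return df.sort_values(["p_value", "pathway_id"]).reset_index(drop=True)


def bh_adjust_series(p: pd.Series) -> pd.Series:
    from .de import bh_adjust

    return pd.Series(bh_adjust(p.to_numpy()), index=p.index)
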