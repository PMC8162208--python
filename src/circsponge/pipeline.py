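"""End-to-end pipeline driver over the synthetic study.

Stages run in dependency order: simulate -> detect -> signatures -> MRE
consensus -> miRNA DE -> evidence integration -> genomic regions.  The
result object carries every intermediate table plus a manifest (record
counts per stage, thresholds, seed, input digests) so reruns under the same
configuration are byte-comparable.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import de as de_mod
from . import detect, evidence, mre, regions, signatures
from .simulate import SimConfig, TruthSet, simulate_all


@dataclass
class PipelineConfig:
    """Thresholds and toggles for a full run; defaults mirror the study rules."""

    seed: int = 0
    anchor_min: int = 10
    min_reads: int = 2
    min_samples: int = 2
    min_votes: int = 2
    align_threshold: float = 80.0
    lfc_thresh: float = 1.0
    p_thresh: float = 0.05
    q_thresh: float = 0.01
    min_classes: int = 2
    sim: SimConfig = field(default_factory=SimConfig)

    def __post_init__(self) -> None:
        if self.anchor_min < 8:
            raise ValueError("anchor_min must be >= 8")
        if self.min_votes < 1:
            raise ValueError("min_votes must be >= 1")
        self.sim.seed = self.seed
        self.sim.anchor = self.anchor_min


@dataclass
class PipelineResult:
    truth: TruthSet
    bundle: dict
    calls: list
    specificity: list
    shared: dict
    length_summary: dict
    consensus: list
    de: pd.DataFrame
    de_summary: de_mod.DESummary
    venn: dict
    evidence: list
    eligible: pd.DataFrame
    enrichment: pd.DataFrame
    region_calls: list
    manifest: dict


def run_pipeline(cfg: PipelineConfig, outdir: str | Path | None = None) -> PipelineResult:
    """Execute every stage on a synthetic study generated under cfg.seed."""
    outpath = Path(outdir) if outdir is not None else None
    bundle, truth = simulate_all(cfg.sim, outpath / "inputs" if outpath else None)
    manifest: dict = {"seed": cfg.seed, "thresholds": {
        "anchor_min": cfg.anchor_min, "min_reads": cfg.min_reads,
        "min_samples": cfg.min_samples, "min_votes": cfg.min_votes,
        "lfc_thresh": cfg.lfc_thresh, "p_thresh": cfg.p_thresh,
        "q_thresh": cfg.q_thresh, "min_classes": cfg.min_classes,
    }, "stages": {}}

    def log(stage: str, n_in: int, n_out: int) -> None:
        manifest["stages"][stage] = {"in": n_in, "out": n_out}

    # --- detection ---------------------------------------------------------
    junctions = detect.split_align_backsplice(
        bundle["reads"], bundle["genome"], bundle["annotation"], cfg.anchor_min
    )
    calls = detect.annotate_exonic(junctions, bundle["annotation"])
    calls = detect.filter_high_confidence(calls, cfg.min_reads, cfg.min_samples)
    calls = detect.compute_srpbm(calls, bundle["samples"])
    log("detect", sum(len(r) for r in bundle["reads"].values()), len(calls))

    # --- signatures --------------------------------------------------------
    spec_records = signatures.call_group_specific(calls, bundle["samples"])
    shared = signatures.shared_fraction(calls, bundle["samples"])
    length_summary = signatures.length_distribution(calls)
    log("signatures", len(calls), len(spec_records))

    # --- MRE consensus -----------------------------------------------------
    mirnas = {mid: mre.MatureMiRNA(mid, seq) for mid, seq in bundle["mirnas"].items()}
    seed_sites, align_sites = [], []
    for circ_id, seq in bundle["circ_seqs"].items():
        for mirna in mirnas.values():
            seed_sites.extend(mre.scan_seed_sites(circ_id, seq, mirna))
            align_sites.extend(
                mre.align_complementarity(circ_id, seq, mirna, cfg.align_threshold)
            )
    consensus = mre.consensus_vote(
        {"seedscan": seed_sites, "compalign": align_sites}, cfg.min_votes
    )
    log("mre", len(seed_sites) + len(align_sites), len(consensus))

    # --- miRNA DE ----------------------------------------------------------
    groups = pd.Series({m.sample_id: m.group for m in bundle["samples"]})
    de_res = de_mod.nb_wald_test(bundle["mirna_counts"], groups)
    summary = de_mod.call_sde(de_res, cfg.lfc_thresh, cfg.p_thresh)
    de_res = de_mod.de_table(de_res, summary)
    log("de", len(de_res), len(summary.sde))

    # --- evidence integration ---------------------------------------------
    fixtures = bundle["fixtures"]
    pairs = [(c.mirna_id, c.circ_id) for c in consensus]
    venn, ev_records = evidence.three_way_overlap(summary.sde, fixtures["reported"], pairs)
    eligible_df = evidence.eligible_table(ev_records, de_res, consensus)
    per_mirna, pooled, _ = evidence.mirna_target_genes(
        eligible_df["miRNA"].tolist(), fixtures["mir2gene"]
    )
    enrichment = evidence.hypergeom_enrich(pooled, fixtures["gene_sets"], q_thresh=cfg.q_thresh)
    log("integrate", len(ev_records), int(venn["triple"]))

    # --- genomic regions ---------------------------------------------------
    features = regions.features_from_table(fixtures["feature_loci"])
    segments = regions.segments_from_bed(fixtures["cnv"])
    region_calls = regions.region_summary(features, fixtures["cytobands"], segments, cfg.min_classes)
    log("regions", len(features), len(region_calls))

    result = PipelineResult(
        truth=truth, bundle=bundle, calls=calls, specificity=spec_records,
        shared=shared, length_summary=length_summary, consensus=consensus,
        de=de_res, de_summary=summary, venn=venn, evidence=ev_records,
        eligible=eligible_df, enrichment=enrichment, region_calls=region_calls,
        manifest=manifest,
    )
    if outpath is not None:
        write_outputs(result, outpath)
    return result


# ---------------------------------------------------------------------------
# output writing
# ---------------------------------------------------------------------------

def calls_table(calls) -> pd.DataFrame:
    rows = []
    for c in calls:
        j = c.junction
        row = {
            "circ_id": c.circ_id, "chrom": j.chrom, "start": j.acceptor_pos,
            "end": j.donor_pos, "strand": j.strand, "gene": c.gene_id,
            "exon_first": c.exon_run[0], "exon_last": c.exon_run[1],
            "spliced_length": c.spliced_length,
        }
        for s, v in sorted(c.counts.items()):
            row[f"count_{s}"] = v
        for s, v in sorted(c.srpbm.items()):
            row[f"srpbm_{s}"] = v
        rows.append(row)
    return pd.DataFrame(rows)


def write_outputs(result: PipelineResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    calls_table(result.calls).to_csv(outdir / "circ_calls.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {
                "circ_id": r.circ_id, "specific_to": r.specific_to,
                "n_detected": len(r.detected_in), "sum_srpbm": r.sum_srpbm,
                "detection_frequency": r.detection_frequency,
            }
            for r in result.specificity
        ]
    ).to_csv(outdir / "specificity.tsv", sep="\t", index=False)
    ranked = signatures.rank_by_abundance(result.specificity)
    for group, df in ranked.items():
        df.to_csv(outdir / f"top10_{group}.tsv", sep="\t", index=False)
    result.length_summary["histogram"].to_csv(outdir / "length_hist.tsv", sep="\t", index=False)
    mre.build_network(result.consensus, outdir / "network.edgelist")
    result.de.to_csv(outdir / "de_results.tsv", sep="\t", index_label="miRNA")
    pd.DataFrame([result.venn]).to_csv(outdir / "venn_counts.tsv", sep="\t", index=False)
    result.eligible.to_csv(outdir / "eligible_table.tsv", sep="\t", index=False)
    result.enrichment.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
    regions.region_table(result.region_calls).to_csv(outdir / "region_calls.tsv", sep="\t", index=False)
    manifest = dict(result.manifest)
    manifest["output_digests"] = {
        p.name: hashlib.sha256(p.read_bytes()).hexdigest()
        for p in sorted(outdir.glob("*.tsv"))
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
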