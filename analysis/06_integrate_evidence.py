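#!/usr/bin/env python
"""Three-way intersection of SDE, literature-Reported and consensus-Predicted
miRNA sets; eligible-miRNA table; hypergeometric KEGG-style enrichment of
the eligible miRNAs' target genes (Q < 0.01).  Writes venn_counts.tsv,
eligible_table.tsv and enrichment.tsv."""

from pathlib import Path

import pandas as pd

from circsponge import evidence
from circsponge.io import read_gmt
from circsponge.mre import ConsensusTarget

BASE = Path(__file__).resolve().parents[1] / "results" / "analysis"


def main() -> None:
    inputs = BASE / "inputs"
    de_table = pd.read_csv(BASE / "de_results.tsv", sep="\t", index_col=0)
    sde = set(de_table.index[de_table["sde"]])
    reported = pd.read_csv(inputs / "reported_mir.tsv", sep="\t")["miRNA"].tolist()
    cons_df = pd.read_csv(BASE / "consensus_targets.tsv", sep="\t")
    consensus = [
        ConsensusTarget(r.circ_id, r.mirna_id, int(r.votes),
                        frozenset(str(r.predictors).split(",")))
        for r in cons_df.itertuples(index=False)
    ]
    pairs = [(c.mirna_id, c.circ_id) for c in consensus]

    venn, records = evidence.three_way_overlap(sde, reported, pairs)
    pd.DataFrame([venn]).to_csv(BASE / "venn_counts.tsv", sep="\t", index=False)
    eligible = evidence.eligible_table(records, de_table, consensus)
    eligible.to_csv(BASE / "eligible_table.tsv", sep="\t", index=False)

    mapping = pd.read_csv(inputs / "mir2gene.tsv", sep="\t")
    per_mirna, pooled, missing = evidence.mirna_target_genes(eligible["miRNA"], mapping)
    gene_sets = read_gmt(inputs / "genesets.gmt")
    enrich = evidence.hypergeom_enrich(pooled, gene_sets)
    enrich.to_csv(BASE / "enrichment.tsv", sep="\t", index=False)

    print(f"Venn: SDE={len(sde)}, Reported={len(set(reported))}, "
          f"Predicted pairs={len(pairs)}; triple intersection={venn['triple']}")
    print(f"{len(eligible)} eligible sponge miRNAs "
          f"(top |log2FC|: {eligible.iloc[0]['miRNA']} {eligible.iloc[0]['log2FC']:+.2f})")
    sig = enrich[enrich["significant"]]
    print(f"{len(sig)} pathway(s) enriched at Q<0.01 over {len(pooled)} pooled target genes; "
          f"best: {enrich.iloc[0]['pathway_id']} (P={enrich.iloc[0]['p_value']:.2e})")


if __name__ == "__main__":
    main()
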