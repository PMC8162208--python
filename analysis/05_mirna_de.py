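#!/usr/bin/env python
"""Negative-binomial differential expression of the miRNA count matrix
(resistant vs sensitive, both backgrounds pooled): median-of-ratios size
factors, method-of-moments dispersion, Wald test, BH adjustment, and the
SDE call (|log2FC| > 1, raw P < 0.05).  Writes de_results.tsv."""

from pathlib import Path

import pandas as pd

from circsponge import de
from circsponge.io import read_samples, read_tsv_matrix

BASE = Path(__file__).resolve().parents[1] / "results" / "analysis"


def main() -> None:
    inputs = BASE / "inputs"
    counts = read_tsv_matrix(inputs / "mirna_counts.tsv")
    samples = read_samples(inputs / "samples.tsv")
    groups = pd.Series({m.sample_id: m.group for m in samples})
    res = de.nb_wald_test(counts, groups)
    summary = de.call_sde(res)
    table = de.de_table(res, summary)
    table.to_csv(BASE / "de_results.tsv", sep="\t", index_label="miRNA")
    print(f"{len(res)} miRNAs tested; {len(summary.sde)} SDE "
          f"({summary.n_up} up-regulated, {summary.n_down} down-regulated)")
    top = table[table["sde"]].reindex(
        table[table["sde"]]["pvalue"].sort_values().index
    ).head(3)
    for mirna, row in top.iterrows():
        print(f"  {mirna}: log2FC={row['log2FoldChange']:+.2f}, P={row['pvalue']:.2e}")


if __name__ == "__main__":
    main()
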