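#!/usr/bin/env python
"""Co-locate differential RNA features with CNV segments per cytoband and
rank multi-level hotspots (>= 2 RNA classes concordantly up in an amplified
band).  Writes region_calls.tsv and a per-chromosome track plot."""

from pathlib import Path

import pandas as pd

from circsponge import regions
from circsponge.io import read_bed, read_cytoband

BASE = Path(__file__).resolve().parents[1] / "results" / "analysis"


def main() -> None:
    inputs = BASE / "inputs"
    features = regions.features_from_table(pd.read_csv(inputs / "feature_loci.tsv", sep="\t"))
    segments = regions.segments_from_bed(read_bed(inputs / "cnv.bed"))
    cytobands = read_cytoband(inputs / "cytoband.txt")
    calls = regions.region_summary(features, cytobands, segments, min_classes=2)
    regions.region_table(calls).to_csv(BASE / "region_calls.tsv", sep="\t", index=False)
    regions.plot_tracks(features, segments, cytobands, str(BASE / "tracks.png"))
    if calls:
        top = calls[0]
        states = "; ".join(f"{k}:{','.join(v)}" for k, v in sorted(top.cnv_states.items()))
        print(f"top region: {top.chrom} {top.band_range} "
              f"(score={top.score}, {top.n_features} features, CNV {states})")
    else:
        print("no region reached the concordance threshold")
    print(f"{len(calls)} region call(s) -> {BASE / 'region_calls.tsv'}; "
          f"track plot -> {BASE / 'tracks.png'}")


if __name__ == "__main__":
    main()
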