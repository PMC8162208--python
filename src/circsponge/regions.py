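"""CNV / multi-RNA genomic co-location per cytoband.

Differential RNA features (mRNA, lncRNA, circRNA, miRNA loci with an
up/down/group-specific direction) are mapped onto cytobands, overlapped with
copy-number segments, and summarized per band run.  A band's concordance
score is the number of RNA classes concordantly over-expressed (up or
resistant-specific) in an amplified band; contiguous qualifying bands are
merged into one region call.  The score is an explicit operationalization of
"a region dominated by DNA amplification and RNA overexpression" -- no
formal criterion exists for that phrase, so the threshold is configurable.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd
from intervaltree import IntervalTree

RNA_CLASSES = ("mRNA", "lncRNA", "circRNA", "miRNA")
DIRECTIONS = ("up", "down", "specific-resistant", "specific-sensitive")
UPWARD = {"up", "specific-resistant"}


@dataclass(frozen=True)
class FeatureLocus:
    feature_id: str
    rna_class: str
    chrom: str
    start: int
    end: int
    direction: str

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"{self.feature_id}: end <= start")
        if self.rna_class not in RNA_CLASSES:
            raise ValueError(f"{self.feature_id}: unknown RNA class {self.rna_class!r}")
        if self.direction not in DIRECTIONS:
            raise ValueError(f"{self.feature_id}: unknown direction {self.direction!r}")


@dataclass(frozen=True)
class CNVSegment:
    cell_line: str
    chrom: str
    start: int
    end: int
    state: str    # amplification | deletion | neutral

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("CNV segment end <= start")
        if self.state not in ("amplification", "deletion", "neutral"):
            raise ValueError(f"unknown CNV state {self.state!r}")


@dataclass
class RegionCall:
    chrom: str
    band_range: str                      # e.g. "q21.1-q21.2"
    bands: tuple[str, ...]
    class_counts: dict                   # rna_class -> {"up": int, "down": int}
    cnv_states: dict                     # cell_line -> set of states in region
    score: int
    n_features: int


def features_from_table(df: pd.DataFrame) -> list[FeatureLocus]:
    return [
        FeatureLocus(str(r.feature), str(r.rna_class), str(r.chrom), int(r.start),
                     int(r.end), str(r.direction))
        for r in df.itertuples(index=False)
    ]


def segments_from_bed(df: pd.DataFrame) -> list[CNVSegment]:
    """CNV BED columns: chrom, start, end, cell_line, state."""
    cols = list(df.columns)
    return [
        CNVSegment(str(row[cols[3]]), str(row[cols[0]]), int(row[cols[1]]),
                   int(row[cols[2]]), str(row[cols[4]]))
        for _, row in df.iterrows()
    ]


def _band_trees(cytobands: pd.DataFrame) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    prev: dict[str, int] = {}
    for row in cytobands.sort_values(["chrom", "start"]).itertuples(index=False):
        if row.chrom in prev and row.start < prev[row.chrom]:
            raise ValueError(f"cytobands overlap on {row.chrom} near {row.start}")
        prev[row.chrom] = row.end
        trees[row.chrom].addi(int(row.start), int(row.end), str(row.band))
    return dict(trees)


def map_to_cytobands(
    features: Sequence[FeatureLocus], cytobands: pd.DataFrame
) -> pd.DataFrame:
    """Assign each feature every band it overlaps (half-open intervals).

    Features beyond any band of their chromosome are reported with band None
    (and a warning would be redundant: they appear in the output unassigned).
    """
    trees = _band_trees(cytobands)
    rows = []
    for f in features:
        tree = trees.get(f.chrom)
        hits = sorted(tree.overlap(f.start, f.end)) if tree is not None else []
        if not hits:
            rows.append((f.feature_id, f.rna_class, f.chrom, f.start, f.end, f.direction, None))
        for iv in hits:
            rows.append((f.feature_id, f.rna_class, f.chrom, f.start, f.end, f.direction, iv.data))
    return pd.DataFrame(
        rows, columns=["feature", "rna_class", "chrom", "start", "end", "direction", "band"]
    )


def overlap_cnv(
    features: Sequence[FeatureLocus], segments: Sequence[CNVSegment]
) -> pd.DataFrame:
    """Per-feature CNV state per cell line: state of any overlapping segment.

    A feature overlapping both amplification and deletion segments of one
    cell line is labeled "mixed"; no overlap means "neutral".
    """
    trees: dict[tuple[str, str], IntervalTree] = defaultdict(IntervalTree)
    cell_lines = sorted({s.cell_line for s in segments})
    for s in segments:
        trees[(s.cell_line, s.chrom)].addi(s.start, s.end, s.state)
    rows = []
    for f in features:
        states = {}
        for cl in cell_lines:
            tree = trees.get((cl, f.chrom))
            hit_states = {iv.data for iv in tree.overlap(f.start, f.end)} if tree else set()
            hit_states.discard("neutral")
            if not hit_states:
                states[cl] = "neutral"
            elif len(hit_states) == 1:
                states[cl] = next(iter(hit_states))
            else:
                states[cl] = "mixed"
        rows.append({"feature": f.feature_id, **states})
    return pd.DataFrame(rows)


def region_summary(
    features: Sequence[FeatureLocus],
    cytobands: pd.DataFrame,
    segments: Sequence[CNVSegment],
    min_classes: int = 2,
) -> list[RegionCall]:
    """Ranked multi-level hotspot calls.

    Per band: count up/down features per RNA class and collect CNV states
    overlapping the band; score = number of RNA classes with >= 1 upward
    feature, counted only when the band is amplified in >= 1 cell line.
    Adjacent qualifying bands merge into one region; regions are ranked by
    score (recomputed over the merged span) then feature count, both
    descending, then (chrom, band) for determinism.
    """
    assigned = map_to_cytobands(features, cytobands)
    assigned = assigned[assigned["band"].notna()]

    seg_trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for s in segments:
        seg_trees[s.chrom].addi(s.start, s.end, (s.cell_line, s.state))

    band_order = cytobands.sort_values(["chrom", "start"]).reset_index(drop=True)
    band_info: list[dict] = []
    for idx, row in band_order.iterrows():
        sub = assigned[(assigned.chrom == row.chrom) & (assigned.band == row.band)]
        up_classes = set(sub.loc[sub.direction.isin(UPWARD), "rna_class"])
        cnv_states: dict[str, set] = defaultdict(set)
        for iv in seg_trees.get(row.chrom, IntervalTree()).overlap(int(row.start), int(row.end)):
            cl, state = iv.data
            cnv_states[cl].add(state)
        amplified = any("amplification" in s for s in cnv_states.values())
        score = len(up_classes) if amplified else 0
        band_info.append(
            {
                "chrom": row.chrom,
                "band": row.band,
                "features": sub,
                "up_classes": up_classes,
                "cnv_states": {k: set(v) for k, v in cnv_states.items()},
                "score": score,
            }
        )

    # merge contiguous qualifying bands per chromosome
    calls: list[RegionCall] = []
    run: list[dict] = []

    def flush(run: list[dict]) -> None:
        if not run:
            return
        feats = pd.concat([b["features"] for b in run]).drop_duplicates("feature")
        up_classes = set().union(*(b["up_classes"] for b in run))
        cnv_states: dict[str, set] = defaultdict(set)
        for b in run:
            for cl, sts in b["cnv_states"].items():
                cnv_states[cl] |= sts
        class_counts = {
            rc: {
                "up": int(feats[(feats.rna_class == rc) & feats.direction.isin(UPWARD)].shape[0]),
                "down": int(feats[(feats.rna_class == rc) & ~feats.direction.isin(UPWARD)].shape[0]),
            }
            for rc in RNA_CLASSES
        }
        bands = tuple(b["band"] for b in run)
        label = bands[0] if len(bands) == 1 else f"{bands[0]}-{bands[-1]}"
        calls.append(
            RegionCall(
                chrom=run[0]["chrom"],
                band_range=label,
                bands=bands,
                class_counts=class_counts,
                cnv_states={k: sorted(v) for k, v in cnv_states.items()},
                score=len(up_classes),
                n_features=int(feats.shape[0]),
            )
        )

    prev_chrom = None
    for info in band_info:
        qualifies = info["score"] >= min_classes
        if qualifies and run and info["chrom"] == prev_chrom:
            run.append(info)
        elif qualifies:
            flush(run)
            run = [info]
        else:
            flush(run)
            run = []
        prev_chrom = info["chrom"]
    flush(run)

    calls.sort(key=lambda c: (-c.score, -c.n_features, c.chrom, c.bands[0]))
    return calls


def plot_tracks(
    features: Sequence[FeatureLocus],
    segments: Sequence[CNVSegment],
    cytobands: pd.DataFrame,
    path: str,
) -> None:
    """Per-chromosome track plot: cytobands, CNV segments, RNA features."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    chroms = sorted(cytobands["chrom"].unique())
    fig, axes = plt.subplots(len(chroms), 1, figsize=(9, 2.2 * len(chroms)), squeeze=False)
    class_y = {rc: i for i, rc in enumerate(RNA_CLASSES)}
    for ax, chrom in zip(axes[:, 0], chroms):
        bands = cytobands[cytobands["chrom"] == chrom]
        for row in bands.itertuples(index=False):
            ax.axvspan(row.start, row.end, ymin=0.0, ymax=0.08,
                       color="0.8" if "pos" not in str(row.stain) else "0.5")
            ax.text((row.start + row.end) / 2, -0.55, str(row.band),
                    ha="center", fontsize=6)
        for s in segments:
            if s.chrom != chrom or s.state == "neutral":
                continue
            ax.hlines(4.6 if s.cell_line.endswith("F") else 4.9, s.start, s.end,
                      colors="red" if s.state == "amplification" else "blue", lw=3)
        for f in features:
            if f.chrom != chrom:
                continue
            ax.hlines(1 + class_y[f.rna_class], f.start, f.end,
                      colors="red" if f.direction in UPWARD else "blue", lw=4)
        ax.set_yticks([1 + v for v in class_y.values()] + [4.75])
        ax.set_yticklabels(list(class_y) + ["CNV"], fontsize=7)
        ax.set_ylim(-1, 5.5)
        ax.set_title(chrom, fontsize=9)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def region_table(calls: Sequence[RegionCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        rows.append(
            {
                "chrom": c.chrom,
                "band_range": c.band_range,
                "score": c.score,
                "n_features": c.n_features,
                "cnv_states": ";".join(f"{k}:{','.join(v)}" for k, v in sorted(c.cnv_states.items())),
                **{
                    f"{rc}_{d}": c.class_counts[rc][d]
                    for rc in RNA_CLASSES
                    for d in ("up", "down")
                },
            }
        )
    return pd.DataFrame(rows)
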