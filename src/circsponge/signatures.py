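"""Group-specific circRNA signatures and summary statistics.

A circRNA is "detected" in a sample when it has at least one unique
back-spliced read there; a circRNA is *specific* to the resistant (or
sensitive) group when its detection is confined to that group's samples.
Also provides abundance ranking, the cross-background shared fraction, the
spliced-length distribution, circular-vs-linear Pearson correlation, and
2^-ddCt relative quantification of qPCR validation data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .detect import CircRNACall
from .io import SampleMeta


@dataclass
class SpecificityRecord:
    circ_id: str
    detected_in: frozenset[str]
    specific_to: str               # "resistant" | "sensitive" | "none"
    sum_srpbm: float
    detection_frequency: float     # detected / samples of its (specific) group


@dataclass(frozen=True)
class QpcrMeasurement:
    """One qPCR replicate: target and endogenous-control Ct values."""

    target_ct: float
    reference_ct: float
    condition: str                 # "resistant" | "sensitive"
    replicate: int = 0

    def __post_init__(self) -> None:
        if not (math.isfinite(self.target_ct) and math.isfinite(self.reference_ct)):
            raise ValueError("Ct values must be finite")


def call_group_specific(
    calls: Sequence[CircRNACall], meta: Sequence[SampleMeta]
) -> list[SpecificityRecord]:
    """Partition calls into resistant-specific / sensitive-specific / none."""
    groups = {m.sample_id: m.group for m in meta}
    group_sizes = {
        g: sum(1 for m in meta if m.group == g) for g in ("resistant", "sensitive")
    }
    records = []
    for call in calls:
        unknown = set(call.counts) - set(groups)
        if unknown:
            raise ValueError(f"{call.circ_id}: samples {sorted(unknown)} missing from metadata")
        detected = frozenset(s for s, c in call.counts.items() if c >= 1)
        present = {groups[s] for s in detected}
        if present == {"resistant"}:
            specific = "resistant"
        elif present == {"sensitive"}:
            specific = "sensitive"
        else:
            specific = "none"
        denom = group_sizes[specific] if specific != "none" else len(meta)
        records.append(
            SpecificityRecord(
                circ_id=call.circ_id,
                detected_in=detected,
                specific_to=specific,
                sum_srpbm=float(sum(call.srpbm.values())) if call.srpbm else 0.0,
                detection_frequency=len(detected) / denom if denom else 0.0,
            )
        )
    return records


def rank_by_abundance(
    records: Sequence[SpecificityRecord], top_n: int = 10
) -> dict[str, pd.DataFrame]:
    """Top-N specifically expressed circRNAs per group by total SRPBM.

    Sort key: sum_srpbm descending, then detection_frequency descending, then
    circ id ascending -- a total order, so the result is stable under input
    permutation.
    """
    out = {}
    for group in ("resistant", "sensitive"):
        rows = [r for r in records if r.specific_to == group]
        rows.sort(key=lambda r: (-r.sum_srpbm, -r.detection_frequency, r.circ_id))
        out[group] = pd.DataFrame(
            [
                {
                    "circ_id": r.circ_id,
                    "sum_srpbm": r.sum_srpbm,
                    "detection_frequency": r.detection_frequency,
                    "n_samples_detected": len(r.detected_in),
                }
                for r in rows[:top_n]
            ]
        )
    return out


def shared_fraction(
    calls: Sequence[CircRNACall],
    meta: Sequence[SampleMeta],
    backgrounds: tuple[str, str] = ("MCF", "MDA"),
) -> dict:
    """Fraction of circRNAs detected in both cell backgrounds.

    Returns the percentage ``|both| / |either| * 100`` plus per-background
    totals, mirroring a two-set Venn over detection.
    """
    for bg in backgrounds:
        if not any(m.background == bg for m in meta):
            raise ValueError(f"background {bg!r} has no samples")
    bg_of = {m.sample_id: m.background for m in meta}
    sets: dict[str, set[str]] = {bg: set() for bg in backgrounds}
    for call in calls:
        for s, c in call.counts.items():
            if c >= 1 and bg_of.get(s) in sets:
                sets[bg_of[s]].add(call.circ_id)
    a, b = (sets[bg] for bg in backgrounds)
    union = a | b
    pct = 100.0 * len(a & b) / len(union) if union else 0.0
    return {
        "shared_pct": pct,
        "n_shared": len(a & b),
        "n_union": len(union),
        **{f"n_{bg}": len(sets[bg]) for bg in backgrounds},
    }


def length_distribution(
    calls: Sequence[CircRNACall], bin_width: int = 100
) -> dict:
    """Histogram of spliced lengths plus quantile-style summaries."""
    lengths = np.array([c.spliced_length for c in calls])
    if lengths.size == 0:
        return {"histogram": pd.DataFrame(columns=["bin_start", "bin_end", "count"]),
                "modal_bin": None, "fraction_below": lambda q: float("nan")}
    top = (int(lengths.max()) // bin_width + 1) * bin_width
    edges = np.arange(0, top + bin_width, bin_width)
    hist, _ = np.histogram(lengths, bins=edges)
    df = pd.DataFrame({"bin_start": edges[:-1], "bin_end": edges[1:], "count": hist})
    modal = df.loc[df["count"].idxmax()]

    def fraction_below(query: float) -> float:
        return float((lengths < query).mean())

    return {
        "histogram": df,
        "modal_bin": (int(modal.bin_start), int(modal.bin_end)),
        "fraction_below": fraction_below,
    }


def correlate_circ_linear(
    circ_expr: Sequence[float], linear_expr: Sequence[float]
) -> tuple[float, float]:
    """Pearson R and two-sided P (t distribution, n-2 df) for paired expression."""
    x = np.asarray(circ_expr, float)
    y = np.asarray(linear_expr, float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    if x.size < 3:
        raise ValueError("need n >= 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def ddct_fold_change(
    resistant: Iterable[QpcrMeasurement], sensitive: Iterable[QpcrMeasurement]
) -> tuple[float, float]:
    """Relative expression by the 2^-ddCt method.

    dCt = mean(target Ct) - mean(reference Ct) within each condition;
    ddCt = dCt_resistant - dCt_sensitive; returns ``(2**-ddCt, se)`` with the
    standard error propagated from the replicate scatter of per-replicate dCt
    values onto the fold-change scale.
    """
    res = list(resistant)
    sen = list(sensitive)
    if not res or not sen:
        raise ValueError("both conditions need >= 1 replicate")
    for m in res + sen:
        if m.reference_ct is None:
            raise ValueError("missing reference Ct")

    def dct_stats(ms: list[QpcrMeasurement]) -> tuple[float, float]:
        d = np.array([m.target_ct - m.reference_ct for m in ms])
        se = d.std(ddof=1) / math.sqrt(len(d)) if len(d) > 1 else 0.0
        return float(d.mean()), float(se)

    dct_r, se_r = dct_stats(res)
    dct_s, se_s = dct_stats(sen)
    ddct = dct_r - dct_s
    fold = 2.0 ** (-ddct)
    se_ddct = math.hypot(se_r, se_s)
    return fold, math.log(2.0) * fold * se_ddct
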