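"""Negative-binomial differential expression for miRNA count matrices.

The model follows the classic NB count-regression pipeline: median-of-ratios
size factors, method-of-moments per-feature dispersion, and a Wald test on
the log fold-change between the resistant and sensitive groups.  No
empirical-Bayes shrinkage of dispersions or fold-changes is applied, so the
statistics approximate, but do not reproduce, shrinkage-based packages.

Small-sample calibration: the Wald statistic is referred to a t distribution
with ``n1 + n2 - 2`` degrees of freedom rather than the normal, which keeps
the type-I error at the nominal level with 6-vs-6 designs (the plug-in
variance estimate is itself noisy at that n).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

DISPERSION_FLOOR = 1e-8
PSEUDOCOUNT = 0.5  # applied only when a group mean is exactly zero


@dataclass
class DESummary:
    sde: set[str]
    n_up: int
    n_down: int


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios normalization factors, one per sample.

    For each feature with a nonzero geometric mean across samples, the ratio
    count/geomean is formed; a sample's factor is the median of its ratios.
    Requires at least one feature with nonzero counts in every sample.
    """
    mat = counts.to_numpy(dtype=float)
    all_pos = (mat > 0).all(axis=1)
    if not all_pos.any():
        raise ValueError(
            "no feature has nonzero counts in all samples; median-of-ratios is "
            "undefined -- consider a pseudo-reference or count prefilter"
        )
    geo = np.exp(np.log(mat[all_pos]).mean(axis=1))
    ratios = mat[all_pos] / geo[:, None]
    factors = np.median(ratios, axis=0)
    return pd.Series(factors, index=counts.columns, name="size_factor")


def estimate_dispersion(
    counts: pd.DataFrame,
    groups: pd.Series | dict,
    factors: pd.Series | None = None,
) -> pd.Series:
    """Method-of-moments NB dispersion per feature on normalized counts.

    ``alpha = max(floor, (pooled within-group variance - mean) / mean^2)``.
    Features with zero mean are returned as NaN (untestable downstream).
    """
    if factors is None:
        factors = size_factors(counts)
    groups = pd.Series(groups)
    y = counts.to_numpy(float) / factors.to_numpy(float)[None, :]
    labels = groups.loc[counts.columns].to_numpy()
    uniq = np.unique(labels)
    if any((labels == g).sum() < 2 for g in uniq):
        raise ValueError("each group needs >= 2 replicates for dispersion estimation")
    ss = np.zeros(y.shape[0])
    df = 0
    for g in uniq:
        sub = y[:, labels == g]
        ss += ((sub - sub.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
        df += sub.shape[1] - 1
    var = ss / df
    mean = y.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (var - mean) / mean**2
    alpha = np.maximum(DISPERSION_FLOOR, alpha)
    alpha[mean == 0] = np.nan
    return pd.Series(alpha, index=counts.index, name="dispersion")


def nb_wald_test(
    counts: pd.DataFrame,
    groups: pd.Series | dict,
    factors: pd.Series | None = None,
    dispersions: pd.Series | None = None,
    test_group: str = "resistant",
    ref_group: str = "sensitive",
) -> pd.DataFrame:
    """Per-feature NB Wald test of resistant vs sensitive means.

    Returns a DataFrame with baseMean, log2FoldChange, lfcSE, stat, pvalue
    and qvalue (BH).  All-zero features are excluded from testing and from
    the BH family (their pvalue/qvalue are NaN).  Swapping the two group
    labels negates the fold-change and leaves P unchanged.
    """
    groups = pd.Series(groups)
    labels = groups.loc[counts.columns]
    for g in (test_group, ref_group):
        if (labels == g).sum() < 2:
            raise ValueError(f"group {g!r} needs >= 2 samples")
    if factors is None:
        factors = size_factors(counts)
    if dispersions is None:
        dispersions = estimate_dispersion(counts, groups, factors)

    y = counts.to_numpy(float) / factors.to_numpy(float)[None, :]
    mask_t = (labels == test_group).to_numpy()
    mask_r = (labels == ref_group).to_numpy()
    n_t, n_r = int(mask_t.sum()), int(mask_r.sum())
    m_t = y[:, mask_t].mean(axis=1)
    m_r = y[:, mask_r].mean(axis=1)
    alpha = dispersions.to_numpy(float)

    zero_either = (m_t == 0) | (m_r == 0)
    mt = np.where(zero_either, m_t + PSEUDOCOUNT, m_t)
    mr = np.where(zero_either, m_r + PSEUDOCOUNT, m_r)
    log2fc = np.log2(mt / mr)

    # asymptotic variance of log(mean) under NB(mu, alpha): (mu + alpha mu^2)/ (n mu^2)
    a = np.where(np.isnan(alpha), 0.0, alpha)
    var_log_t = (mt + a * mt**2) / (n_t * mt**2)
    var_log_r = (mr + a * mr**2) / (n_r * mr**2)
    se_ln = np.sqrt(var_log_t + var_log_r)
    stat = np.log(mt / mr) / se_ln
    df = n_t + n_r - 2
    pvalue = 2.0 * stats.t.sf(np.abs(stat), df)

    all_zero = counts.sum(axis=1).to_numpy() == 0
    pvalue = np.where(all_zero, np.nan, pvalue)
    qvalue = np.full_like(pvalue, np.nan)
    tested = ~np.isnan(pvalue)
    if tested.any():
        qvalue[tested] = bh_adjust(pvalue[tested])

    out = pd.DataFrame(
        {
            "baseMean": y.mean(axis=1),
            "log2FoldChange": log2fc,
            "lfcSE": se_ln / np.log(2),
            "stat": stat,
            "pvalue": pvalue,
            "qvalue": qvalue,
        },
        index=counts.index,
    )
    out.loc[all_zero, ["log2FoldChange", "lfcSE", "stat"]] = np.nan
    return out


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted P values (monotone, rank-preserving)."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def call_sde(
    de: pd.DataFrame, lfc_thresh: float = 1.0, p_thresh: float = 0.05
) -> DESummary:
    """Significantly differentially expressed call: |log2FC| > 1 and raw P < 0.05.

    The gate uses the raw P value; BH-adjusted Q is reported alongside in the
    DE table but does not enter the call.
    """
    ok = (de["pvalue"] < p_thresh) & (de["log2FoldChange"].abs() > lfc_thresh)
    ok = ok.fillna(False)
    sde = set(de.index[ok])
    n_up = int((ok & (de["log2FoldChange"] > lfc_thresh)).sum())
    n_down = int((ok & (de["log2FoldChange"] < -lfc_thresh)).sum())
    return DESummary(sde=sde, n_up=n_up, n_down=n_down)


def de_table(de: pd.DataFrame, summary: DESummary) -> pd.DataFrame:
    """Attach sde/direction columns for reporting."""
    out = de.copy()
    out["sde"] = out.index.isin(summary.sde)
    out["direction"] = np.where(
        out["log2FoldChange"] > 0, "up", np.where(out["log2FoldChange"] < 0, "down", "none")
    )
    out.loc[~out["sde"], "direction"] = "none"
    return out
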