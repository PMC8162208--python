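import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.stats.multitest import multipletests

from circsponge import de


def _nb_matrix(rng, n_feat, mean, alpha, n1=6, n2=6, lfc=0.0, n_de=None):
    """NB count matrix; the first ``n_de`` features carry the planted lfc.

    DE features are a minority (default 10%) so that median-of-ratios
    normalization is anchored by the unchanged majority, as in real designs.
    """
    r = 1.0 / alpha
    if n_de is None:
        n_de = n_feat if lfc == 0.0 else max(1, n_feat // 10)
    mu1 = np.full(n_feat, float(mean))
    mu2 = mu1.copy()
    mu2[:n_de] *= 2.0**lfc
    c1 = rng.negative_binomial(r, r / (r + mu1[:, None]), size=(n_feat, n1))
    c2 = rng.negative_binomial(r, r / (r + mu2[:, None]), size=(n_feat, n2))
    cols = [f"S{i}" for i in range(n1)] + [f"R{i}" for i in range(n2)]
    df = pd.DataFrame(np.hstack([c1, c2]), columns=cols)
    groups = pd.Series(["sensitive"] * n1 + ["resistant"] * n2, index=cols)
    return df, groups


class TestSizeFactors:
    def test_doubled_sample_ratio_two(self, rng):
        a = rng.integers(10, 100, size=50)
        df = pd.DataFrame({"A": a, "B": 2 * a})
        f = de.size_factors(df)
        assert f["B"] / f["A"] == pytest.approx(2.0)

    def test_identical_samples_all_one(self, rng):
        a = rng.integers(10, 100, size=50)
        df = pd.DataFrame({"A": a, "B": a, "C": a})
        assert np.allclose(de.size_factors(df), 1.0)

    def test_matches_brute_force_median_of_ratios(self, rng):
        df = pd.DataFrame(rng.integers(1, 500, size=(50, 6)),
                          columns=[f"s{i}" for i in range(6)])
        f = de.size_factors(df)
        mat = df.to_numpy(float)
        geo = np.exp(np.log(mat).mean(axis=1))
        for j, col in enumerate(df.columns):
            expected = np.median(mat[:, j] / geo)
            assert f[col] == pytest.approx(expected, rel=1e-12)

    def test_feature_permutation_invariant(self, rng):
        df = pd.DataFrame(rng.integers(1, 500, size=(40, 4)))
        perm = df.sample(frac=1, random_state=1)
        assert np.allclose(de.size_factors(df), de.size_factors(perm))

    def test_no_common_feature_raises(self):
        df = pd.DataFrame({"A": [0, 5], "B": [5, 0]})
        with pytest.raises(ValueError, match="pseudo-reference"):
            de.size_factors(df)


class TestDispersion:
    def test_poisson_counts_near_floor(self, rng):
        df, groups = _nb_matrix(rng, 2000, 500, 1e-9)  # effectively Poisson
        mu = np.full((2000, 12), 500.0)
        df = pd.DataFrame(rng.poisson(mu), columns=df.columns)
        alpha = de.estimate_dispersion(df, groups)
        assert np.nanmedian(alpha) < 0.01

    def test_recovers_planted_dispersion(self, rng):
        df, groups = _nb_matrix(rng, 2000, 500, 0.2)
        alpha = de.estimate_dispersion(df, groups)
        assert 0.1 <= np.nanmedian(alpha) <= 0.4

    def test_constant_counts_hit_floor(self):
        df = pd.DataFrame(np.full((3, 6), 7), columns=[f"s{i}" for i in range(6)])
        groups = pd.Series(["sensitive"] * 3 + ["resistant"] * 3, index=df.columns)
        alpha = de.estimate_dispersion(df, groups, pd.Series(1.0, index=df.columns))
        assert np.allclose(alpha, de.DISPERSION_FLOOR)

    def test_zero_mean_flagged_nan(self):
        arr = np.vstack([np.zeros(6, int), np.full(6, 10)])
        df = pd.DataFrame(arr, columns=[f"s{i}" for i in range(6)])
        groups = pd.Series(["sensitive"] * 3 + ["resistant"] * 3, index=df.columns)
        alpha = de.estimate_dispersion(df, groups, pd.Series(1.0, index=df.columns))
        assert np.isnan(alpha.iloc[0]) and not np.isnan(alpha.iloc[1])


class TestWald:
    def test_group_swap_antisymmetry(self, rng):
        df, groups = _nb_matrix(rng, 100, 300, 0.05, lfc=1.0)
        fwd = de.nb_wald_test(df, groups)
        rev = de.nb_wald_test(df, groups, test_group="sensitive", ref_group="resistant")
        assert np.allclose(fwd["log2FoldChange"], -rev["log2FoldChange"])
        assert np.allclose(fwd["pvalue"], rev["pvalue"])

    def test_all_zero_feature_excluded_from_family(self, rng):
        df, groups = _nb_matrix(rng, 20, 300, 0.05)
        df.iloc[0] = 0
        res = de.nb_wald_test(df, groups)
        assert np.isnan(res["pvalue"].iloc[0]) and np.isnan(res["qvalue"].iloc[0])
        assert res["pvalue"].iloc[1:].notna().all()

    def test_zero_group_mean_uses_pseudocount(self, rng):
        df, groups = _nb_matrix(rng, 5, 300, 0.05)
        df.loc[df.index[0], [c for c in df.columns if c.startswith("R")]] = 0
        res = de.nb_wald_test(df, groups)
        assert np.isfinite(res["log2FoldChange"].iloc[0])
        assert res["log2FoldChange"].iloc[0] < 0

    def test_planted_lfc_recovered(self, rng):
        df, groups = _nb_matrix(rng, 400, 500, 0.05, lfc=2.0, n_de=40)
        res = de.nb_wald_test(df, groups)
        err = np.median(np.abs(res["log2FoldChange"].iloc[:40] - 2.0))
        assert err <= 0.3

    def test_power_above_080_for_strong_effect(self, rng):
        df, groups = _nb_matrix(rng, 400, 200, 0.05, lfc=2.0, n_de=40)
        res = de.nb_wald_test(df, groups)
        summary = de.call_sde(res)
        hits = sum(1 for f in df.index[:40] if f in summary.sde)
        assert hits / 40 > 0.8

    def test_too_few_replicates_rejected(self, rng):
        df, groups = _nb_matrix(rng, 10, 100, 0.05, n1=1, n2=6)
        with pytest.raises(ValueError):
            de.nb_wald_test(df, groups)


class TestBH:
    def test_hand_evaluated_step_up(self):
        q = de.bh_adjust([0.01, 0.02, 0.03])
        assert np.allclose(q, [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert de.bh_adjust([0.2]) == pytest.approx([0.2])

    def test_all_ones_stay_one(self):
        assert np.allclose(de.bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_matches_brute_force_step_up(self, rng):
        for _ in range(20):
            p = rng.uniform(size=rng.integers(1, 60))
            q = de.bh_adjust(p)
            m = p.size
            brute = np.empty(m)
            order = np.argsort(p)
            for rank_pos, idx in enumerate(order, start=1):
                later = [p[j] * m / (list(order).index(j) + 1)
                         for j in order[rank_pos - 1:]]
                brute[idx] = min(1.0, min(later))
            assert np.allclose(q, brute, atol=1e-12)

    def test_matches_statsmodels(self, rng):
        p = rng.uniform(size=200)
        _, q_sm, _, _ = multipletests(p, method="fdr_bh")
        assert np.allclose(de.bh_adjust(p), q_sm, atol=1e-12)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            de.bh_adjust([0.5, 1.5])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=50))
    def test_properties_hold_for_arbitrary_p_vectors(self, p):
        q = de.bh_adjust(p)
        assert ((q >= 0) & (q <= 1)).all()
        # rank order preserved
        order_p = np.argsort(p, kind="mergesort")
        assert (np.diff(q[order_p]) >= -1e-15).all()
        _, q_sm, _, _ = multipletests(p, method="fdr_bh")
        assert np.allclose(q, q_sm, atol=1e-12)


class TestCallSde:
    def _records(self):
        return pd.DataFrame(
            {
                "log2FoldChange": [2.04, 0.9, -3.64, -1.05, 0.0],
                "pvalue": [5.51e-3, 1e-6, 1.95e-5, 0.2, 0.9],
                "qvalue": [0.01, 1e-5, 1e-4, 0.3, 0.95],
            },
            index=["miR-346", "miR-x", "miR-204-5p", "miR-877-3p", "miR-null"],
        )

    def test_rule_on_raw_p_and_lfc(self):
        summary = de.call_sde(self._records())
        assert summary.sde == {"miR-346", "miR-204-5p"}
        assert summary.n_up == 1 and summary.n_down == 1

    def test_fold_change_gate_blocks_significant_p(self):
        summary = de.call_sde(self._records())
        assert "miR-x" not in summary.sde

    def test_high_p_blocks_large_fold_change(self):
        summary = de.call_sde(self._records())
        assert "miR-877-3p" not in summary.sde


def test_agrees_with_independent_nb_glm_implementation(rng):
    """Cross-check against pyDESeq2 as an independent NB Wald pipeline.

    Exact equality is not expected (pyDESeq2 shrinks dispersions and fits a
    GLM); fold-change estimates should agree tightly and the strong-effect
    calls should coincide.
    """
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        from pydeseq2.dds import DeseqDataSet
        from pydeseq2.ds import DeseqStats

        df, groups = _nb_matrix(rng, 200, 500, 0.05, lfc=2.0, n_de=20)
        df.index = [f"f{i}" for i in range(len(df))]
        meta = pd.DataFrame({"condition": groups})
        dds = DeseqDataSet(counts=df.T, metadata=meta, design="~condition", quiet=True)
        dds.deseq2()
        stats = DeseqStats(
            dds, contrast=["condition", "resistant", "sensitive"], quiet=True
        )
        stats.summary()
        ref = stats.results_df

    ours = de.nb_wald_test(df, groups)
    corr = np.corrcoef(ref["log2FoldChange"], ours["log2FoldChange"])[0, 1]
    assert corr > 0.99
    ref_sde = set(
        ref.index[(ref["pvalue"] < 0.05) & (ref["log2FoldChange"].abs() > 1)]
    )
    ours_sde = de.call_sde(ours).sde
    planted = set(df.index[:20])
    assert planted <= ours_sde
    assert len(ours_sde & ref_sde) >= 0.9 * max(len(ours_sde), len(ref_sde))


def test_pipeline_determinism(rng):
    df, groups = _nb_matrix(rng, 60, 300, 0.05, lfc=1.0)
    a = de.nb_wald_test(df, groups)
    b = de.nb_wald_test(df.copy(), groups.copy())
    pd.testing.assert_frame_equal(a, b)
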