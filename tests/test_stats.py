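"""Normalization, PCA, and the rank-based testing layer."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from tiledc import (
    adjust_p,
    dunn_test,
    kruskal_wallis,
    log_normalize,
    normality_check,
    pca,
    size_factors,
)


class TestSizeFactors:
    def test_identical_columns_unit_factors(self):
        t = pd.DataFrame({"a": [1.0, 2, 3], "b": [1.0, 2, 3]})
        assert size_factors(t).tolist() == pytest.approx([1.0, 1.0])

    def test_doubled_column_closed_form(self):
        t = pd.DataFrame({"a": [1.0, 4, 10], "b": [2.0, 8, 20]})
        f = size_factors(t)
        assert f["a"] == pytest.approx(1 / np.sqrt(2))
        assert f["b"] == pytest.approx(np.sqrt(2))

    def test_zero_rows_ignored(self):
        t = pd.DataFrame({"a": [1.0, 0.0, 2.0], "b": [1.0, 100.0, 2.0]})
        assert size_factors(t).tolist() == pytest.approx([1.0, 1.0])

    def test_no_all_positive_row_rejected(self):
        t = pd.DataFrame({"a": [0.0, 1.0], "b": [1.0, 0.0]})
        with pytest.raises(ValueError):
            size_factors(t)

    def test_matches_deseq2_convention(self):
        # median-of-ratios on a small random table vs direct definition
        rng = np.random.default_rng(7)
        t = pd.DataFrame(rng.poisson(20.0, size=(50, 4)) + 1.0)
        f = size_factors(t)
        logg = np.log(t.to_numpy()).mean(axis=1)
        expect = [
            np.exp(np.median(np.log(t.to_numpy()[:, j]) - logg))
            for j in range(4)
        ]
        assert f.tolist() == pytest.approx(expect)


class TestLogNormalize:
    def test_values(self):
        t = pd.DataFrame({"a": [0.0, 1.0, 3.0]})
        f = pd.Series({"a": 1.0})
        out = log_normalize(t, f)
        assert out["a"].tolist() == pytest.approx([0.0, 1.0, 2.0])

    def test_factor_applied_before_log(self):
        t = pd.DataFrame({"a": [3.0]})
        f = pd.Series({"a": 2.0})
        assert log_normalize(t, f)["a"][0] == pytest.approx(np.log2(2.5))


class TestPCA:
    def test_identical_samples_identical_coordinates(self):
        rng = np.random.default_rng(1)
        col = rng.normal(size=30)
        t = pd.DataFrame({"a": col, "b": col, "c": col + rng.normal(size=30)})
        res = pca(t)
        np.testing.assert_allclose(
            res.coordinates.loc["a"], res.coordinates.loc["b"], atol=1e-10
        )

    def test_variance_fractions_non_increasing_and_bounded(self):
        rng = np.random.default_rng(2)
        t = pd.DataFrame(rng.normal(size=(40, 5)))
        res = pca(t)
        assert np.all(np.diff(res.explained) <= 1e-12)
        assert res.explained.sum() <= 1 + 1e-9

    def test_rank_one_table_pc1_explains_all(self):
        t = pd.DataFrame({"a": [1.0, 5, 5], "b": [2.0, 5, 5], "c": [4.0, 5, 5]})
        res = pca(t)
        assert res.explained[0] == pytest.approx(1.0)

    def test_reconstruction(self):
        rng = np.random.default_rng(3)
        t = pd.DataFrame(rng.normal(size=(20, 4)))
        res = pca(t)
        x = t.to_numpy()
        centered = (x - x.mean(axis=1, keepdims=True)).T
        recon = res.coordinates.to_numpy() @ res.loadings.T
        np.testing.assert_allclose(recon, centered, atol=1e-8)

    def test_sign_deterministic(self):
        rng = np.random.default_rng(4)
        t = pd.DataFrame(rng.normal(size=(25, 3)))
        a, b = pca(t), pca(t)
        np.testing.assert_allclose(
            a.coordinates.to_numpy(), b.coordinates.to_numpy()
        )
        for c in range(a.loadings.shape[1]):
            peak = np.argmax(np.abs(a.loadings[:, c]))
            assert a.loadings[peak, c] > 0

    def test_constant_table_rejected(self):
        t = pd.DataFrame({"a": [1.0, 1.0], "b": [1.0, 1.0]})
        with pytest.raises(ValueError):
            pca(t)


class TestNormalityCheck:
    def test_small_and_constant_inputs_rejected(self):
        with pytest.raises(ValueError):
            normality_check([1.0, 2.0])
        with pytest.raises(ValueError):
            normality_check([3.0] * 10)

    def test_matches_r_reference_on_frozen_sample(self):
        # heavy-tailed sample drawn once; reference value computed with
        # R's shapiro.test on the identical numbers
        rng = np.random.default_rng(42)
        x = rng.standard_cauchy(50)
        assert normality_check(x) == pytest.approx(8.19424719748e-11, abs=1e-3)

    def test_contact_like_counts_flagged_non_normal(self):
        rng = np.random.default_rng(5)
        counts = rng.poisson(0.8, size=500).astype(float)
        assert normality_check(counts) < 1e-6


class TestKruskalWallis:
    def test_worked_example(self):
        res = kruskal_wallis({"a": [1, 2, 3], "b": [4, 5, 6]})
        assert res.H == pytest.approx(3.8571, abs=1e-4)
        assert res.p == pytest.approx(0.04953, abs=1e-4)
        assert res.df == 1
        assert res.mean_ranks == {"a": 2.0, "b": 5.0}

    def test_all_tied_convention(self):
        res = kruskal_wallis({"a": [2, 2], "b": [2, 2, 2]})
        assert res.H == 0 and res.p == 1

    def test_matches_scipy_with_ties(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            groups = [rng.integers(0, 6, size=rng.integers(3, 12)) for _ in range(3)]
            ours = kruskal_wallis(groups)
            ref = sps.kruskal(*groups)
            assert ours.H == pytest.approx(ref.statistic, rel=1e-12)
            assert ours.p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_matches_permutation_oracle(self):
        # chi-square approximation vs brute-force permutation null
        rng = np.random.default_rng(8)
        a = [3.1, 5.2, 7.7, 9.0, 2.2, 6.4, 8.8, 4.9]
        b = [4.0, 6.6, 10.1, 5.5, 7.2, 9.9, 3.3, 8.1]
        c = [12.0, 7.9, 10.5, 6.1, 11.3, 9.4, 13.2, 8.5]
        obs = kruskal_wallis([a, b, c])
        pooled = np.array(a + b + c)
        sizes = [len(a), len(b), len(c)]
        hits = 0
        n_perm = 10_000
        for _ in range(n_perm):
            rng.shuffle(pooled)
            parts = np.split(pooled, np.cumsum(sizes)[:-1])
            if kruskal_wallis(parts).H >= obs.H:
                hits += 1
        assert abs(obs.p - hits / n_perm) <= 0.02

    def test_rejects_single_group(self):
        with pytest.raises(ValueError):
            kruskal_wallis({"a": [1, 2, 3]})


class TestDunn:
    def test_worked_example(self):
        res = dunn_test({"a": [1, 2, 3], "b": [4, 5, 6]}, adjust="none")
        row = res.table.iloc[0]
        assert abs(row["z"]) == pytest.approx(1.9640, abs=1e-4)
        assert row["p"] == pytest.approx(0.0495, abs=1e-4)
        assert row["p_adj"] == row["p"]

    def test_identical_groups_p_one(self):
        res = dunn_test({"a": [1, 1], "b": [1, 1], "c": [1, 1]})
        assert (res.table["z"] == 0).all()
        assert (res.table["p"] == 1).all()

    def test_two_groups_agrees_with_kw(self):
        rng = np.random.default_rng(9)
        for _ in range(10):
            groups = {
                "a": rng.normal(size=rng.integers(5, 15)),
                "b": rng.normal(loc=0.5, size=rng.integers(5, 15)),
            }
            kw = kruskal_wallis(groups)
            dunn = dunn_test(groups, adjust="none")
            assert dunn.table["p"].iloc[0] == pytest.approx(kw.p, abs=0.002)

    def test_posthoc_flag_follows_omnibus(self):
        clear = dunn_test({"a": [1, 2, 3, 4], "b": [10, 11, 12, 13]})
        assert clear.posthoc_warranted
        null = dunn_test({"a": [1, 4, 2, 5], "b": [3, 2, 5, 1]})
        assert not null.posthoc_warranted

    def test_adjusted_never_below_raw(self):
        rng = np.random.default_rng(10)
        groups = {k: rng.normal(size=8) for k in "abcd"}
        for method in ("holm", "bh"):
            res = dunn_test(groups, adjust=method)
            assert (res.table["p_adj"] >= res.table["p"] - 1e-15).all()
            assert (res.table["p_adj"] <= 1).all()


class TestAdjustP:
    def test_single_p_unchanged(self):
        assert adjust_p([0.03], "holm") == [0.03]
        assert adjust_p([0.03], "bh") == [0.03]

    def test_bh_step_up_with_monotonicity(self):
        assert adjust_p([0.01, 0.02, 0.03], "bh") == pytest.approx([0.03, 0.03, 0.03])

    def test_holm_step_down(self):
        assert adjust_p([0.01, 0.04], "holm") == pytest.approx([0.02, 0.04])

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(11)
        ps = rng.uniform(size=25)
        for ours, theirs in (("holm", "holm"), ("bh", "fdr_bh")):
            got = adjust_p(ps.tolist(), ours)
            want = multipletests(ps, method=theirs)[1]
            assert got == pytest.approx(want.tolist())

    @settings(max_examples=100, derandomize=True)
    @given(
        ps=st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=20),
        method=st.sampled_from(["holm", "bh"]),
    )
    def test_adjustment_invariants(self, ps, method):
        adj = adjust_p(ps, method)
        assert all(a >= p - 1e-15 for a, p in zip(adj, ps))
        assert all(a <= 1 for a in adj)
        if method == "bh":
            order = np.argsort(ps, kind="stable")
            assert np.all(np.diff(np.asarray(adj)[order]) >= -1e-12)
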