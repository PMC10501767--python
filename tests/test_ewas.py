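"""Paired testing, Bonferroni threshold, inflation diagnostic, descriptives."""

import numpy as np
import pandas as pd
import pytest
from itertools import product
from scipy import stats

from twinewas import (
    bonferroni_threshold,
    inflation_lambda,
    paired_descriptives,
    paired_ewas,
    rank_by_p,
    within_pair_differences,
)
from twinewas.preprocess import ResidualMatrix

from conftest import toy_pairs


def _diffs(values):
    arr = np.atleast_2d(np.asarray(values, dtype=float))
    return pd.DataFrame(arr, index=[f"cg{i}" for i in range(arr.shape[0])],
                        columns=[f"p{j}" for j in range(arr.shape[1])])


class TestWithinPairDifferences:
    def test_sign_convention_non_smoker_minus_smoker(self):
        # smoker residual 0.50, never-smoking co-twin 0.60 -> +0.10
        values = pd.DataFrame([[0.50, 0.60], [0.2, 0.2]],
                              index=["cg0", "cg1"], columns=["s1", "s2"])
        resid = ResidualMatrix(values=values, covariates=(), design_columns=())
        pairs = toy_pairs([
            ("p1", "s1", "s2", "discordant_current_never", "s1"),
            ("p2", "x", "y", "discordant_current_never", "x"),
        ])
        # second pair only to satisfy the >= 2 pairs precondition
        values["x"] = [0.0, 0.0]
        values["y"] = [0.0, 0.0]
        d = within_pair_differences(resid, pairs, "discordant_current_never")
        assert d.loc["cg0", "p1"] == pytest.approx(0.10)
        assert d.loc["cg1", "p1"] == pytest.approx(0.0)

    def test_three_pair_subtraction(self):
        values = pd.DataFrame(
            [[0.1, 0.2, 0.3, 0.5, 0.2, 0.5]],
            index=["cg0"], columns=["e1", "u1", "e2", "u2", "e3", "u3"],
        )
        resid = ResidualMatrix(values=values, covariates=(), design_columns=())
        pairs = toy_pairs([
            ("p1", "e1", "u1", "discordant_current_never", "e1"),
            ("p2", "e2", "u2", "discordant_current_never", "e2"),
            ("p3", "e3", "u3", "discordant_current_never", "e3"),
        ])
        d = within_pair_differences(resid, pairs, "discordant_current_never")
        assert d.loc["cg0"].to_numpy() == pytest.approx([0.1, 0.2, 0.3])

    def test_unknown_group_and_missing_member(self):
        values = pd.DataFrame([[0.1, 0.2]], index=["cg0"], columns=["a", "b"])
        resid = ResidualMatrix(values=values, covariates=(), design_columns=())
        pairs = toy_pairs([
            ("p1", "a", "b", "concordant_never", None),
            ("p2", "c", "d", "concordant_never", None),
        ])
        with pytest.raises(ValueError, match="unknown group"):
            within_pair_differences(resid, pairs, "light_smokers")
        with pytest.raises(ValueError, match="absent"):
            within_pair_differences(resid, pairs, "concordant_never")


class TestPairedEwas:
    def test_textbook_example(self):
        res = paired_ewas(_diffs([0.1, 0.2, 0.3]))
        row = res.iloc[0]
        assert row["mean_diff"] == pytest.approx(0.2)
        assert row["t"] == pytest.approx(0.2 / (0.1 / np.sqrt(3)), rel=1e-9)
        assert row["t"] == pytest.approx(3.4641016, rel=1e-6)
        assert row["p"] == pytest.approx(2 * stats.t.sf(3.4641016, 2), rel=1e-6)
        assert row["p"] == pytest.approx(0.0742, abs=2e-4)

    def test_zero_variance_flagged_degenerate(self):
        res = paired_ewas(_diffs([0.0, 0.0, 0.0]))
        assert bool(res.iloc[0]["degenerate"])
        assert np.isnan(res.iloc[0]["p"])
        assert not np.isinf(res["t"].fillna(0)).any()

    def test_matches_independent_t_implementation(self):
        rng = np.random.default_rng(12)
        d = rng.normal(0.02, 0.05, size=(40, 17))
        res = paired_ewas(_diffs(d))
        oracle = stats.ttest_1samp(d, 0.0, axis=1)
        assert np.max(np.abs(res["t"].to_numpy() - oracle.statistic)) < 1e-10
        assert np.max(np.abs(res["p"].to_numpy() - oracle.pvalue)) < 1e-10
        lo, hi = oracle.confidence_interval(0.95)
        assert np.max(np.abs(res["ci_low"].to_numpy() - lo)) < 1e-10
        assert np.max(np.abs(res["ci_high"].to_numpy() - hi)) < 1e-10

    def test_ci_t_mean_internally_consistent(self):
        rng = np.random.default_rng(3)
        res = paired_ewas(_diffs(rng.normal(0, 0.05, size=(25, 20))))
        n = res["n_pairs"].to_numpy()
        half = (res["ci_high"] - res["ci_low"]).to_numpy() / 2
        se = half / stats.t.ppf(0.975, n - 1)
        t_rebuilt = res["mean_diff"].to_numpy() / se
        assert np.max(np.abs(t_rebuilt - res["t"].to_numpy())) < 1e-6

    def test_complete_pairs_only_per_cpg(self):
        d = np.array([[0.1, 0.2, np.nan, 0.4], [0.1, 0.2, 0.3, 0.4]])
        res = paired_ewas(_diffs(d))
        assert res["n_pairs"].tolist() == [3, 4]

    def test_bonferroni_flag_counts_tested_cpgs(self):
        rng = np.random.default_rng(8)
        d = rng.normal(0, 0.05, size=(50, 10))
        d[0] += 1.0  # one overwhelming effect
        res = paired_ewas(_diffs(d), alpha=0.05)
        assert res.attrs["m_tested"] == 50
        assert res.attrs["bonferroni_threshold"] == pytest.approx(0.001)
        assert bool(res.iloc[0]["significant"])


class TestBonferroni:
    def test_reported_epigenome_wide_threshold(self):
        thr = bonferroni_threshold(0.05, 411_169)
        assert thr == pytest.approx(1.216e-7, rel=1e-3)

    @pytest.mark.parametrize("alpha,m,expected", [(0.05, 1, 0.05), (0.05, 100, 5e-4)])
    def test_simple_cases(self, alpha, m, expected):
        assert bonferroni_threshold(alpha, m) == pytest.approx(expected)

    def test_zero_tests_rejected(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(0.05, 0)


class TestInflation:
    def test_uniform_p_grid_gives_lambda_one(self):
        grid = (np.arange(20001) + 0.5) / 20001
        t_stats = stats.t.ppf(grid, 52)
        rep = inflation_lambda(t_stats, df=52)
        assert rep.lam == pytest.approx(1.0, abs=0.01)
        assert rep.z_mean == pytest.approx(0.0, abs=0.01)
        assert rep.z_sd == pytest.approx(1.0, abs=0.01)

    def test_scaled_statistics_recover_inflation_factor(self):
        # chi2(1) draws scaled by 1.3 correspond to z-scores scaled by sqrt(1.3)
        rng = np.random.default_rng(21)
        z = rng.standard_normal(100_000) * np.sqrt(1.3)
        rep = inflation_lambda(z, df=10**7)
        assert rep.lam == pytest.approx(1.3, abs=0.02)

    def test_empty_and_single_input_rejected(self):
        with pytest.raises(ValueError):
            inflation_lambda([], df=52)
        with pytest.raises(ValueError):
            inflation_lambda([1.5], df=52)

    def test_small_input_warns(self):
        with pytest.warns(UserWarning, match="unstable"):
            inflation_lambda(np.linspace(-2, 2, 50), df=52)


def _pheno_pairs(diffs):
    rows, sheet_rows = [], []
    for i, d in enumerate(diffs):
        a, b = f"a{i}", f"b{i}"
        rows.append((f"p{i}", a, b, "concordant_never", None))
        sheet_rows += [
            {"sample_id": a, "pair_id": f"p{i}", "smoking_status": "never", "y": d},
            {"sample_id": b, "pair_id": f"p{i}", "smoking_status": "never", "y": 0.0},
        ]
    return pd.DataFrame(sheet_rows), toy_pairs(rows)


class TestPairedDescriptives:
    def test_constant_differences_flagged_degenerate(self):
        sheet, pairs = _pheno_pairs([1.0, 1.0, 1.0, 1.0])
        res = paired_descriptives(sheet, pairs, "y", "continuous")
        assert res["degenerate"]

    def test_continuous_matches_scipy(self):
        d = [0.5, -1.2, 0.3, 2.0, 0.9, -0.4]
        sheet, pairs = _pheno_pairs(d)
        res = paired_descriptives(sheet, pairs, "y", "continuous")
        oracle = stats.ttest_1samp(d, 0.0)
        assert res["statistic"] == pytest.approx(oracle.statistic, rel=1e-10)
        assert res["p"] == pytest.approx(oracle.pvalue, rel=1e-10)

    @pytest.mark.parametrize("d", [(1.0, -2.0, 3.0), (3, -1, 2, -4, 5, 7, -2.5, 6)])
    def test_signed_rank_exact_against_enumeration(self, d):
        d = np.asarray(d, dtype=float)
        sheet, pairs = _pheno_pairs(d)
        res = paired_descriptives(sheet, pairs, "y", "ordinal")
        ranks = stats.rankdata(np.abs(d))
        total = ranks.sum()
        w_obs = min(ranks[d > 0].sum(), total - ranks[d > 0].sum())
        count = 0
        for signs in product([1, -1], repeat=len(d)):
            wp = ranks[np.array(signs) > 0].sum()
            if min(wp, total - wp) <= w_obs:
                count += 1
        assert res["statistic"] == pytest.approx(w_obs)
        assert res["p"] == pytest.approx(count / 2 ** len(d), rel=1e-12)

    def test_large_sample_uses_normal_approximation(self):
        rng = np.random.default_rng(6)
        d = rng.normal(0.3, 1.0, size=40).round(3)
        sheet, pairs = _pheno_pairs(d)
        res = paired_descriptives(sheet, pairs, "y", "ordinal")
        oracle = stats.wilcoxon(d, correction=True, method="approx")
        assert res["p"] == pytest.approx(oracle.pvalue, rel=1e-10)


def test_rank_by_p_tie_breaking():
    res = pd.DataFrame(
        {"p": [0.5, 0.01, 0.01, 0.01], "t": [0.1, -3.0, 2.0, 3.0]},
        index=["cg_d", "cg_c", "cg_b", "cg_a"],
    )
    ranked = rank_by_p(res)
    # ties on p: |t| descending, then lexicographic id
    assert list(ranked.index) == ["cg_a", "cg_c", "cg_b", "cg_d"]
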