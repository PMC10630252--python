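import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from episign.sitetest import (
    InsufficientDataError,
    SignificanceParams,
    adjust_fdr,
    call_significant_sites,
    differential_scan,
    linear_model_test,
    mean_difference,
    welch_test,
)


def bh_brute_force(p):
    """Textbook BH definition: q(i) = min_{j >= i} p_(j) * m / j."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    sorted_p = p[order]
    for rank_i in range(m):
        q[order[rank_i]] = min(
            min(sorted_p[j] * m / (j + 1) for j in range(rank_i, m)), 1.0
        )
    return q


class TestWelch:
    def test_identical_groups_give_t_zero_p_one(self):
        t, df, p = welch_test([0.1, 0.2, 0.3], [0.1, 0.2, 0.3])
        assert t == 0.0 and p == 1.0

    def test_hand_computed_statistic_and_df(self):
        # closed form: means 0.3/0.7, per-group var 0.02, se^2 = 0.02,
        # t = -0.4/sqrt(0.02), Satterthwaite df = 2
        t, df, p = welch_test([0.2, 0.4], [0.6, 0.8])
        assert t == pytest.approx(-2.8284, abs=1e-4)
        assert df == pytest.approx(2.0)
        assert p == pytest.approx(2 * stats.t.sf(2.8284271, 2.0), rel=1e-4)

    def test_zero_variance_unequal_means_floors_p(self):
        t, df, p = welch_test([0, 0, 0], [1, 1, 1])
        assert p == np.finfo(float).tiny and np.isinf(t)

    def test_insufficient_n_signals_linear_path(self):
        with pytest.raises(InsufficientDataError, match="linear_model"):
            welch_test([0.5], [0.1, 0.2, 0.3])

    @given(
        st.lists(st.floats(0, 1, width=32), min_size=2, max_size=6),
        st.lists(st.floats(0, 1, width=32), min_size=2, max_size=6),
    )
    @settings(max_examples=50, deadline=None)
    def test_antisymmetric_under_group_swap(self, a, b):
        t1, df1, p1 = welch_test(a, b)
        t2, df2, p2 = welch_test(b, a)
        assert t1 == pytest.approx(-t2, nan_ok=True)
        assert p1 == pytest.approx(p2)
        assert df1 == pytest.approx(df2)

    def test_matches_scipy_reference(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            a, b = rng.normal(size=5), rng.normal(size=8)
            t, df, p = welch_test(a, b)
            ref = stats.ttest_ind(a, b, equal_var=False)
            assert t == pytest.approx(ref.statistic)
            assert p == pytest.approx(ref.pvalue)


class TestMeanDifference:
    @pytest.mark.parametrize(
        "case,control,expected",
        [([0.8, 0.8], [0.5, 0.5], 0.3), ([0.4], [0.4], 0.0), ([1.0], [0.0], 1.0)],
    )
    def test_examples(self, case, control, expected):
        assert mean_difference(case, control) == pytest.approx(expected)

    def test_empty_group_is_missing(self):
        assert np.isnan(mean_difference([], [0.5]))


class TestFdr:
    @pytest.mark.parametrize(
        "p,expected",
        [
            ([0.01, 0.02, 0.03], [0.03, 0.03, 0.03]),
            ([0.5], [0.5]),
            ([0.04, 0.5, 1.0], [0.12, 0.75, 1.0]),
        ],
    )
    def test_hand_worked_examples(self, p, expected):
        assert adjust_fdr(np.array(p)) == pytest.approx(expected)

    def test_exhaustive_grid_against_brute_force(self):
        grid = [0.001, 0.04, 0.2, 0.5, 1.0]
        for n in (1, 2, 3):
            for combo in itertools.product(grid, repeat=n):
                got = adjust_fdr(np.array(combo))
                assert got == pytest.approx(bh_brute_force(combo)), combo

    @given(st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=8))
    @settings(max_examples=100, deadline=None)
    def test_random_vectors_against_brute_force(self, p):
        assert adjust_fdr(np.array(p)) == pytest.approx(bh_brute_force(p))

    def test_nan_propagated(self):
        q = adjust_fdr(np.array([0.01, np.nan, 0.02]))
        assert np.isnan(q[1]) and not np.isnan(q[0])


class TestLinearModel:
    def _design(self, n_case, n_control):
        return pd.DataFrame(
            {"intercept": 1.0, "group": [1.0] * n_case + [0.0] * n_control},
            index=[f"S{i}" for i in range(n_case + n_control)],
        )

    def test_equals_equal_variance_t_test(self):
        rng = np.random.default_rng(5)
        y = rng.uniform(0, 1, 10)
        d = self._design(4, 6)
        eff, p = linear_model_test(y, d)
        ref = stats.ttest_ind(y[:4], y[4:], equal_var=True)
        assert p == pytest.approx(ref.pvalue)
        assert eff == pytest.approx(y[:4].mean() - y[4:].mean())

    def test_single_case_against_large_control_pool(self):
        rng = np.random.default_rng(6)
        y = rng.uniform(0.4, 0.6, 64)
        d = self._design(1, 63)
        eff, p = linear_model_test(y, d)
        assert 0 < p <= 1
        # residual df is n - 2 = 62; compare against statsmodels OLS
        import statsmodels.api as sm

        fit = sm.OLS(y, d.to_numpy()).fit()
        assert fit.df_resid == 62
        assert p == pytest.approx(fit.pvalues[1])

    def test_rank_deficient_site_untestable(self):
        d = self._design(2, 2)
        y = np.array([0.5, np.nan, np.nan, np.nan])  # only 1 usable row
        eff, p = linear_model_test(y, d)
        assert np.isnan(p)

    def test_planted_effect_recovered(self):
        rng = np.random.default_rng(7)
        d = self._design(4, 64)
        hits = 0
        for _ in range(200):
            y = np.concatenate([rng.normal(0.8, 0.05, 4), rng.normal(0.5, 0.05, 64)])
            eff, _ = linear_model_test(y, d)
            hits += abs(eff - 0.3) <= 0.05
        assert hits / 200 >= 0.95


class TestSignificanceCalling:
    def _results(self, rows):
        df = pd.DataFrame(rows, columns=["chrom", "pos", "delta_beta", "p", "q"])
        df["direction"] = np.where(df["delta_beta"] > 0, "hyper", "hypo")
        return df

    def test_joint_rule_boundaries(self):
        res = self._results(
            [
                ("chr1", 1, 0.25, 1e-4, 0.01),  # passes both
                ("chr1", 2, 0.15, 1e-4, 0.01),  # fails the >20% rule
                ("chr1", 3, 0.50, 0.05, 0.20),  # fails FDR
            ]
        )
        sig = call_significant_sites(res, SignificanceParams())
        assert list(sig["pos"]) == [1]
        assert sig.attrs["n_hyper"] == 1 and sig.attrs["n_hypo"] == 0

    def test_strict_threshold_boundaries(self):
        res = self._results([("chr1", 1, 0.20, 1e-4, 0.01), ("chr1", 2, 0.21, 1e-4, 0.05)])
        sig = call_significant_sites(res, SignificanceParams())
        assert len(sig) == 0  # 0.20 is not > 0.20; q = 0.05 is not < 0.05


class TestDifferentialScan:
    def _null_beta(self, n_sites, n_case, n_control, seed=0):
        rng = np.random.default_rng(seed)
        vals = rng.normal(0.5, 0.05, size=(n_sites, n_case + n_control)).clip(0, 1)
        idx = pd.MultiIndex.from_arrays(
            [["chr1"] * n_sites, range(1, n_sites + 1)], names=["chrom", "pos"]
        )
        cols = [f"P{i}" for i in range(n_case)] + [f"C{i}" for i in range(n_control)]
        return pd.DataFrame(vals, index=idx, columns=cols)

    def test_null_scan_calls_almost_nothing(self):
        beta = self._null_beta(5000, 4, 64, seed=9)
        res = differential_scan(beta, [f"P{i}" for i in range(4)], [f"C{i}" for i in range(64)])
        sig = call_significant_sites(res)
        assert len(sig) <= 5

    def test_welch_and_linear_paths_agree_on_direction(self):
        beta = self._null_beta(200, 4, 10, seed=10)
        case, ctrl = [f"P{i}" for i in range(4)], [f"C{i}" for i in range(10)]
        res_w = differential_scan(beta, case, ctrl, params=SignificanceParams(test="welch"))
        res_l = differential_scan(beta, case, ctrl, params=SignificanceParams(test="linear_model"))
        pd.testing.assert_series_equal(res_w["delta_beta"], res_l["delta_beta"])

    def test_power_on_planted_blocks(self):
        # 300 planted sites at delta 0.25 among 3000 null sites, n=4 vs 64
        rng = np.random.default_rng(11)
        n_sites = 3000
        beta = self._null_beta(n_sites, 4, 64, seed=11)
        planted = rng.choice(n_sites, 300, replace=False)
        vals = beta.to_numpy()
        vals[np.ix_(planted, range(4))] += 0.25
        beta = pd.DataFrame(vals.clip(0, 1), index=beta.index, columns=beta.columns)
        res = differential_scan(beta, [f"P{i}" for i in range(4)], [f"C{i}" for i in range(64)])
        sig = call_significant_sites(res)
        called = set(sig.index)
        assert len(called & set(planted)) / 300 >= 0.90
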