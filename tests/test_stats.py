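import numpy as np
import pandas as pd
import pytest
import scipy.stats as sps
from hypothesis import given, settings, strategies as st

from repleteaudit.errors import DataError
from repleteaudit.stats import (
    GroupStats,
    cohens_d,
    decision_regression,
    pre_post_effect,
    students_t,
    threshold_anova,
)

from tests.oracle import ols_normal_equations, pooled_t_closed_form


class TestCohensD:
    def test_identical_groups_is_zero(self, rng):
        x = rng.normal(size=50)
        assert cohens_d(x, x) == 0.0

    def test_unit_case(self):
        a = GroupStats(n=100, mean=1.0, sd=1.0)
        b = GroupStats(n=100, mean=0.0, sd=1.0)
        assert cohens_d(a, b) == pytest.approx(1.0)

    def test_planted_shift_recovered(self, rng):
        n = 10_000
        pre = rng.normal(0.0, 1.0, n)
        post = rng.normal(0.5, 1.0, n)
        d = cohens_d(post, pre)
        assert d == pytest.approx(0.5, abs=0.05)

    def test_degenerate_pooled_sd(self):
        same = GroupStats(n=5, mean=2.0, sd=0.0)
        other = GroupStats(n=5, mean=3.0, sd=0.0)
        assert cohens_d(same, same) == 0.0
        assert cohens_d(other, same) == np.inf
        assert cohens_d(same, other) == -np.inf

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        scale=st.floats(0.1, 50.0),
        shift=st.floats(-100.0, 100.0),
    )
    def test_scale_and_shift_invariance(self, scale, shift):
        rng = np.random.default_rng(7)
        a, b = rng.normal(1, 1, 40), rng.normal(0, 2, 30)
        d0 = cohens_d(a, b)
        d1 = cohens_d(a * scale + shift, b * scale + shift)
        assert d1 == pytest.approx(d0, rel=1e-9)


class TestStudentsT:
    def test_identical_groups(self):
        x = np.array([1.0, 2.0, 3.0])
        res = students_t(x, x)
        assert res.t_statistic == 0.0 and res.p_value == 1.0

    def test_zero_pooled_variance_is_flagged(self):
        res = students_t([2.0, 2.0, 2.0], [2.0, 2.0])
        assert res.degenerate and res.t_statistic == 0.0 and res.p_value == 1.0

    def test_textbook_closed_form(self):
        a, b = [1.0, 2.0, 3.0], [3.0, 4.0, 5.0]
        res = students_t(a, b)
        assert res.t_statistic == pytest.approx(pooled_t_closed_form(a, b))
        assert res.df == 4
        # cross-check against the standard library implementation
        t_ref, p_ref = sps.ttest_ind(a, b)
        assert res.t_statistic == pytest.approx(float(t_ref))
        assert res.p_value == pytest.approx(float(p_ref))

    def test_antisymmetry(self, rng):
        a, b = rng.normal(0, 1, 20), rng.normal(1, 2, 25)
        r1, r2 = students_t(a, b), students_t(b, a)
        assert r1.t_statistic == pytest.approx(-r2.t_statistic)
        assert r1.p_value == pytest.approx(r2.p_value)
        assert r1.d_cohen == pytest.approx(-r2.d_cohen)

    def test_needs_two_per_group(self):
        with pytest.raises(DataError):
            students_t([1.0], [1.0, 2.0])


class TestPrePostEffect:
    @staticmethod
    def _episodes(pre, post, elec="potassium"):
        return pd.DataFrame(
            {
                "electrolyte": elec,
                "scenario": "1L_1R",
                "index_value": pre,
                "followup_value": post,
                "order_time": pd.Timestamp("2140-01-01"),
                "n_ignored": 0,
            }
        )

    def test_post_equals_pre_gives_zero_d(self, rng):
        x = rng.normal(4, 0.4, 100)
        res = pre_post_effect(self._episodes(x, x))
        assert res["d_cohen"].iloc[0] == 0.0

    def test_planted_shift_recovered(self, rng):
        n = 5000
        pre = rng.normal(4.0, 0.5, n)
        post = pre + 0.3 * 0.5 + rng.normal(0, 0.1, n)
        res = pre_post_effect(self._episodes(pre, post))
        assert res["d_cohen"].iloc[0] == pytest.approx(0.3 * 0.5 / np.sqrt((0.25 + 0.26) / 2), abs=0.05)
        assert res["p"].iloc[0] < 1e-6

    def test_incomplete_episodes_are_excluded_by_contract(self, rng):
        pre = rng.normal(4, 0.4, 60)
        post = pre + 0.2
        ep = self._episodes(pre, post)
        with_missing = pd.concat(
            [ep, self._episodes([3.0, 3.1], [np.nan, np.nan])], ignore_index=True
        )
        res_a, res_b = pre_post_effect(ep), pre_post_effect(with_missing)
        assert res_a["d_cohen"].iloc[0] == res_b["d_cohen"].iloc[0]
        assert res_b["n"].iloc[0] == 60

    def test_fewer_than_two_complete_is_flagged_undefined(self):
        res = pre_post_effect(self._episodes([4.0], [4.2]))
        assert not res["defined"].iloc[0]

    def test_paired_mode_uses_differences(self, rng):
        pre = rng.normal(4, 0.5, 500)
        post = pre + 0.2 + rng.normal(0, 0.05, 500)
        res = pre_post_effect(self._episodes(pre, post), paired=True)
        # paired d is huge because the within-pair noise is tiny
        assert res["d_cohen"].iloc[0] > 2.0


class TestDecisionRegression:
    def test_exact_linear_fit(self):
        x = np.arange(10.0)
        df = pd.DataFrame({"x": x, "y": 2.0 * x + 1.0})
        fit = decision_regression(df, "y", ["x"])
        assert fit.coefficients.loc["x", "coef"] == pytest.approx(2.0)
        assert fit.coefficients.loc["const", "coef"] == pytest.approx(1.0)
        assert fit.r_squared == pytest.approx(1.0)

    def test_constant_outcome(self, rng):
        df = pd.DataFrame({"x": rng.normal(size=30), "y": 5.0})
        fit = decision_regression(df, "y", ["x"])
        assert fit.coefficients.loc["x", "coef"] == pytest.approx(0.0, abs=1e-12)
        assert fit.r_squared == pytest.approx(0.0, abs=1e-12)

    def test_matches_normal_equations_oracle(self, rng):
        X = rng.normal(size=(50, 5))
        y = rng.normal(size=50)
        df = pd.DataFrame(X, columns=[f"x{i}" for i in range(5)])
        df["y"] = y
        fit = decision_regression(df, "y", [f"x{i}" for i in range(5)])
        beta, se, resid = ols_normal_equations(X, y)
        np.testing.assert_allclose(fit.coefficients["coef"].to_numpy(), beta, atol=1e-8)
        np.testing.assert_allclose(fit.coefficients["se"].to_numpy(), se, atol=1e-8)
        # residual orthogonality to every predictor
        design = np.column_stack([np.ones(50), X])
        assert np.abs(design.T @ resid).max() < 1e-8

    def test_f_df_layout(self, rng):
        X = rng.normal(size=(100, 3))
        df = pd.DataFrame(X, columns=["a", "b", "c"])
        df["y"] = X @ [1.0, 0.5, 0.0] + rng.normal(size=100)
        fit = decision_regression(df, "y", ["a", "b", "c"])
        assert fit.f_df == (3, 96)
        assert fit.adjusted_r_squared <= fit.r_squared

    def test_rank_deficiency_names_columns(self, rng):
        x = rng.normal(size=40)
        df = pd.DataFrame({"x1": x, "x2": 2 * x, "y": rng.normal(size=40)})
        with pytest.raises(DataError, match="x2"):
            decision_regression(df, "y", ["x1", "x2"])

    def test_zero_variance_predictor_is_hard_error(self, rng):
        df = pd.DataFrame({"x": 1.0, "y": rng.normal(size=20)}, index=range(20))
        with pytest.raises(DataError, match="zero-variance"):
            decision_regression(df, "y", ["x"])

    def test_planted_coefficients_recovered_within_3se(self, rng):
        hits = 0
        n_rep = 60
        beta_true = np.array([0.8, -0.5, 0.0])
        for _ in range(n_rep):
            X = rng.normal(size=(200, 3))
            y = 1.0 + X @ beta_true + rng.normal(size=200)
            df = pd.DataFrame(X, columns=["a", "b", "c"])
            df["y"] = y
            fit = decision_regression(df, "y", ["a", "b", "c"])
            est = fit.coefficients.loc[["a", "b", "c"], "coef"].to_numpy()
            se = fit.coefficients.loc[["a", "b", "c"], "se"].to_numpy()
            if np.all(np.abs(est - beta_true) <= 3 * se):
                hits += 1
        assert hits >= int(0.9 * n_rep)

    def test_stepwise_modes_screen_noise_variables(self, rng):
        X = rng.normal(size=(300, 4))
        y = 2.0 * X[:, 0] + rng.normal(size=300)
        df = pd.DataFrame(X, columns=["signal", "n1", "n2", "n3"])
        df["y"] = y
        for mode in ("add", "subtract"):
            fit = decision_regression(df, "y", list(df.columns[:-1]), stepwise=mode)
            assert "signal" in fit.coefficients.index


class TestThresholdAnova:
    def test_identical_data_gives_f_zero(self):
        vals = np.array([3.0] * 12)
        groups = np.repeat(["a", "b", "c"], 4)
        res = threshold_anova(vals, groups)
        assert res.f_statistic == 0.0
        assert (res.df_between, res.df_within) == (2, 9)

    def test_two_groups_f_equals_t_squared(self, rng):
        a, b = rng.normal(0, 1, 30), rng.normal(0.5, 1, 25)
        vals = np.concatenate([a, b])
        groups = np.array(["a"] * 30 + ["b"] * 25)
        res = threshold_anova(vals, groups)
        t = students_t(a, b)
        assert res.f_statistic == pytest.approx(t.t_statistic**2)
        assert res.p_value == pytest.approx(t.p_value)

    def test_matches_scipy_reference(self, rng):
        vals = rng.normal(size=90)
        groups = rng.choice(["u1", "u2", "u3"], size=90)
        res = threshold_anova(vals, groups)
        ref_f, ref_p = sps.f_oneway(*[vals[groups == g] for g in np.unique(groups)])
        assert res.f_statistic == pytest.approx(float(ref_f))
        assert res.p_value == pytest.approx(float(ref_p))

    def test_small_group_excluded_with_warning(self, rng):
        vals = np.concatenate([rng.normal(size=20), rng.normal(size=20), [1.0]])
        groups = np.array(["a"] * 20 + ["b"] * 20 + ["tiny"])
        with pytest.warns(UserWarning, match="tiny"):
            res = threshold_anova(vals, groups)
        assert res.excluded_groups == ("tiny",)
        assert res.df_within == 38

    def test_planted_unit_offsets_are_detected(self, rng):
        n = 500
        vals = np.concatenate(
            [rng.normal(0.0, 1.0, n), rng.normal(0.3, 1.0, n), rng.normal(-0.2, 1.0, n)]
        )
        groups = np.repeat(["MICU", "SICU", "CICU"], n)
        res = threshold_anova(vals, groups)
        assert res.p_value < 0.05
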