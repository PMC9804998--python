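"""Robust regressions, the anatomical gamma GLM, Dunn's test, reporting gate."""

import numpy as np
import pytest
from scipy import stats

from mesolim.simulate import simulate_glm_dataset
from mesolim.traitstats import (
    GammaGLMRegressor,
    RegressionResult,
    RobustLinearRegression,
    RobustPowerRegression,
    dunn_test,
    fit_gamma_glm,
    gate_significance,
    mcfadden_r2,
    robust_linear_fit,
    robust_power_fit,
)


class TestRobustLinear:
    def test_exact_line(self):
        x = np.linspace(0, 10, 20)
        res = robust_linear_fit(x, 2 * x + 1)
        assert res.coefficients == pytest.approx((1.0, 2.0), abs=1e-8)
        assert res.r2 == pytest.approx(1.0)
        assert res.reported  # n = 20 >= 12

    def test_resists_gross_outlier_where_ols_fails(self):
        x = np.linspace(0, 10, 20)
        y = 2 * x + 1
        y[5] += 100.0
        robust = robust_linear_fit(x, y)
        ols_slope = np.polyfit(x, y, 1)[0]
        assert abs(robust.coefficients[1] - 2.0) < 0.05
        assert abs(ols_slope - 2.0) > 0.5

    def test_agrees_with_ols_on_clean_gaussian_data(self):
        rng = np.random.default_rng(11)
        x = rng.uniform(0, 10, 100)
        y = 1.5 * x + 2 + rng.normal(0, 1, 100)
        robust = RobustLinearRegression().fit(x, y)
        slope, intercept, *_ = stats.linregress(x, y)
        se = stats.linregress(x, y).stderr
        assert abs(robust.coef_[0] - slope) < 2 * se

    def test_small_sample_not_reported(self):
        x = np.linspace(0, 9, 10)
        res = robust_linear_fit(x, 2 * x + 1)
        assert res.n == 10 and not res.reported

    def test_constant_x_raises(self):
        with pytest.raises(ValueError, match="constant"):
            robust_linear_fit(np.ones(10), np.arange(10.0))


class TestRobustPower:
    def test_exact_power_law(self):
        x = np.linspace(0.5, 5, 30)
        res = robust_power_fit(x, 3 * x**0.5)
        assert res.coefficients == pytest.approx((3.0, 0.5), abs=1e-6)

    def test_drawdown_inverse_law(self):
        """Fick's law: drawdown = A_n/g_m at constant A_n is a power law
        with exponent -1."""
        rng = np.random.default_rng(3)
        gm = rng.uniform(0.05, 0.5, 40)
        res = robust_power_fit(gm, 20.0 / gm)
        assert res.coefficients[1] == pytest.approx(-1.0, abs=1e-6)
        assert res.coefficients[0] == pytest.approx(20.0, rel=1e-6)

    def test_contamination_robustness(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(0.5, 5, 60)
        y = 3 * x**0.5
        idx = rng.choice(60, 6, replace=False)  # 10% contamination
        y[idx] *= 3.0
        res = robust_power_fit(x, y)
        assert abs(res.coefficients[1] - 0.5) < 0.05
        # the non-robust fit is pulled away
        from scipy.optimize import curve_fit

        p, _ = curve_fit(lambda x, a, b: a * x**b, x, y, p0=(3, 0.5))
        assert abs(p[1] - 0.5) > 0.05

    def test_requires_positive_data(self):
        with pytest.raises(ValueError):
            robust_power_fit([-1, 2, 3, 4, 5], [1, 2, 3, 4, 5])

    def test_predict_matches_model(self):
        x = np.linspace(0.5, 5, 30)
        est = RobustPowerRegression().fit(x, 3 * x**0.5)
        assert est.predict([4.0])[0] == pytest.approx(6.0, rel=1e-6)


class TestGammaGlm:
    EXP_BETAS = (0.128, 1.050, 0.096)

    def test_noise_free_exact_recovery(self):
        rng = np.random.default_rng(0)
        Sc = rng.uniform(5, 40, 100)
        Tcw = rng.uniform(0.05, 0.6, 100)
        gm = np.exp(
            np.log(self.EXP_BETAS[0])
            + np.log(self.EXP_BETAS[1]) * Sc
            + np.log(self.EXP_BETAS[2]) * Tcw
        )
        fit = fit_gamma_glm(gm, Sc, Tcw)
        assert fit.exp_beta0 == pytest.approx(self.EXP_BETAS[0], abs=1e-8)
        assert fit.exp_beta1 == pytest.approx(self.EXP_BETAS[1], abs=1e-8)
        assert fit.exp_beta2 == pytest.approx(self.EXP_BETAS[2], abs=1e-8)
        assert fit.pseudo_r2 == pytest.approx(1.0, abs=1e-6)

    def test_model_identity_on_exp_scale(self):
        df = simulate_glm_dataset(80, rng=1)
        est = GammaGLMRegressor().fit(df[["Sc", "Tcw"]], df["gm_25"])
        manual = (
            est.exp_params_[0]
            * est.exp_params_[1] ** df["Sc"]
            * est.exp_params_[2] ** df["Tcw"]
        )
        assert np.allclose(est.predict(df[["Sc", "Tcw"]]), manual, rtol=1e-9)

    def test_first_order_unbiased_under_own_model(self):
        vals = []
        for s in range(60):
            df = simulate_glm_dataset(295, self.EXP_BETAS, rng=np.random.default_rng(s))
            fit = fit_gamma_glm(df["gm_25"], df["Sc"], df["Tcw"])
            vals.append(fit.exp_beta1)
        assert np.mean(vals) == pytest.approx(self.EXP_BETAS[1], rel=0.005)

    def test_constant_covariate_raises_with_name(self):
        df = simulate_glm_dataset(50, rng=2)
        with pytest.raises(ValueError, match="Tcw"):
            fit_gamma_glm(df["gm_25"], df["Sc"], np.full(50, 0.3))

    def test_study_count_reported(self):
        df = simulate_glm_dataset(40, rng=4)
        study = np.repeat([f"s{i}" for i in range(8)], 5)
        fit = fit_gamma_glm(df["gm_25"], df["Sc"], df["Tcw"], study_id=study)
        assert fit.n_studies == 8 and fit.n_measurements == 40


class TestMcFadden:
    def test_arithmetic(self):
        assert mcfadden_r2(-100.0, -100.0) == 0.0
        assert mcfadden_r2(-50.0, -100.0) == 0.5

    def test_zero_null_raises(self):
        with pytest.raises(ValueError):
            mcfadden_r2(-50.0, 0.0)


class TestDunn:
    def test_identical_groups(self):
        out = dunn_test([1, 2, 3, 1, 2, 3.0], ["a"] * 3 + ["b"] * 3)
        assert out["z"].iloc[0] == pytest.approx(0.0)
        assert out["pvalue"].iloc[0] == pytest.approx(1.0)

    def test_hand_computed_statistic(self):
        # {1..5} vs {101..105}: mean ranks 3 and 8,
        # var = (10*11/12)(1/5+1/5) = 11/3, z = -5/sqrt(11/3)
        out = dunn_test(
            np.r_[1:6, 101:106].astype(float), np.array(["a"] * 5 + ["b"] * 5)
        )
        assert out["z"].iloc[0] == pytest.approx(-5.0 / np.sqrt(11.0 / 3.0), rel=1e-12)

    def test_two_groups_reduce_to_mann_whitney_normal_approx(self):
        rng = np.random.default_rng(8)
        x = rng.normal(0, 1, 12)
        y = rng.normal(1, 1, 15)  # continuous: tie-free
        out = dunn_test(np.r_[x, y], np.array(["x"] * 12 + ["y"] * 15))
        U = stats.mannwhitneyu(x, y, alternative="two-sided").statistic
        m, n = 12, 15
        z_mw = (U - m * n / 2.0) / np.sqrt(m * n * (m + n + 1) / 12.0)
        assert abs(out["z"].iloc[0]) == pytest.approx(abs(z_mw), rel=1e-9)

    def test_tie_correction_against_brute_force(self):
        values = np.array([1.0, 2.0, 2.0, 2.0, 3.0, 4.0, 4.0, 5.0, 6.0, 7.0])
        groups = np.array(["a"] * 5 + ["b"] * 5)
        out = dunn_test(values, groups)
        ranks = stats.rankdata(values)
        N = len(values)
        _, t = np.unique(values, return_counts=True)
        tie = np.sum(t**3 - t) / (12.0 * (N - 1))
        var = (N * (N + 1) / 12.0 - tie) * (2.0 / 5.0)
        z = (ranks[:5].mean() - ranks[5:].mean()) / np.sqrt(var)
        assert out["z"].iloc[0] == pytest.approx(z, rel=1e-12)

    def test_distinct_median_groups_all_significant(self):
        """Six overlapping gamma distributions with well-separated medians:
        every pairwise comparison significant after Holm adjustment."""
        rng = np.random.default_rng(42)
        means = [0.05, 0.09, 0.15, 0.25, 0.4, 0.65]
        vals = np.concatenate([rng.gamma(5.0, m / 5.0, 60) for m in means])
        grp = np.repeat([f"pft{i}" for i in range(6)], 60)
        out = dunn_test(vals, grp)
        assert len(out) == 15
        assert out["significant"].all()

    def test_unadjusted_option(self):
        out = dunn_test([1, 2, 3, 7, 8, 9.0], ["a"] * 3 + ["b"] * 3, p_adjust="none")
        assert (out["pvalue_adjusted"] == out["pvalue"]).all()

    def test_tiny_group_raises(self):
        with pytest.raises(ValueError):
            dunn_test([1.0, 2.0, 3.0], ["a", "a", "b"])


class TestReportingGate:
    @pytest.mark.parametrize("n, expected", [(12, True), (11, False), (1000, True)])
    def test_threshold(self, n, expected):
        res = RegressionResult("linear", (0.0, 1.0), 0.5, 0.01, n, reported=True)
        assert gate_significance(res).reported is expected

    def test_threshold_configurable(self):
        res = RegressionResult("linear", (0.0, 1.0), 0.5, 0.01, 8, reported=False)
        assert gate_significance(res, min_n=5).reported
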