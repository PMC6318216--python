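import numpy as np
import pytest
import statsmodels.api as sm
from hypothesis import given, settings
from hypothesis import strategies as hst

from bcef.model import (
    BcefModel,
    fit_bcef_auto,
    glm_rto_bcef,
    hat_diagonal,
    ls_rto_bcef,
    ratio_bcef,
)

LINEAR_METHODS = ("ls_rto", "ratio_mean_of_ratios", "ratio_ratio_of_means")


class TestRatioEstimators:
    def test_mean_of_ratios_hand_example(self, toy_wv):
        W, V = toy_wv
        fit = ratio_bcef(W, V, "mean_of_ratios")
        assert fit.estimate == pytest.approx(2.0)  # (2 + 1.5 + 2.5)/3

    def test_ratio_of_means_hand_example(self, toy_wv):
        W, V = toy_wv
        fit = ratio_bcef(W, V, "ratio_of_means")
        assert fit.estimate == pytest.approx(15.0 / 7.0)

    @pytest.mark.parametrize("variant", ["mean_of_ratios", "ratio_of_means"])
    def test_proportional_data_exact_with_zero_se(self, variant):
        V = np.array([0.2, 1.0, 3.5, 7.0])
        fit = ratio_bcef(2.7 * V, V, variant)
        assert fit.estimate == pytest.approx(2.7)
        assert fit.se == pytest.approx(0.0, abs=1e-12)

    def test_nonpositive_volume_rejected(self):
        with pytest.raises(ValueError, match="volume"):
            ratio_bcef([1.0, 2.0], [1.0, 0.0])

    def test_single_tree_rejected(self):
        with pytest.raises(ValueError, match="n >= 2"):
            ratio_bcef([1.0], [1.0])


class TestLeastSquaresRto:
    def test_closed_form_hand_example(self, toy_wv):
        W, V = toy_wv
        fit = ls_rto_bcef(W, V)
        assert fit.estimate == pytest.approx(48.0 / 21.0)
        assert fit.se == pytest.approx(0.27970, abs=1e-5)

    def test_normal_equation_residual_orthogonality(self, rng):
        V = rng.uniform(0.1, 5.0, 40)
        W = 0.6 * V + rng.normal(0, 0.2, 40)
        fit = ls_rto_bcef(W, V)
        assert abs(np.sum(V * fit.resid)) < 1e-8 * np.sum(np.abs(V * W))

    def test_exact_fit_has_zero_residuals(self):
        V = np.array([1.0, 2.0, 5.0])
        fit = ls_rto_bcef(3.0 * V, V)
        assert fit.estimate == pytest.approx(3.0)
        assert fit.se == 0.0
        np.testing.assert_allclose(fit.resid, 0.0, atol=1e-14)

    def test_matches_generic_least_squares_oracle(self, rng):
        for _ in range(20):
            n = rng.integers(3, 30)
            V = rng.uniform(0.05, 8.0, n)
            W = 0.7 * V + rng.normal(0, 0.3, n)
            slope = np.linalg.lstsq(V[:, None], W, rcond=None)[0][0]
            assert ls_rto_bcef(W, V).estimate == pytest.approx(slope, rel=1e-10)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            ls_rto_bcef([1.0], [1.0])
        with pytest.raises(ValueError, match="zero"):
            ls_rto_bcef([1.0, 2.0], [0.0, 0.0])


class TestWeightedLsIdentities:
    """The two ratio variants are weighted LS through the origin in disguise."""

    def test_weights_inverse_v_give_ratio_of_means(self, rng):
        V = rng.uniform(0.1, 5.0, 25)
        W = 0.5 * V + rng.normal(0, 0.2, 25)
        wls = sm.WLS(W, V[:, None], weights=1.0 / V).fit().params[0]
        assert ratio_bcef(W, V, "ratio_of_means").estimate == pytest.approx(wls, rel=1e-10)

    def test_weights_inverse_v_squared_give_mean_of_ratios(self, rng):
        V = rng.uniform(0.1, 5.0, 25)
        W = 0.5 * V + rng.normal(0, 0.2, 25)
        wls = sm.WLS(W, V[:, None], weights=1.0 / V**2).fit().params[0]
        assert ratio_bcef(W, V, "mean_of_ratios").estimate == pytest.approx(wls, rel=1e-10)


class TestHatDiagonal:
    def test_ls_rto_closed_form(self):
        np.testing.assert_allclose(hat_diagonal([1.0, 2.0], "ls_rto"), [0.2, 0.8])

    def test_mean_of_ratios_uniform_leverage(self):
        h = hat_diagonal([0.3, 1.0, 4.0], "ratio_mean_of_ratios")
        np.testing.assert_allclose(h, 1.0 / 3.0)

    def test_ratio_of_means_proportional_leverage(self):
        np.testing.assert_allclose(
            hat_diagonal([1.0, 2.0, 3.0], "ratio_ratio_of_means"), [1 / 6, 2 / 6, 3 / 6]
        )

    @pytest.mark.parametrize("method", LINEAR_METHODS)
    def test_one_parameter_smoother_trace(self, method, rng):
        V = rng.uniform(0.1, 5.0, 17)
        assert hat_diagonal(V, method).sum() == pytest.approx(1.0, rel=1e-12)

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError):
            hat_diagonal([1.0, 2.0], "spline")


@settings(max_examples=30, deadline=None, derandomize=True)
@given(
    c=hst.floats(min_value=1e-3, max_value=1e3),
    seed=hst.integers(min_value=0, max_value=2**16),
)
def test_scale_equivariance(c, seed):
    """Scaling W by c scales every estimator by c; scaling V divides it by c."""
    rng = np.random.default_rng(seed)
    V = rng.uniform(0.1, 4.0, 12)
    W = 0.8 * V + rng.normal(0, 0.1, 12)
    W = np.abs(W) + 1e-6
    for method in LINEAR_METHODS:
        base = BcefModel(W, V).fit(method).estimate
        assert BcefModel(c * W, V).fit(method).estimate == pytest.approx(c * base, rel=1e-9)
        assert BcefModel(W, c * V).fit(method).estimate == pytest.approx(base / c, rel=1e-9)


class TestGlmRto:
    def test_proportional_limit(self):
        V = np.array([0.5, 1.0, 2.0, 4.0])
        fit = glm_rto_bcef(2.0 * V, V)
        assert fit.estimate == pytest.approx(2.0, rel=1e-6)

    def test_gamma_parameter_recovery(self):
        rng = np.random.default_rng(11)
        n, beta, shape = 2000, 0.5, 6.0
        V = rng.uniform(0.2, 5.0, n)
        W = beta * V * rng.gamma(shape, 1.0 / shape, n)
        fit = glm_rto_bcef(W, V)
        assert abs(fit.estimate - beta) < 3 * fit.se

    def test_nonpositive_biomass_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            glm_rto_bcef([1.0, 0.0, 2.0], [1.0, 1.0, 2.0])

    def test_gamma_identity_slope_is_mean_of_ratios(self, rng):
        # the IRLS weights 1/mu^2 cancel the V^2 leverage, so the ML slope
        # coincides with the mean of per-tree ratios
        V = rng.uniform(0.3, 4.0, 50)
        W = 0.6 * V * rng.lognormal(0, 0.4, 50)
        glm = glm_rto_bcef(W, V)
        mor = ratio_bcef(W, V, "mean_of_ratios")
        assert glm.estimate == pytest.approx(mor.estimate, rel=1e-6)


class TestNormalityGate:
    def test_normal_noise_keeps_least_squares(self):
        rng = np.random.default_rng(5)
        V = rng.uniform(0.2, 4.0, 200)
        W = 0.7 * V + rng.normal(0, 0.1, 200)
        fit = fit_bcef_auto(W, V)
        assert fit.method == "ls_rto"
        assert fit.gate["decision"] == "ls_rto"

    def test_heavy_tailed_noise_switches_to_glm(self):
        rng = np.random.default_rng(5)
        V = rng.uniform(0.2, 4.0, 200)
        W = 0.7 * V * rng.lognormal(0, 1.0, 200)
        fit = fit_bcef_auto(W, V)
        assert fit.method == "glm_rto"
        assert fit.gate["p"] < 0.05

    def test_gate_needs_three_observations(self):
        with pytest.raises(ValueError, match="n >= 3"):
            fit_bcef_auto([1.0, 2.0], [1.0, 2.0])


class TestResultsObject:
    def test_summary_mentions_estimate_and_method(self, toy_wv):
        W, V = toy_wv
        text = BcefModel(W, V, component="stem", species="sp").fit("ls_rto").summary()
        assert "2.2857" in text and "ls_rto" in text and "stem" in text

    def test_from_dataframe_constructor(self, small_dataset):
        df = small_dataset.analysis_pairs()
        m = BcefModel.from_dataframe(df, component="stem", species="A")
        assert m.nobs == 3
        assert m.fit("ls_rto").estimate == pytest.approx(0.4)

    def test_variance_ordering_under_var_proportional_v_squared(self):
        """With sd ∝ V the per-tree ratios are iid, making mean-of-ratios the
        minimum-variance member of the three linear estimators."""
        rng = np.random.default_rng(99)
        est = {m: [] for m in LINEAR_METHODS}
        for _ in range(2000):
            V = rng.uniform(0.1, 5.0, 30)
            W = 0.6 * V + rng.normal(0, 1.0, 30) * 0.2 * V
            for m in LINEAR_METHODS:
                est[m].append(BcefModel(W, V).fit(m).estimate)
        var = {m: np.var(v) for m, v in est.items()}
        assert var["ratio_mean_of_ratios"] < var["ratio_ratio_of_means"] < var["ls_rto"]
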