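"""Input-integration model: forward evaluation, NLS fitting, reduction, AIC."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest

from aralogic import (
    DoseResponse,
    GradientDesign,
    IntegrationCoefficients,
    PromoterIntegrationModel,
    REFERENCE_COEFFICIENTS,
    coefficient_significance,
    compute_aic,
    fit_integration_model,
    forward_expression,
    reduce_and_compare,
    simulate_gradient_expression,
)


def _noisy_dataset(truth, sigma, seed, design=None):
    rng = np.random.default_rng(seed)
    return simulate_gradient_expression(
        design or GradientDesign(), truth, noise_sigma=sigma, rng=rng
    )


class TestForwardExpression:
    def test_published_arabad_coefficients_at_unit_activity(self):
        coeffs = IntegrationCoefficients(alpha=2.535, gamma=4.347)
        assert forward_expression(1.0, 1.0, 1.0, coeffs) == pytest.approx(6.882)

    def test_structural_zero_beta(self):
        coeffs = IntegrationCoefficients(alpha=1.0, gamma=2.0, basal=7.0)
        # without AraC activity the beta-less model sits at basal whatever C*
        for c in (0.0, 1.0, 10.0):
            assert forward_expression(0.0, c, 1.0, coeffs) == pytest.approx(7.0)

    def test_linear_in_sigma(self):
        coeffs = IntegrationCoefficients(alpha=2.0, beta=0.5, gamma=3.0, basal=4.0)
        b1 = forward_expression(1.5, 0.7, 1.0, coeffs) - coeffs.basal
        b2 = forward_expression(1.5, 0.7, 2.0, coeffs) - coeffs.basal
        assert b2 == pytest.approx(2 * b1)

    def test_negative_activity_rejected(self):
        with pytest.raises(ValueError):
            forward_expression(-1.0, 0.0, 1.0, IntegrationCoefficients(1.0, 1.0))

    def test_occupancy_form_bounded_by_additive(self):
        add = IntegrationCoefficients(alpha=2.0, gamma=3.0, form="additive")
        occ = IntegrationCoefficients(alpha=2.0, gamma=3.0, form="occupancy")
        a, c = 1.3, 0.8
        assert forward_expression(a, c, 1.0, occ) < forward_expression(a, c, 1.0, add)


class TestFitting:
    @pytest.mark.parametrize("promoter", sorted(REFERENCE_COEFFICIENTS))
    def test_noise_free_recovery_is_exact(self, promoter):
        truth = REFERENCE_COEFFICIENTS[promoter]
        df = simulate_gradient_expression(GradientDesign(), truth)
        fit = fit_integration_model(df, terms=("alpha", "gamma"))
        assert fit.coefficients.alpha == pytest.approx(truth.alpha, rel=1e-6)
        assert fit.coefficients.gamma == pytest.approx(truth.gamma, rel=1e-6)
        assert fit.converged

    def test_additive_fit_matches_ols_closed_form(self):
        """The additive model is linear in its parameters, so honest NLS must
        land on the ordinary-least-squares solution (independent oracle)."""
        import statsmodels.api as sm

        truth = IntegrationCoefficients(alpha=1.5, beta=0.4, gamma=2.5, basal=3.0)
        df = _noisy_dataset(truth, sigma=0.1, seed=11)
        fit = fit_integration_model(df)
        a, c, s = (df[k].to_numpy() for k in ("A_star", "C_star", "sigma"))
        X = np.column_stack([s * a, s * c, s * a * c, np.ones(len(df))])
        ols = sm.OLS(df["expression"].to_numpy(), X).fit()
        est = [fit.coefficients.alpha, fit.coefficients.beta,
               fit.coefficients.gamma, fit.coefficients.basal]
        np.testing.assert_allclose(est, ols.params, rtol=1e-8, atol=1e-8)
        np.testing.assert_allclose(
            [fit.standard_errors[t] for t in ("alpha", "beta", "gamma", "basal")],
            ols.bse, rtol=1e-8,
        )

    def test_singular_design_raises(self):
        df = pd.DataFrame(
            {"A_star": np.ones(10), "C_star": np.ones(10), "sigma": np.ones(10),
             "expression": np.ones(10)}
        )
        with pytest.raises(np.linalg.LinAlgError, match="singular"):
            fit_integration_model(df)

    def test_pinned_basal(self):
        truth = IntegrationCoefficients(alpha=2.0, gamma=1.0, basal=5.0)
        df = simulate_gradient_expression(GradientDesign(), truth)
        fit = fit_integration_model(df, terms=("alpha", "gamma"),
                                    fit_basal=False, basal=5.0)
        assert fit.coefficients.basal == 5.0
        assert fit.coefficients.alpha == pytest.approx(2.0, rel=1e-6)

    def test_scale_absorption_leaves_predictions_invariant(self):
        """Rescaling activities by c with (alpha, beta)/c and gamma/c^2 gives
        identical predictions: fitted coefficients are relative quantities."""
        truth = IntegrationCoefficients(alpha=1.5, beta=0.4, gamma=2.5)
        df = _noisy_dataset(truth, sigma=0.05, seed=3)
        X = df[["A_star", "C_star", "sigma"]].to_numpy()
        scale = 2.7
        m1 = PromoterIntegrationModel().fit(X, df["expression"])
        X2 = X.copy()
        X2[:, :2] *= scale
        m2 = PromoterIntegrationModel().fit(X2, df["expression"])
        np.testing.assert_allclose(m2.alpha_, m1.alpha_ / scale, rtol=1e-6)
        np.testing.assert_allclose(m2.gamma_, m1.gamma_ / scale**2, rtol=1e-6)
        np.testing.assert_allclose(m2.predict(X2), m1.predict(X), rtol=1e-8)

    def test_estimator_recovery_bias_shrinks_with_noise(self):
        truth = IntegrationCoefficients(alpha=2.0, gamma=4.0)
        spreads = []
        for sigma in (0.10, 0.05, 0.01):
            ests = []
            for seed in range(20):
                df = _noisy_dataset(truth, sigma=sigma, seed=100 + seed)
                fit = fit_integration_model(df, terms=("alpha", "gamma"))
                ests.append(fit.coefficients.gamma)
            spreads.append(np.std(ests))
        assert spreads[0] > spreads[1] > spreads[2]

    def test_sklearn_interface(self):
        m = PromoterIntegrationModel(terms=("alpha", "gamma"))
        assert m.get_params()["form"] == "additive"
        truth = IntegrationCoefficients(alpha=1.0, gamma=1.0)
        df = simulate_gradient_expression(GradientDesign(), truth)
        X = df[["A_star", "C_star", "sigma"]]
        m.fit(X, df["expression"])
        assert m.score(X, df["expression"]) == pytest.approx(1.0)
        assert m.beta_ is None  # structurally absent


class TestSignificanceAndReduction:
    def test_noise_free_terms_are_significant(self):
        truth = IntegrationCoefficients(alpha=2.535, gamma=4.347)
        df = _noisy_dataset(truth, sigma=1e-9, seed=0)
        fit = fit_integration_model(df, terms=("alpha", "gamma"))
        flags = coefficient_significance(fit)
        assert flags["alpha"] and flags["gamma"]

    def test_level_one_makes_everything_significant(self):
        truth = IntegrationCoefficients(alpha=1.0, gamma=1.0)
        df = _noisy_dataset(truth, sigma=0.3, seed=5)
        fit = fit_integration_model(df)
        assert all(coefficient_significance(fit, level=1.0).values())

    def test_absent_crp_term_fitted_near_zero_and_insignificant(self):
        """Data generated without a CRP-alone contribution: the fitted beta
        should be statistically indistinguishable from zero in the vast
        majority of replicates."""
        truth = IntegrationCoefficients(alpha=2.535, gamma=4.347)
        insignificant = 0
        n_rep = 200
        for seed in range(n_rep):
            df = _noisy_dataset(truth, sigma=0.05, seed=seed)
            fit = fit_integration_model(df)
            if fit.p_values["beta"] > 0.05:
                insignificant += 1
        assert insignificant >= 0.90 * n_rep

    def test_beta_zero_truth_selects_reduced_model(self):
        truth = IntegrationCoefficients(alpha=2.535, gamma=4.347)
        df = _noisy_dataset(truth, sigma=0.05, seed=42)
        comp = reduce_and_compare(df)
        assert "beta" in comp.dropped
        assert comp.selected == "reduced"
        assert comp.reduced.aic < comp.full.aic
        assert comp.reduced.n_params < comp.full.n_params

    def test_all_significant_fit_reports_no_reduction(self):
        truth = IntegrationCoefficients(alpha=2.0, beta=3.0, gamma=4.0)
        df = _noisy_dataset(truth, sigma=0.02, seed=1)
        comp = reduce_and_compare(df)
        assert comp.selected == "no_reduction"
        assert comp.dropped == ()
        assert comp.reduced is comp.full

    def test_strong_beta_is_retained(self):
        truth = IntegrationCoefficients(alpha=2.0, beta=5.0, gamma=4.0)
        df = _noisy_dataset(truth, sigma=0.05, seed=7)
        comp = reduce_and_compare(df)
        assert "beta" not in comp.dropped

    def test_unconverged_fit_rejected(self):
        truth = IntegrationCoefficients(alpha=1.0, gamma=1.0)
        df = _noisy_dataset(truth, sigma=0.05, seed=2)
        fit = fit_integration_model(df)
        fit.converged = False
        with pytest.raises(ValueError, match="converge"):
            coefficient_significance(fit)


class TestAic:
    def test_direct_evaluation(self):
        assert compute_aic(rss=10.0, n_obs=10, n_params=2) == pytest.approx(6.0)

    def test_useless_parameter_costs_two(self):
        assert compute_aic(5.0, 20, 3) - compute_aic(5.0, 20, 2) == pytest.approx(2.0)

    def test_halving_rss_gains_n_log_two(self):
        delta = compute_aic(8.0, 20, 2) - compute_aic(4.0, 20, 2)
        assert delta == pytest.approx(20 * math.log(2))

    def test_zero_rss_sentinel(self):
        with pytest.warns(UserWarning, match="-inf"):
            assert compute_aic(0.0, 10, 2) == float("-inf")

    def test_saturated_fit_rejected(self):
        with pytest.raises(ValueError):
            compute_aic(1.0, 3, 3)
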