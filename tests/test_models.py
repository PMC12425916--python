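"""Model builders and closed-form focal effects, cross-checked against
independent oracles (OLS regression, RAM path tracing, self-generated data)."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from clpm_scrutiny import (
    ConvergenceError,
    DegenerateDataError,
    beta_change,
    beta_lagged,
    beta_reversed,
    build_artifact_model,
    build_clpm,
    build_lcsm,
    build_reversed_clpm,
    baseline_chi2,
    fit_indices,
    fit_ml,
    focal_effect,
    model_implied_sigma,
    sample_mvn,
)
from clpm_scrutiny.simulate import random_correlation_matrix

reasonable_r = st.floats(-0.85, 0.85)


class TestClosedForms:
    def test_lagged_vanishing_numerator(self):
        assert beta_lagged(0.18, 0.3, 0.6) == pytest.approx(0.0, abs=1e-15)

    def test_lagged_reduces_to_zero_order(self):
        assert beta_lagged(0.4, 0.0, 0.5) == pytest.approx(0.4)

    def test_lagged_frozen_value(self):
        assert beta_lagged(0.5, 0.3, 0.6) == pytest.approx(0.32 / 0.91)

    def test_change_zero_when_correlations_equal(self):
        assert beta_change(0.3, 0.3, 0.6) == 0.0

    def test_change_frozen_value(self):
        assert beta_change(0.5, 0.3, 0.6) == pytest.approx(0.2 / math.sqrt(0.8))

    @given(reasonable_r, reasonable_r, reasonable_r)
    def test_change_antisymmetric(self, a, b, r):
        assert beta_change(a, b, r) == pytest.approx(-beta_change(b, a, r), abs=1e-12)

    def test_reversed_frozen_value(self):
        assert beta_reversed(0.4, 0.2, 0.5) == pytest.approx(0.3125)

    def test_reversed_vanishing_numerator(self):
        assert beta_reversed(0.3, 0.5, 0.6) == pytest.approx(0.0, abs=1e-15)

    @given(reasonable_r, reasonable_r, reasonable_r)
    def test_reversed_is_lagged_with_waves_exchanged(self, r1, r2, rc):
        assert beta_reversed(r1, r2, rc) == pytest.approx(
            beta_lagged(r1, r2, rc), abs=1e-12)

    def test_degenerate_inputs(self):
        with pytest.raises(DegenerateDataError):
            beta_lagged(0.5, 1.0, 0.5)
        with pytest.raises(DegenerateDataError):
            beta_change(0.5, 0.3, 1.0)
        with pytest.raises(DegenerateDataError):
            beta_reversed(0.5, 1.0, 0.5)

    def test_against_ols_oracle(self, example_record):
        """The lagged formula is the standardized two-predictor OLS slope."""
        import statsmodels.api as sm

        from clpm_scrutiny import correlation_matrix

        target = correlation_matrix(example_record)
        df = sample_mvn(target, 542, "exact", seed=9).to_frame()
        ols = sm.OLS(df["E2"], sm.add_constant(df[["P1", "E1"]])).fit()
        expected = beta_lagged(0.3, 0.4, 0.6)
        assert ols.params["P1"] == pytest.approx(expected, abs=1e-10)
        # SEM expected-information SE agrees with OLS up to finite-n scaling
        fit = fit_ml(build_clpm(), df.cov(ddof=0).to_numpy(), 542)
        eff = focal_effect(fit, "clpm")
        assert eff.b == pytest.approx(expected, abs=1e-6)
        assert eff.se == pytest.approx(ols.bse["P1"], rel=0.05)


class TestBuilders:
    @pytest.mark.parametrize("builder,n_free,df", [
        (build_clpm, 10, 0),
        (build_reversed_clpm, 6, 0),
        (build_lcsm, 10, 0),
        (lambda: build_artifact_model(1), 4, 6),
        (lambda: build_artifact_model(-1), 4, 6),
    ])
    def test_parameter_counts(self, builder, n_free, df):
        spec = builder()
        assert spec.n_free == n_free
        assert spec.degrees_of_freedom() == df

    def test_artifact_sign_validated(self):
        with pytest.raises(Exception, match="sign"):
            build_artifact_model(0)

    def test_artifact_negative_sign_implies_negative_cross_correlations(self):
        spec = build_artifact_model(-1)
        theta = {"v_gneg": 0.3, "theta_p": 0.7, "theta_e": 0.7, "state_cov": 0.0}
        sigma = model_implied_sigma(spec, theta)
        # cross-construct block (P x E) must be negative when var(gNeg) > 0
        assert np.all(sigma[:2, 2:] < 0)

    def test_artifact_cross_block_is_rank_one_plus_state(self):
        spec = build_artifact_model(1)
        theta = {"v_gneg": 0.25, "theta_p": 0.6, "theta_e": 0.8, "state_cov": 0.07}
        sigma = model_implied_sigma(spec, theta)
        cross = sigma[:2, 2:] - 0.07 * np.eye(2)
        assert np.linalg.matrix_rank(cross, tol=1e-10) == 1

    def test_artifact_implied_matches_hand_computed_factor_algebra(self):
        # brute-force path tracing of the second-order factor model
        v, tp, te, c, sign = 0.3, 0.7, 0.7, 0.1, 1.0
        expected = np.array([
            [v + tp,       v,            sign * v + c, sign * v],
            [v,            v + tp,       sign * v,     sign * v + c],
            [sign * v + c, sign * v,     v + te,       v],
            [sign * v,     sign * v + c, v,            v + te],
        ])
        sigma = model_implied_sigma(
            build_artifact_model(1),
            {"v_gneg": v, "theta_p": tp, "theta_e": te, "state_cov": c})
        assert np.allclose(sigma, expected, atol=1e-12)


class TestSemOracleEquivalence:
    @pytest.mark.parametrize("seed", range(40))
    def test_fitted_focal_effects_match_closed_forms(self, seed):
        """SEM estimates on exact-mode data equal the correlation formulas."""
        target = random_correlation_matrix(seed)
        m = target.matrix
        x = sample_mvn(target, 200, "exact", seed=seed).scores
        s = (x - x.mean(0)).T @ (x - x.mean(0)) / 200

        fit_a = fit_ml(build_clpm(), s, 200)
        assert focal_effect(fit_a, "clpm").b == pytest.approx(
            beta_lagged(m[0, 3], m[0, 2], m[2, 3]), abs=1e-6)

        idx = np.ix_([0, 2, 3], [0, 2, 3])
        fit_b = fit_ml(build_reversed_clpm(), s[idx], 200)
        assert focal_effect(fit_b, "reversed").b == pytest.approx(
            beta_reversed(m[0, 2], m[0, 3], m[2, 3]), abs=1e-6)

        fit_c = fit_ml(build_lcsm(), s, 200)
        assert focal_effect(fit_c, "lcsm").b == pytest.approx(
            beta_change(m[0, 3], m[0, 2], m[2, 3]), abs=1e-6)


class TestGenuineEffectSignature:
    def test_sign_pattern_over_parameter_grid(self):
        """With a true positive cross path (and no baseline confounding) the
        CLPM focal is +, the time-reversed focal is -, the change focal is +."""
        from clpm_scrutiny import GenuineDGP, implied_correlations_genuine

        for stability in (0.2, 0.45, 0.7):
            for cross in (0.1, 0.25, 0.4):
                dgp = GenuineDGP(stability_p=stability, stability_e=stability,
                                 cross_pe=cross, cross_ep=0.0, r0=0.0)
                m = implied_correlations_genuine(dgp).matrix
                assert beta_lagged(m[0, 3], m[0, 2], m[2, 3]) > 0
                assert beta_reversed(m[0, 2], m[0, 3], m[2, 3]) < 0
                assert beta_change(m[0, 3], m[0, 2], m[2, 3]) > 0


class TestFocalEffect:
    def test_null_effect_has_p_one(self):
        target = random_correlation_matrix(0)
        m = np.eye(4)  # independent variables: focal effect exactly 0
        from clpm_scrutiny.simulate import CorrelationMatrix4

        x = sample_mvn(CorrelationMatrix4(m), 200, "exact", seed=1).scores
        s = (x - x.mean(0)).T @ (x - x.mean(0)) / 200
        eff = focal_effect(fit_ml(build_clpm(), s, 200), "clpm")
        assert eff.b == pytest.approx(0.0, abs=1e-8)
        assert eff.p_value > 0.999
        assert not eff.significant

    def test_wald_interval_consistency(self, example_record):
        from clpm_scrutiny import correlation_matrix

        target = correlation_matrix(example_record)
        x = sample_mvn(target, 542, "exact", seed=2).scores
        s = (x - x.mean(0)).T @ (x - x.mean(0)) / 542
        eff = focal_effect(fit_ml(build_clpm(), s, 542), "clpm")
        assert eff.ci95[0] < eff.b < eff.ci95[1]
        assert eff.significant == (not eff.ci95[0] <= 0.0 <= eff.ci95[1])

    def test_refuses_non_converged_fit(self):
        fit = fit_ml(build_clpm(), np.eye(4), 100)
        fit.converged = False
        with pytest.raises(ConvergenceError):
            focal_effect(fit, "clpm")

    def test_lcsm_standardization_uses_implied_change_variance(self):
        """Standardized LCSM focal = raw path / sd(E2 - E1)."""
        target = random_correlation_matrix(21)
        x = sample_mvn(target, 300, "exact", seed=3).scores
        s = (x - x.mean(0)).T @ (x - x.mean(0)) / 300
        fit = fit_ml(build_lcsm(), s, 300)
        raw = fit.theta["b_p1_de"]
        sd_change = math.sqrt(2 * (1 - target.matrix[2, 3]))
        assert focal_effect(fit, "lcsm").b == pytest.approx(raw / sd_change, abs=1e-6)


class TestArtifactSelfFit:
    def test_data_generated_under_model_fit_perfectly(self):
        """Exact data from the artifactualness model: zero misfit, exact recovery."""
        from clpm_scrutiny import ArtifactualDGP, implied_correlations_artifactual

        dgp = ArtifactualDGP()
        r = implied_correlations_artifactual(dgp)
        x = sample_mvn(r, 1000, "exact", seed=4).scores
        s = (x - x.mean(0)).T @ (x - x.mean(0)) / 1000
        fit = fit_ml(build_artifact_model(dgp.sign), s, 1000)
        assert fit.chi2 < 1e-6
        for lab, truth in dgp.model_theta().items():
            assert fit.theta[lab] == pytest.approx(truth, abs=1e-4)
        fi = fit_indices(fit, baseline_chi2(s, 1000))
        assert fi.cfi == pytest.approx(1.0)
        assert fi.rmsea == pytest.approx(0.0)
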