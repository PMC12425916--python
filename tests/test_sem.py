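"""The ML SEM engine: RAM algebra, discrepancy, fitting, fit indices."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from clpm_scrutiny import (
    IdentificationError,
    NumericalError,
    SemModel,
    SemSpec,
    ValidationError,
    baseline_chi2,
    fit_indices,
    fit_ml,
    independence_spec,
    ml_discrepancy,
    model_implied_sigma,
    rmsea_ci,
    saturated_spec,
)
from clpm_scrutiny.simulate import random_correlation_matrix


class TestImpliedSigma:
    def test_no_paths_unit_variances_is_identity(self):
        spec = SemSpec(["x", "y"], ["x", "y"])
        spec.add_variance("x", fixed=1.0).add_variance("y", fixed=1.0)
        assert np.allclose(model_implied_sigma(spec, {}), np.eye(2))

    def test_single_path_rule(self):
        # x -> y with coefficient b, unit exogenous variance, residual 1-b^2
        b = 0.37
        spec = SemSpec(["x", "y"], ["x", "y"])
        spec.add_path("x", "y", free="b")
        spec.add_variance("x", fixed=1.0)
        spec.add_variance("y", fixed=1.0 - b ** 2)
        sigma = model_implied_sigma(spec, {"b": b})
        assert sigma[0, 1] == pytest.approx(b)
        assert sigma[1, 1] == pytest.approx(1.0)

    def test_missing_label_rejected(self):
        spec = SemSpec(["x", "y"], ["x", "y"])
        spec.add_path("x", "y", free="b")
        spec.add_variance("x", fixed=1.0).add_variance("y", fixed=1.0)
        with pytest.raises(ValidationError, match="b"):
            model_implied_sigma(spec, {})

    def test_cyclic_structure_rejected(self):
        spec = SemSpec(["x", "y"], ["x", "y"])
        spec.add_path("x", "y", free="a").add_path("y", "x", free="b")
        spec.add_variance("x", fixed=1.0).add_variance("y", fixed=1.0)
        with pytest.raises(ValidationError, match="cyclic"):
            model_implied_sigma(spec, {"a": 0.5, "b": 0.5})


class TestMlDiscrepancy:
    def test_zero_at_identity(self, rng):
        a = rng.standard_normal((4, 4))
        s = a @ a.T + 4 * np.eye(4)
        assert ml_discrepancy(s, s) == pytest.approx(0.0, abs=1e-12)

    def test_direct_evaluation(self):
        # F(2I, I) = log|2I| + tr(I/2) - 0 - 2 = 2 log 2 - 1
        assert ml_discrepancy(2 * np.eye(2), np.eye(2)) == pytest.approx(
            2 * math.log(2) - 1, abs=1e-12)

    @given(st.integers(0, 1000))
    def test_strictly_positive_away_from_s(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.standard_normal((3, 3))
        s = a @ a.T + 3 * np.eye(3)
        b = rng.standard_normal((3, 3))
        sigma = b @ b.T + 3 * np.eye(3)
        if not np.allclose(sigma, s):
            assert ml_discrepancy(sigma, s) > 0

    def test_non_pd_rejected(self):
        with pytest.raises(NumericalError):
            ml_discrepancy(np.array([[1.0, 2.0], [2.0, 1.0]]), np.eye(2))


class TestFitMl:
    def test_saturated_model_reproduces_sample_moments(self):
        r = random_correlation_matrix(3).matrix
        fit = fit_ml(saturated_spec(["P1", "P2", "E1", "E2"]), r, 200)
        assert fit.df == 0
        assert fit.chi2 < 1e-8
        sigma = fit.sigma_hat
        assert np.abs(sigma - r).max() < 1e-6

    def test_restricted_model_has_larger_chi2(self):
        # likelihood monotonicity for nested specs on the same data
        r = random_correlation_matrix(5).matrix
        full = fit_ml(saturated_spec(["P1", "P2", "E1", "E2"]), r, 150)
        restricted = fit_ml(independence_spec(["P1", "P2", "E1", "E2"]), r, 150)
        assert restricted.chi2 >= full.chi2 >= 0

    def test_standard_errors_scale_as_inverse_sqrt_n(self):
        r = random_correlation_matrix(7).matrix
        fit1 = fit_ml(saturated_spec(["P1", "P2", "E1", "E2"]), r, 500)
        fit2 = fit_ml(saturated_spec(["P1", "P2", "E1", "E2"]), r, 1000)
        for lab in fit1.labels:
            assert fit2.se[lab] / fit1.se[lab] == pytest.approx(1 / math.sqrt(2), rel=0.02)

    def test_overparameterized_spec_rejected(self):
        spec = SemSpec(["f", "x"], ["x"])
        spec.add_path("f", "x", free="loading")
        spec.add_variance("f", free="vf")
        spec.add_variance("x", free="vx")
        with pytest.raises(IdentificationError):
            fit_ml(spec, np.array([[1.0]]), 100)

    def test_non_pd_sample_matrix_rejected(self):
        s = np.array([[1.0, 1.0], [1.0, 1.0]])
        spec = saturated_spec(["x", "y"])
        with pytest.raises(NumericalError):
            fit_ml(spec, s, 100)


class TestBaseline:
    def test_diagonal_sample_matrix_fits_perfectly(self):
        chi2_b, df_b = baseline_chi2(np.diag([1.0, 2.0, 0.5]), 300)
        assert chi2_b == pytest.approx(0.0, abs=1e-10)
        assert df_b == 3

    def test_four_variables_have_six_baseline_df(self):
        assert baseline_chi2(np.eye(4), 100)[1] == 6

    def test_bivariate_closed_form(self):
        s = np.array([[1.0, 0.5], [0.5, 1.0]])
        chi2_b, df_b = baseline_chi2(s, 100)
        assert chi2_b == pytest.approx(-100 * math.log(1 - 0.25), rel=1e-10)
        assert df_b == 1

    def test_matches_iterative_engine(self):
        r = random_correlation_matrix(11).matrix
        chi2_b, _ = baseline_chi2(r, 250)
        fit = fit_ml(independence_spec(["P1", "P2", "E1", "E2"]), r, 250)
        assert fit.chi2 == pytest.approx(chi2_b, abs=1e-6)


class TestFitIndices:
    def _fit_with_chi2(self, chi2, df, n):
        """A minimal stand-in SemFit carrying the given test statistic."""
        from clpm_scrutiny.sem import SemFit

        return SemFit(spec=saturated_spec(["x"]), theta={}, se={},
                      sigma_hat=np.eye(4), sigma_full=np.eye(4), chi2=chi2,
                      df=df, n=n, converged=True, n_iter=1, fmin=chi2 / n,
                      s_sample=np.eye(4), labels=[], param_cov=np.zeros((0, 0)))

    def test_perfect_fit(self):
        fi = fit_indices(self._fit_with_chi2(0.0, 6, 500), baseline=(120.0, 6))
        assert fi.cfi == 1.0
        assert fi.tli == 1.0
        assert fi.rmsea == 0.0
        assert fi.srmr == pytest.approx(0.0)

    @pytest.mark.parametrize("chi2,n,expected", [
        (50.6, 1226, 0.08),  # printed pair, df = 6
        (21.0, 542, 0.07),   # printed pair, df = 6
    ])
    def test_rmsea_matches_printed_values(self, chi2, n, expected):
        fi = fit_indices(self._fit_with_chi2(chi2, 6, n), baseline=(1000.0, 6))
        assert round(fi.rmsea, 2) == expected

    def test_saturated_df_zero_reports_not_applicable(self):
        fi = fit_indices(self._fit_with_chi2(0.0, 0, 500), baseline=(120.0, 6))
        assert fi.cfi == 1.0
        assert math.isnan(fi.tli)
        assert math.isnan(fi.rmsea)

    def test_baseline_df_must_dominate(self):
        with pytest.raises(ValidationError):
            fit_indices(self._fit_with_chi2(5.0, 7, 100), baseline=(10.0, 6))


class TestRmseaCI:
    def test_zero_lower_bound_when_chi2_below_df(self):
        lo, hi = rmsea_ci(4.0, 6, 500)
        assert lo == 0.0
        assert hi >= 0.0

    @pytest.mark.parametrize("chi2,n,expected", [
        (50.6, 1226, (0.06, 0.10)),  # printed 90% CI
        (21.0, 542, (0.04, 0.10)),   # printed 90% CI
    ])
    def test_matches_printed_intervals(self, chi2, n, expected):
        lo, hi = rmsea_ci(chi2, 6, n)
        assert (round(lo, 2), round(hi, 2)) == expected

    def test_monotone_in_chi2(self):
        bounds = [rmsea_ci(c, 6, 300) for c in (5.0, 10.0, 20.0, 40.0, 80.0)]
        for (lo1, hi1), (lo2, hi2) in zip(bounds, bounds[1:]):
            assert lo2 >= lo1
            assert hi2 >= hi1

    def test_df_zero_rejected(self):
        with pytest.raises(ValidationError):
            rmsea_ci(1.0, 0, 100)


class TestSpecSerialization:
    def test_json_round_trip_preserves_model(self, tmp_path):
        from clpm_scrutiny import build_lcsm

        spec = build_lcsm()
        path = tmp_path / "lcsm.json"
        spec.to_json(path)
        back = SemSpec.from_json(path)
        assert back.labels == spec.labels
        assert back.degrees_of_freedom() == spec.degrees_of_freedom()
        assert back.focal == spec.focal
        theta = {lab: 0.2 for lab in spec.labels}
        for lab in spec.labels:  # keep variances positive
            if lab.startswith("v"):
                theta[lab] = 0.8
        assert np.allclose(model_implied_sigma(spec, theta),
                           model_implied_sigma(back, theta))

    def test_equation_rendering_mentions_every_variable(self):
        from clpm_scrutiny import build_clpm

        text = build_clpm().equations()
        for name in ("P1", "P2", "E1", "E2"):
            assert name in text


class TestSemModelEstimator:
    def test_fits_raw_data_like_sklearn(self, example_record):
        from clpm_scrutiny import build_clpm, correlation_matrix, sample_mvn

        target = correlation_matrix(example_record)
        data = sample_mvn(target, 300, "exact", seed=1)
        model = SemModel(build_clpm()).fit(data.to_frame())
        assert model.converged_
        assert model.chi2_ < 1e-8
        assert set(model.theta_) == set(model.labels_)

    def test_get_params_round_trip(self):
        from clpm_scrutiny import build_clpm

        model = SemModel(build_clpm(), chi2_multiplier="n-1")
        params = model.get_params()
        assert params["chi2_multiplier"] == "n-1"
        clone = SemModel(**params)
        assert clone.chi2_multiplier == "n-1"
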