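"""Response basis, mean prediction, likelihood/posterior densities."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ppgr.io import AnalysisDataset
from ppgr.model import (
    GroupParams,
    PatientParams,
    PriorConfig,
    log_likelihood,
    log_posterior,
    population_response_curve,
    predict_mean,
    response_basis,
    summarize_posterior,
    variance_explained,
)
from conftest import make_dataset


class TestResponseBasis:
    def test_unit_peak_at_meal_time(self):
        assert response_basis(37.0, 37.0, 20.0) == 1.0

    def test_one_length_scale_away(self):
        assert response_basis(57.0, 37.0, 20.0) == pytest.approx(np.exp(-0.5))

    @given(st.floats(-200, 200), st.floats(1, 60))
    @settings(max_examples=50, derandomize=True)
    def test_symmetry(self, x, alpha):
        tau = 100.0
        assert response_basis(tau + x, tau, alpha) == pytest.approx(
            float(response_basis(tau - x, tau, alpha))
        )

    def test_nonpositive_alpha_rejected(self):
        with pytest.raises(ValueError):
            response_basis(0.0, 0.0, 0.0)


class TestPredictMean:
    def test_no_meals_gives_constant_baseline(self):
        p = PatientParams(beta=0.05, alpha=20, baseline=5.3, noise_sd=0.3)
        t = np.arange(0, 1440, 15.0)
        assert np.all(predict_mean(p, [], [], t) == 5.3)

    def test_single_meal_peak_excess(self):
        # 30 g at beta 0.086 mmol/l/g -> 2.58 mmol/l above baseline at the meal
        p = PatientParams(
            beta=0.086, alpha=20, baseline=5.0, noise_sd=0.3, offsets=[0.0]
        )
        t = np.arange(0, 1440, 1.0)
        curve = predict_mean(p, [720.0], [30.0], t)
        assert np.max(curve) - 5.0 == pytest.approx(0.086 * 30, abs=1e-9)
        assert t[np.argmax(curve)] == 720.0

    def test_linearity_in_carbs(self, rng):
        ds, params = make_dataset(rng)
        base = predict_mean(params, ds.meal_times_min, ds.meal_carbs, ds.times_min)
        double = predict_mean(
            params, ds.meal_times_min, 2 * ds.meal_carbs, ds.times_min
        )
        np.testing.assert_allclose(
            double - params.baseline, 2 * (base - params.baseline),
            rtol=1e-9, atol=1e-12,
        )

    def test_monotone_in_single_meal_carbs(self, rng):
        ds, params = make_dataset(rng)
        carbs_up = ds.meal_carbs.copy()
        carbs_up[1] += 10.0
        lo = predict_mean(params, ds.meal_times_min, ds.meal_carbs, ds.times_min)
        hi = predict_mean(params, ds.meal_times_min, carbs_up, ds.times_min)
        assert np.all(hi >= lo)

    def test_offset_count_mismatch_rejected(self):
        p = PatientParams(beta=0.05, alpha=20, baseline=5.3, noise_sd=0.3)
        with pytest.raises(ValueError, match="offsets"):
            predict_mean(p, [100.0], [30.0], np.arange(5.0))


class TestLogDensities:
    def test_zero_residuals_closed_form(self, rng):
        ds, params = make_dataset(rng, n_meals=2, n_samples=50)
        ds.glucose = predict_mean(
            params, ds.meal_times_min, ds.meal_carbs, ds.times_min
        )
        n = ds.times_min.size
        expect = -(n / 2) * np.log(2 * np.pi * params.noise_sd**2)
        assert log_likelihood(params, ds) == pytest.approx(expect, abs=1e-9)

    def test_larger_residual_decreases_likelihood(self, rng):
        ds, params = make_dataset(rng)
        base = log_likelihood(params, ds)
        mu = predict_mean(params, ds.meal_times_min, ds.meal_carbs, ds.times_min)
        r5 = ds.glucose[5] - mu[5]
        ds.glucose[5] = mu[5] + abs(r5) + 1.0  # strictly larger residual
        assert log_likelihood(params, ds) < base

    def test_missing_samples_excluded(self, rng):
        ds, params = make_dataset(rng)
        full = log_likelihood(params, ds)
        ds2 = AnalysisDataset(
            patient_id=ds.patient_id,
            period=ds.period,
            window_start=ds.window_start,
            times_min=np.append(ds.times_min, ds.times_min[-1] + 15),
            glucose=np.append(ds.glucose, np.nan),
            meal_times_min=ds.meal_times_min,
            meal_carbs=ds.meal_carbs,
        )
        assert log_likelihood(params, ds2) == pytest.approx(full, abs=1e-12)

    def test_nonpositive_noise_rejected(self, rng):
        ds, params = make_dataset(rng)
        params.noise_sd = 0.0
        with pytest.raises(ValueError):
            log_likelihood(params, ds)

    def test_prior_only_when_no_data(self, rng):
        ds, params = make_dataset(rng)
        group = GroupParams(beta_g=0.05, alpha_g=20, sd_beta=0.02, sd_alpha=0.3)
        prior = PriorConfig()
        with_data = log_posterior(params, group, prior, ds)
        prior_only = log_posterior(params, group, prior, None)
        assert with_data == pytest.approx(
            prior_only + log_likelihood(params, ds), abs=1e-9
        )

    def test_out_of_support_is_neg_inf_not_exception(self, rng):
        ds, params = make_dataset(rng)
        group = GroupParams(beta_g=0.05, alpha_g=20, sd_beta=0.02, sd_alpha=0.3)
        params.offsets = params.offsets + 200.0  # beyond the +/-60 min bound
        assert log_posterior(params, group, PriorConfig(), ds) == -np.inf

    def test_zero_offsets_maximize_offset_prior(self, rng):
        ds, params = make_dataset(rng, n_meals=2)
        group = GroupParams(beta_g=0.05, alpha_g=20, sd_beta=0.02, sd_alpha=0.3)
        prior = PriorConfig()
        params.offsets = np.zeros(2)
        at_zero = log_posterior(params, group, prior, None)
        params.offsets = np.array([5.0, -3.0])
        assert log_posterior(params, group, prior, None) < at_zero


class TestVarianceExplained:
    def test_perfect_fit_is_100(self, rng):
        y = rng.normal(5, 1, 50)
        assert variance_explained(y, y) == 100.0

    def test_null_model_is_0(self, rng):
        y = rng.normal(5, 1, 50)
        assert variance_explained(y, np.full(50, y.mean())) == pytest.approx(
            0.0, abs=1e-9
        )

    def test_matches_formula_oracle(self, rng):
        y = rng.normal(5, 1, 40)
        f = y + rng.normal(0, 0.5, 40)
        expect = 100 * (1 - np.var(y - f, ddof=1) / np.var(y, ddof=1))
        assert variance_explained(y, f) == pytest.approx(expect, abs=1e-9)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            variance_explained(np.ones(5), np.zeros(5))


def _point_mass_result(beta, alpha, n=5):
    from ppgr.model import PosteriorResult

    draws = {
        "beta_g": np.full((1, n), beta),
        "alpha_g": np.full((1, n), alpha),
        "sd_beta": np.full((1, n), 0.01),
        "sd_alpha": np.full((1, n), 0.1),
    }
    diag = pd.DataFrame(columns=["parameter", "patient", "rhat", "ess"])
    return PosteriorResult(
        draws=draws,
        patient_ids=[],
        group="G",
        period="pre",
        seed=0,
        sampler_settings={},
        diagnostics=diag,
        converged=True,
    )


class TestPopulationCurve:
    def test_peak_is_beta_mean_for_unit_carb(self):
        res = _point_mass_result(0.086, 19.6)
        curve = population_response_curve(res, 1.0, np.array([0.0]))
        assert curve["mean"].iloc[0] == pytest.approx(0.086)

    def test_pre_post_shape_comparison(self):
        # post: higher + narrower; pre: lower + wider. Areas scale as beta*alpha.
        grid = np.arange(-120.0, 120.5, 0.5)
        post = population_response_curve(_point_mass_result(0.086, 19.6), 1.0, grid)
        pre = population_response_curve(_point_mass_result(0.046, 22.8), 1.0, grid)
        assert post["mean"].max() > pre["mean"].max()
        area_post = np.trapezoid(post["mean"], grid)
        area_pre = np.trapezoid(pre["mean"], grid)
        assert area_post / area_pre == pytest.approx(
            (0.086 * 19.6) / (0.046 * 22.8), rel=1e-3
        )

    def test_point_mass_area_closed_form(self):
        grid = np.arange(-200.0, 200.25, 0.25)
        curve = population_response_curve(_point_mass_result(0.05, 20.0), 40.0, grid)
        expect = 0.05 * 40.0 * 20.0 * np.sqrt(2 * np.pi)
        assert np.trapezoid(curve["mean"], grid) == pytest.approx(expect, rel=1e-4)

    def test_negative_carbs_rejected(self):
        with pytest.raises(ValueError):
            population_response_curve(_point_mass_result(0.05, 20), -1.0, np.arange(3.0))


class TestSummarize:
    def test_degenerate_point_mass(self):
        res = _point_mass_result(0.05, 20.0)
        s = summarize_posterior(res).set_index("parameter")
        assert s.loc["beta_g", "mean"] == 0.05
        assert s.loc["beta_g", "q2.5"] == s.loc["beta_g", "q97.5"] == 0.05

    def test_quantile_rule_linear_interpolation(self):
        res = _point_mass_result(0.05, 20.0, n=100)
        res.draws["beta_g"] = np.arange(1.0, 101.0).reshape(1, 100)
        s = summarize_posterior(res).set_index("parameter")
        assert s.loc["beta_g", "q2.5"] == pytest.approx(3.475)
        assert s.loc["beta_g", "q97.5"] == pytest.approx(97.525)

    def test_one_row_per_patient_parameter(self):
        res = _point_mass_result(0.05, 20.0)
        P = 10
        res.patient_ids = [f"P{i:02d}" for i in range(P)]
        for name in res.PATIENT_PARAMS:
            res.draws[name] = np.tile(np.linspace(1, 2, 5), (1, 1, P)).reshape(1, 5, P)
        s = summarize_posterior(res)
        assert (s["parameter"] == "beta_p").sum() == P
        assert np.all(s["q2.5"] <= s["mean"]) and np.all(s["mean"] <= s["q97.5"])
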