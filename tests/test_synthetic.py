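"""Synthetic cohort generator: determinism, moments, superposition."""

import numpy as np
import pytest

from ppgr.model import PatientParams, predict_mean
from ppgr.synthetic import (
    MIN_MEAL_GAP,
    WAKE_END,
    WAKE_START,
    SimulationConfig,
    generate_cohort,
    jitter_meal_times,
    make_meal_schedule,
    simulate_trace,
)


class TestSimulationConfig:
    def test_default_cohort_shape(self):
        cfg = SimulationConfig()
        assert cfg.n_patients_per_group == {"RYGB": 10, "OAGB": 7}
        assert cfg.n_samples == 288  # 3 days at 15-minute sampling

    @pytest.mark.parametrize(
        "kw",
        [
            {"noise_sd": -0.1},
            {"carb_range": (50, 10)},
            {"days": 0},
            {"sample_interval": 7.0},
            {"report_jitter_sd": -1},
            {"group_beta_mean": {("RYGB", "pre"): -0.01}},
        ],
    )
    def test_invalid_config_rejected(self, kw):
        with pytest.raises(ValueError):
            SimulationConfig(**kw)


class TestSimulateTrace:
    def test_no_meals_no_noise_is_flat_baseline(self):
        p = PatientParams(beta=0.05, alpha=20, baseline=5.3, noise_sd=0.0)
        tr = simulate_trace(p, [], [], np.arange(0, 1440, 15.0), rng=0)
        assert np.all(tr.glucose == 5.3)

    def test_single_meal_peak_height(self):
        # 30 g at beta 0.086 -> excess of exactly 2.58 mmol/l at the meal time
        p = PatientParams(beta=0.086, alpha=20.0, baseline=5.0, noise_sd=0.0)
        grid = np.arange(0, 1440, 1.0)
        tr = simulate_trace(p, [600.0], [30.0], grid, rng=0)
        assert np.max(tr.glucose) - 5.0 == pytest.approx(0.086 * 30, abs=1e-12)
        assert grid[np.argmax(tr.glucose)] == 600.0

    def test_noise_moment_recovery(self):
        p = PatientParams(beta=0.0, alpha=20, baseline=5.0, noise_sd=0.3)
        tr = simulate_trace(p, [], [], np.arange(10_000, dtype=float), rng=5)
        assert np.std(tr.glucose - 5.0) == pytest.approx(0.3, rel=0.05)

    def test_empty_grid_rejected(self):
        p = PatientParams(beta=0.05, alpha=20, baseline=5.3, noise_sd=0.0)
        with pytest.raises(ValueError):
            simulate_trace(p, [], [], np.array([]), rng=0)

    def test_superposition_of_coincident_meals(self):
        p = PatientParams(beta=0.05, alpha=20, baseline=5.0, noise_sd=0.0)
        grid = np.arange(0, 1440, 15.0)
        two = simulate_trace(p, [600.0, 600.0], [20.0, 15.0], grid, rng=0)
        one = simulate_trace(p, [600.0], [35.0], grid, rng=0)
        np.testing.assert_allclose(two.glucose, one.glucose, atol=1e-12)

    def test_noise_free_trace_equals_predict_mean(self):
        p = PatientParams(
            beta=0.06, alpha=25, baseline=5.5, noise_sd=0.0, offsets=[3.0, -7.0]
        )
        grid = np.arange(0, 1440, 15.0)
        tr = simulate_trace(p, [300.0, 800.0], [40.0, 20.0], grid, rng=1)
        mu = predict_mean(p, [300.0, 800.0], [40.0, 20.0], grid)
        np.testing.assert_allclose(tr.glucose, mu, atol=1e-12)


class TestJitter:
    def test_zero_sd_is_identity(self):
        t = np.array([100.0, 500.0])
        np.testing.assert_array_equal(jitter_meal_times(t, 0.0, 3), t)

    def test_seeded_determinism(self):
        t = np.arange(5, dtype=float) * 200
        np.testing.assert_array_equal(
            jitter_meal_times(t, 15.0, 7), jitter_meal_times(t, 15.0, 7)
        )

    def test_negative_sd_rejected(self):
        with pytest.raises(ValueError):
            jitter_meal_times(np.array([1.0]), -1.0, 0)

    def test_moment_recovery(self):
        t = np.zeros(10_000)
        j = jitter_meal_times(t, 15.0, 9)
        assert np.std(j - t) == pytest.approx(15.0, rel=0.05)


class TestSchedule:
    def test_waking_hours_and_gap(self):
        rng = np.random.default_rng(4)
        for meals in (3, 5, 8):
            times = make_meal_schedule(rng, days=3, meals_per_day=meals)
            assert times.size == 3 * meals
            day_time = times % 1440
            assert np.all(day_time >= WAKE_START) and np.all(day_time <= WAKE_END)
            for d in range(3):
                day = times[(times >= d * 1440) & (times < (d + 1) * 1440)]
                if day.size > 1:
                    assert np.min(np.diff(day)) >= MIN_MEAL_GAP - 1e-9


class TestGenerateCohort:
    def test_default_shape_matches_study(self):
        cohort = generate_cohort(SimulationConfig(days=1, seed=3))
        assert len(cohort.select("RYGB", "pre")) == 10
        assert len(cohort.select("OAGB", "pre")) == 7
        assert len(cohort.patients) == 2 * (10 + 7)
        for p in cohort.patients:
            assert p.trace.n_samples == 96
            assert p.reported_meal_times.size == p.true_meal_times.size

    def test_seeded_determinism(self):
        cfg = SimulationConfig(n_patients_per_group={"G": 2},
                               group_beta_mean={("G", "pre"): 0.05, ("G", "post"): 0.08},
                               group_alpha_mean={("G", "pre"): 20.0, ("G", "post"): 19.0},
                               days=1, seed=42)
        a, b = generate_cohort(cfg), generate_cohort(cfg)
        for pa, pb in zip(a.patients, b.patients):
            np.testing.assert_array_equal(pa.trace.glucose, pb.trace.glucose)
            np.testing.assert_array_equal(pa.reported_meal_times, pb.reported_meal_times)
            assert pa.params.beta == pb.params.beta

    def test_degenerate_hierarchy_pins_beta_to_group_mean(self):
        cfg = SimulationConfig(
            n_patients_per_group={"G": 3},
            group_beta_mean={("G", "pre"): 0.05, ("G", "post"): 0.08},
            group_alpha_mean={("G", "pre"): 20.0, ("G", "post"): 19.0},
            beta_sd_frac=0.0,
            alpha_log_sd=0.0,
            days=1,
            seed=0,
        )
        cohort = generate_cohort(cfg)
        assert {p.params.beta for p in cohort.select("G", "pre")} == {0.05}
        assert {p.params.alpha for p in cohort.select("G", "post")} == {19.0}

    def test_ground_truth_retrievable_and_offsets_map_reported_to_true(self):
        cohort = generate_cohort(SimulationConfig(days=1, seed=6))
        p = cohort.get("RYGB03", "post")
        np.testing.assert_allclose(
            p.reported_meal_times + p.params.offsets, p.true_meal_times, atol=1e-12
        )

    def test_fixture_roundtrip(self, tmp_path):
        cfg = SimulationConfig(n_patients_per_group={"G": 2},
                               group_beta_mean={("G", "pre"): 0.05, ("G", "post"): 0.08},
                               group_alpha_mean={("G", "pre"): 20.0, ("G", "post"): 19.0},
                               days=1, seed=13)
        cohort = generate_cohort(cfg)
        paths = cohort.write_fixtures(tmp_path)
        from ppgr.io import read_cgm_csv, read_food_diary

        traces, _ = read_cgm_csv(paths["cgm"])
        assert len(traces) == 4  # 2 patients x 2 periods
        meals, _ = read_food_diary(paths["diary"])
        assert len(meals) == sum(p.meal_carbs.size for p in cohort.patients)
        assert paths["ground_truth"].read_text().startswith("seed=13")
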