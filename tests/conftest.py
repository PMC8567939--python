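import numpy as np
import pandas as pd
import pytest

from ppgr.io import AnalysisDataset
from ppgr.model import PatientParams


def make_dataset(
    rng,
    n_meals: int = 3,
    n_samples: int = 96,
    interval: float = 15.0,
    patient_id: str = "P01",
    period: str = "pre",
) -> tuple[AnalysisDataset, PatientParams]:
    """Random small dataset plus the parameters that generated it."""
    times = np.arange(n_samples) * interval
    meal_times = np.sort(rng.uniform(60, times[-1] - 60, n_meals))
    carbs = rng.uniform(10, 60, n_meals)
    params = PatientParams(
        beta=rng.uniform(0.02, 0.1),
        alpha=rng.uniform(15, 30),
        baseline=rng.uniform(4.5, 6.0),
        noise_sd=rng.uniform(0.1, 0.5),
        offsets=rng.uniform(-20, 20, n_meals),
    )
    from ppgr.model import predict_mean

    glucose = predict_mean(params, meal_times, carbs, times)
    glucose = glucose + params.noise_sd * rng.standard_normal(n_samples)
    ds = AnalysisDataset(
        patient_id=patient_id,
        period=period,
        window_start=pd.Timestamp("2021-03-01"),
        times_min=times,
        glucose=glucose,
        meal_times_min=meal_times,
        meal_carbs=carbs,
    )
    return ds, params


@pytest.fixture
def rng():
    return np.random.default_rng(20210301)


@pytest.fixture(scope="session")
def small_cohort():
    """One 3-patient group, both periods, fast to fit."""
    from ppgr.synthetic import SimulationConfig, generate_cohort

    cfg = SimulationConfig(
        n_patients_per_group={"G": 3},
        meals_per_day=4,
        group_beta_mean={("G", "pre"): 0.05, ("G", "post"): 0.086},
        group_alpha_mean={("G", "pre"): 20.0, ("G", "post"): 19.6},
        seed=11,
    )
    return generate_cohort(cfg)
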