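"""Synthetic CGM cohorts with known ground truth.

Emulates the design the analysis assumes: two surgery groups (RYGB, OAGB)
of 10 and 7 patients, each recorded pre- and post-operatively for three
days of 15-minute CGM sampling alongside a food diary.  Each patient's
glucose is a constant baseline plus additive carbohydrate-scaled Gaussian
bumps at the true meal times, with Gaussian sensor noise; the diary
reports meal times with Gaussian error.  Group-level response means
default to the published pre/post values so that simulated cohorts
reproduce the study's effect direction (higher, narrower responses after
surgery).

Not emulated: circadian baseline variation, insulin/absorption dynamics,
sensor drift, diary omission of meals.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri

from .io import AnalysisDataset, GlucoseTrace, MealRecord, write_cgm_csv, write_food_diary
from .model import PatientParams, predict_mean

__all__ = [
    "SimulationConfig",
    "SyntheticPatient",
    "SyntheticCohort",
    "generate_cohort",
    "simulate_trace",
    "jitter_meal_times",
    "make_meal_schedule",
]

GROUPS = ("RYGB", "OAGB")

# Published group-mean response parameters, pre/post operation.
DEFAULT_BETA_MEANS = {
    ("RYGB", "pre"): 0.046,
    ("RYGB", "post"): 0.086,
    ("OAGB", "pre"): 0.034,
    ("OAGB", "post"): 0.088,
}
DEFAULT_ALPHA_MEANS = {
    ("RYGB", "pre"): 22.80,
    ("RYGB", "post"): 19.60,
    ("OAGB", "pre"): 20.56,
    ("OAGB", "post"): 18.33,
}

_PERIOD_START = {"pre": pd.Timestamp("2021-03-01"), "post": pd.Timestamp("2021-05-10")}

WAKE_START = 7 * 60.0  # meals between 07:00
WAKE_END = 21 * 60.0  # and 21:00
MIN_MEAL_GAP = 90.0  # minutes


@dataclasses.dataclass
class SimulationConfig:
    """Study-shaped simulation settings.

    ``n_patients_per_group`` maps group label to arm size (default 10
    RYGB, 7 OAGB); ``group_beta_mean`` / ``group_alpha_mean`` map
    (group, period) to the population response height (mmol/l per gram)
    and length-scale (minutes).  ``report_jitter_sd`` is the diary
    timing-error standard deviation in minutes.
    """

    n_patients_per_group: Mapping[str, int] = dataclasses.field(
        default_factory=lambda: {"RYGB": 10, "OAGB": 7}
    )
    days: int = 3
    sample_interval: float = 15.0
    meals_per_day: int = 5
    carb_range: tuple[float, float] = (10.0, 60.0)
    group_beta_mean: Mapping[tuple[str, str], float] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_BETA_MEANS)
    )
    group_alpha_mean: Mapping[tuple[str, str], float] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_ALPHA_MEANS)
    )
    baseline_mean: float = 5.3
    baseline_sd: float = 0.4
    noise_sd: float = 0.3
    report_jitter_sd: float = 15.0
    beta_sd_frac: float = 0.3  # between-patient spread as fraction of mean
    alpha_log_sd: float = 0.15  # between-patient spread of log alpha
    trait_corr: float = 0.9  # within-patient correlation of traits across periods
    glucose_floor: float = 2.2  # sensor lower range, mmol/l
    seed: int = 0

    def __post_init__(self) -> None:
        if self.days < 1:
            raise ValueError("days must be >= 1")
        if self.sample_interval <= 0 or (24 * 60) % self.sample_interval != 0:
            raise ValueError("sample_interval must divide 24 h evenly")
        if self.meals_per_day < 1:
            raise ValueError("meals_per_day must be >= 1")
        lo, hi = self.carb_range
        if lo < 0 or lo > hi:
            raise ValueError("carb_range must satisfy 0 <= low <= high")
        for name in ("baseline_mean", "baseline_sd", "noise_sd", "glucose_floor"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.report_jitter_sd < 0:
            raise ValueError("report_jitter_sd must be >= 0")
        if self.beta_sd_frac < 0 or self.alpha_log_sd < 0:
            raise ValueError("between-patient spreads must be >= 0")
        if not -1.0 <= self.trait_corr <= 1.0:
            raise ValueError("trait_corr must be in [-1, 1]")
        for d in (self.group_beta_mean, self.group_alpha_mean):
            if any(v <= 0 for v in d.values()):
                raise ValueError("group means must be positive")

    @property
    def n_samples(self) -> int:
        return int(self.days * 24 * 60 / self.sample_interval)

    def grid(self) -> np.ndarray:
        return np.arange(self.n_samples) * self.sample_interval


@dataclasses.dataclass
class SyntheticPatient:
    """One patient-period with its ground truth attached."""

    patient_id: str
    group: str
    period: str
    params: PatientParams  # truth; offsets = true - reported times
    true_meal_times: np.ndarray  # minutes from window start
    reported_meal_times: np.ndarray
    meal_carbs: np.ndarray
    trace: GlucoseTrace
    meal_records: list[MealRecord]

    def dataset(self) -> AnalysisDataset:
        """Analysis view: the trace plus *reported* meal times."""
        return AnalysisDataset(
            patient_id=self.patient_id,
            period=self.period,
            window_start=self.trace.start,
            times_min=self.trace.times_min,
            glucose=self.trace.glucose,
            meal_times_min=self.reported_meal_times,
            meal_carbs=self.meal_carbs,
        )


@dataclasses.dataclass
class SyntheticCohort:
    config: SimulationConfig
    patients: list[SyntheticPatient]

    def get(self, patient_id: str, period: str) -> SyntheticPatient:
        for p in self.patients:
            if p.patient_id == patient_id and p.period == period:
                return p
        raise KeyError((patient_id, period))

    def select(self, group: str | None = None, period: str | None = None) -> list[SyntheticPatient]:
        return [
            p
            for p in self.patients
            if (group is None or p.group == group)
            and (period is None or p.period == period)
        ]

    def datasets(self, group: str, period: str) -> list[AnalysisDataset]:
        return [p.dataset() for p in self.select(group, period)]

    def write_fixtures(self, outdir: str | Path) -> dict[str, Path]:
        """Write CGM CSV + diary CSV + a key=value ground-truth sidecar."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        cgm = outdir / "cgm.csv"
        diary = outdir / "diary.csv"
        truth = outdir / "ground_truth.txt"
        write_cgm_csv([p.trace for p in self.patients], cgm)
        write_food_diary(
            [m for p in self.patients for m in p.meal_records], diary
        )
        with open(truth, "w") as fh:
            fh.write(f"seed={self.config.seed}\n")
            for p in self.patients:
                key = f"{p.patient_id}.{p.period}"
                fh.write(f"{key}.beta={p.params.beta!r}\n")
                fh.write(f"{key}.alpha={p.params.alpha!r}\n")
                fh.write(f"{key}.baseline={p.params.baseline!r}\n")
                fh.write(f"{key}.noise_sd={p.params.noise_sd!r}\n")
        return {"cgm": cgm, "diary": diary, "ground_truth": truth}


def _truncated_normal(rng: np.random.Generator, mean, sd, low=0.0):
    """Inverse-CDF draw from N(mean, sd) truncated to [low, inf)."""
    a = ndtr((low - mean) / sd)
    u = rng.uniform(a, 1.0)
    return mean + sd * ndtri(np.clip(u, 1e-15, 1 - 1e-16))


def _truncnorm_from_z(z: float, mean: float, sd: float, low: float = 0.0) -> float:
    """Map a standard-normal trait z through the N(mean, sd) truncated-at-
    ``low`` quantile function (Gaussian-copula coupling across periods)."""
    a = float(ndtr((low - mean) / sd))
    u = a + float(ndtr(z)) * (1.0 - a)
    return mean + sd * float(ndtri(np.clip(u, 1e-15, 1 - 1e-16)))


def make_meal_schedule(
    rng: np.random.Generator, days: int, meals_per_day: int
) -> np.ndarray:
    """True meal times: uniform inside waking hours with a minimum gap.

    Rejection-samples sorted uniforms on [07:00, 21:00] per day until all
    gaps exceed 90 minutes; falls back to jittered even spacing for very
    dense schedules.
    """
    out = []
    span = WAKE_END - WAKE_START
    for d in range(days):
        times = None
        for _ in range(200):
            cand = np.sort(rng.uniform(WAKE_START, WAKE_END, meals_per_day))
            if meals_per_day == 1 or np.min(np.diff(cand)) >= MIN_MEAL_GAP:
                times = cand
                break
        if times is None:
            slots = WAKE_START + span * (np.arange(meals_per_day) + 0.5) / meals_per_day
            wiggle = max((span / meals_per_day - MIN_MEAL_GAP) / 2.0, 0.0)
            times = slots + rng.uniform(-wiggle, wiggle, meals_per_day)
        out.append(times + d * 1440.0)
    return np.concatenate(out)


def jitter_meal_times(
    true_times: np.ndarray, sd: float, rng: np.random.Generator | int
) -> np.ndarray:
    """Reported meal times: truth plus Gaussian error of sd minutes.

    The drawn order is preserved even if jitter reorders meals.
    """
    if sd < 0:
        raise ValueError("jitter sd must be >= 0")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    true_times = np.asarray(true_times, dtype=float)
    return true_times + sd * rng.standard_normal(true_times.shape)


def simulate_trace(
    params: PatientParams,
    meal_times: np.ndarray,
    meal_carbs: np.ndarray,
    grid: np.ndarray,
    rng: np.random.Generator | int,
    *,
    patient_id: str = "sim",
    period: str = "pre",
    start: pd.Timestamp | None = None,
    floor: float = 0.0,
    sample_interval: float = 15.0,
) -> GlucoseTrace:
    """Simulate one CGM trace: model mean curve plus Gaussian noise.

    ``params.noise_sd == 0`` yields the exact mean curve.  ``floor``
    clips at the sensor's lower range.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("time grid is empty")
    if grid.size > 1 and np.any(np.diff(grid) <= 0):
        raise ValueError("time grid must be strictly increasing")
    if np.any(np.asarray(meal_carbs, float) < 0):
        raise ValueError("carbs must be >= 0")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    n_meals = np.asarray(meal_times, dtype=float).size
    if params.offsets.size == 0 and n_meals:
        params = dataclasses.replace(params, offsets=np.zeros(n_meals))
    mu = predict_mean(params, meal_times, meal_carbs, grid)
    y = mu + params.noise_sd * rng.standard_normal(grid.shape)
    if floor > 0:
        y = np.maximum(y, floor)
    return GlucoseTrace(
        patient_id=patient_id,
        period=period,
        start=start or _PERIOD_START.get(period, pd.Timestamp("2021-01-01")),
        times_min=grid,
        glucose=y,
        nominal_interval=sample_interval,
    )


def generate_cohort(config: SimulationConfig | None = None) -> SyntheticCohort:
    """Draw a full two-group, two-period cohort with known ground truth.

    Per patient and period: response height beta_p from a zero-truncated
    normal around the group mean (sd = ``beta_sd_frac`` x mean), length-
    scale alpha_p log-normal around the group mean, baseline normal, and
    a fresh meal schedule with uniform carbohydrate loads; the diary
    reports each meal time with Gaussian error.  A patient's response
    traits persist across the pre and post periods (Gaussian-copula
    correlation ``trait_corr``; the paired design measures the same
    physiology twice), leaving each period's marginal unchanged.
    Deterministic given ``config.seed``.
    """
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed)
    grid = config.grid()
    rho = config.trait_corr
    mix = np.sqrt(max(1.0 - rho**2, 0.0))
    patients: list[SyntheticPatient] = []
    for group in config.n_patients_per_group:
        n = int(config.n_patients_per_group[group])
        for i in range(n):
            pid = f"{group}{i + 1:02d}"
            z_beta_p, z_alpha_p = rng.standard_normal(2)  # persistent traits
            for period in ("pre", "post"):
                beta_mu = config.group_beta_mean[(group, period)]
                alpha_mu = config.group_alpha_mean[(group, period)]
                z_beta = rho * z_beta_p + mix * rng.standard_normal()
                z_alpha = rho * z_alpha_p + mix * rng.standard_normal()
                beta = (
                    _truncnorm_from_z(z_beta, beta_mu, config.beta_sd_frac * beta_mu)
                    if config.beta_sd_frac > 0
                    else beta_mu
                )
                alpha = float(alpha_mu * np.exp(config.alpha_log_sd * z_alpha))
                baseline = float(
                    _truncated_normal(
                        rng, config.baseline_mean, max(config.baseline_sd, 1e-12),
                        low=config.glucose_floor + 0.5,
                    )
                ) if config.baseline_sd > 0 else config.baseline_mean
                true_times = make_meal_schedule(rng, config.days, config.meals_per_day)
                carbs = rng.uniform(*config.carb_range, true_times.size)
                reported = jitter_meal_times(true_times, config.report_jitter_sd, rng)
                # truth offsets map reported -> true meal times
                params = PatientParams(
                    beta=beta,
                    alpha=alpha,
                    baseline=baseline,
                    noise_sd=config.noise_sd,
                    offsets=true_times - reported,
                )
                start = _PERIOD_START[period]
                trace = simulate_trace(
                    params,
                    reported,
                    carbs,
                    grid,
                    rng,
                    patient_id=pid,
                    period=period,
                    start=start,
                    floor=config.glucose_floor,
                    sample_interval=config.sample_interval,
                )
                records = [
                    MealRecord(
                        patient_id=pid,
                        period=period,
                        reported_time=start + pd.Timedelta(minutes=round(float(t))),
                        carbs=float(c),
                    )
                    for t, c in zip(reported, carbs)
                ]
                patients.append(
                    SyntheticPatient(
                        patient_id=pid,
                        group=group,
                        period=period,
                        params=params,
                        true_meal_times=true_times,
                        reported_meal_times=reported,
                        meal_carbs=carbs,
                        trace=trace,
                        meal_records=records,
                    )
                )
    return SyntheticCohort(config=config, patients=patients)
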