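"""Hierarchical Bayesian postprandial glucose-response model.

Observed glucose for patient *p* at time *t* (minutes) is modelled as a
constant between-meal baseline plus a carbohydrate-scaled bell-shaped bump
per meal, at a latent meal time that corrects the reported one:

    y_p(t) = b_p + sum_m beta_p * c_m * K(t; r_m + delta_m, alpha_p) + eps

with unit-peak Gaussian kernel K(t; tau, alpha) = exp(-(t-tau)^2 / 2 alpha^2),
homoscedastic Gaussian noise eps ~ N(0, sigma_p^2), and reporting-error
offsets delta_m ~ N(0, jitter_sd^2) truncated to +/-60 min.  beta_p (mmol/l
per gram) is the height of the response per carbohydrate gram; alpha_p
(minutes) its length-scale.  Patients within a group-period share population
parameters: beta_p ~ N+(beta_g, sd_beta^2), log alpha_p ~ N(log alpha_g,
sd_alpha^2).
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import log_ndtr

from .io import AnalysisDataset

__all__ = [
    "PatientParams",
    "GroupParams",
    "PriorConfig",
    "PosteriorResult",
    "ConvergenceError",
    "response_basis",
    "predict_mean",
    "log_likelihood",
    "log_posterior",
    "summarize_posterior",
    "variance_explained",
    "population_response_curve",
]

OFFSET_BOUND = 60.0  # minutes; support of the meal-time correction

_LOG2PI = np.log(2.0 * np.pi)


@dataclasses.dataclass
class PatientParams:
    """Per-patient parameters; ``offsets`` holds one latent delta per meal.

    The model's support is beta >= 0, alpha > 0, baseline > 0,
    noise_sd > 0 and |offset| <= 60 min; density evaluations outside it
    return -inf rather than raising, so values are not validated here.
    """

    beta: float
    alpha: float
    baseline: float
    noise_sd: float
    offsets: np.ndarray = dataclasses.field(default_factory=lambda: np.zeros(0))

    def __post_init__(self) -> None:
        self.offsets = np.asarray(self.offsets, dtype=float)

    def in_support(self) -> bool:
        return (
            self.beta >= 0
            and self.alpha > 0
            and self.baseline > 0
            and self.noise_sd > 0
            and bool(np.all(np.abs(self.offsets) <= OFFSET_BOUND))
        )


@dataclasses.dataclass
class GroupParams:
    """Population-level parameters for one group-period fit."""

    beta_g: float
    alpha_g: float
    sd_beta: float
    sd_alpha: float
    jitter_sd: float = 20.0

    def __post_init__(self) -> None:
        if min(self.beta_g, self.alpha_g, self.sd_beta, self.sd_alpha) <= 0:
            raise ValueError("group parameters must be positive")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be >= 0")


@dataclasses.dataclass
class PriorConfig:
    """Weakly-informative hyperpriors, centred on printed magnitudes.

    Locations/scales are in model units: beta in mmol/l per gram, alpha in
    minutes (log-normal), baseline and noise in mmol/l.  ``jitter_sd`` is
    the prior standard deviation of the meal-time offsets; 0 disables the
    latent-time correction (offsets pinned at their reported times).
    """

    beta_g_loc: float = 0.05
    beta_g_scale: float = 0.05
    log_alpha_g_loc: float = float(np.log(20.0))
    log_alpha_g_scale: float = 0.5
    sd_beta_scale: float = 0.03  # half-normal
    sd_alpha_scale: float = 0.5  # half-normal, on the log-alpha scale
    baseline_loc: float = 5.3
    baseline_scale: float = 1.0
    noise_scale: float = 1.0  # half-normal
    jitter_sd: float = 20.0

    def __post_init__(self) -> None:
        scales = (
            self.beta_g_scale,
            self.log_alpha_g_scale,
            self.sd_beta_scale,
            self.sd_alpha_scale,
            self.baseline_scale,
            self.noise_scale,
        )
        if min(scales) <= 0:
            raise ValueError("prior scales must be positive")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be >= 0")


def response_basis(t, tau, alpha: float):
    """Unit-peak Gaussian response kernel exp(-(t-tau)^2 / (2 alpha^2)).

    Symmetric in (t - tau) with value 1 at t == tau; alpha is the
    length-scale in minutes.  Broadcasts over ``t`` and ``tau``.
    """
    if alpha <= 0:
        raise ValueError("alpha must be > 0")
    t = np.asarray(t, dtype=float)
    tau = np.asarray(tau, dtype=float)
    z = (t - tau) / alpha
    return np.exp(-0.5 * z * z)


def basis_matrix(
    times: np.ndarray, meal_times: np.ndarray, offsets: np.ndarray, alpha: float
) -> np.ndarray:
    """(n_samples, n_meals) kernel matrix at corrected meal times."""
    tau = np.asarray(meal_times, dtype=float) + np.asarray(offsets, dtype=float)
    return response_basis(np.asarray(times, float)[:, None], tau[None, :], alpha)


def predict_mean(
    params: PatientParams,
    meal_times: np.ndarray,
    meal_carbs: np.ndarray,
    times: np.ndarray,
) -> np.ndarray:
    """Noise-free model curve: baseline + sum of carb-scaled bumps.

    Linear in each meal's carbohydrate amount.
    """
    meal_times = np.asarray(meal_times, dtype=float)
    meal_carbs = np.asarray(meal_carbs, dtype=float)
    if meal_times.size != meal_carbs.size:
        raise ValueError("meal times and carbs must have equal length")
    if params.offsets.size != meal_times.size:
        raise ValueError(
            f"{params.offsets.size} offsets for {meal_times.size} meals"
        )
    times = np.asarray(times, dtype=float)
    if meal_times.size == 0:
        return np.full(times.shape, params.baseline)
    B = basis_matrix(times, meal_times, params.offsets, params.alpha)
    return params.baseline + params.beta * (B @ meal_carbs)


def log_likelihood(params: PatientParams, dataset: AnalysisDataset) -> float:
    """Gaussian log-likelihood over non-missing CGM samples."""
    if params.noise_sd <= 0:
        raise ValueError("noise_sd must be > 0")
    mask = dataset.observed_mask
    n = int(mask.sum())
    if n == 0:
        raise ValueError("dataset has no observed samples")
    mu = predict_mean(
        params, dataset.meal_times_min, dataset.meal_carbs, dataset.times_min[mask]
    )
    r = dataset.glucose[mask] - mu
    s2 = params.noise_sd**2
    return float(-0.5 * n * (_LOG2PI + np.log(s2)) - 0.5 * np.dot(r, r) / s2)


def _halfnormal_logpdf(x: float, scale: float) -> float:
    if x < 0:
        return -np.inf
    return float(
        0.5 * np.log(2.0 / np.pi) - np.log(scale) - 0.5 * (x / scale) ** 2
    )


def _normal_logpdf(x, loc, scale):
    z = (x - loc) / scale
    return -0.5 * _LOG2PI - np.log(scale) - 0.5 * z * z


def log_prior(
    params: PatientParams,
    group: GroupParams,
    prior: PriorConfig,
) -> float:
    """Hierarchical prior for one patient plus the group hyperpriors' share
    attributable to that patient is *not* included here -- this is the
    patient-level conditional prior p(theta_p | group) only."""
    if not params.in_support():
        return -np.inf
    lp = 0.0
    # beta_p ~ Normal+(beta_g, sd_beta^2): renormalised by P(beta >= 0)
    lp += float(_normal_logpdf(params.beta, group.beta_g, group.sd_beta))
    lp -= float(log_ndtr(group.beta_g / group.sd_beta))
    # log alpha_p ~ Normal(log alpha_g, sd_alpha^2)
    lp += float(
        _normal_logpdf(np.log(params.alpha), np.log(group.alpha_g), group.sd_alpha)
    ) - float(np.log(params.alpha))
    lp += float(_normal_logpdf(params.baseline, prior.baseline_loc, prior.baseline_scale))
    lp += _halfnormal_logpdf(params.noise_sd, prior.noise_scale)
    if params.offsets.size:
        if np.any(np.abs(params.offsets) > OFFSET_BOUND):
            return -np.inf
        if group.jitter_sd == 0:
            if np.any(params.offsets != 0):
                return -np.inf
        else:
            lp += float(
                np.sum(_normal_logpdf(params.offsets, 0.0, group.jitter_sd))
            )
    return lp


def log_hyperprior(group: GroupParams, prior: PriorConfig) -> float:
    """Hyperprior density of the group-level parameters."""
    if group.beta_g < 0:
        return -np.inf
    lp = float(_normal_logpdf(group.beta_g, prior.beta_g_loc, prior.beta_g_scale))
    lp -= float(log_ndtr(prior.beta_g_loc / prior.beta_g_scale))
    lp += float(
        _normal_logpdf(np.log(group.alpha_g), prior.log_alpha_g_loc, prior.log_alpha_g_scale)
    ) - float(np.log(group.alpha_g))
    lp += _halfnormal_logpdf(group.sd_beta, prior.sd_beta_scale)
    lp += _halfnormal_logpdf(group.sd_alpha, prior.sd_alpha_scale)
    return lp


def log_posterior(
    params: PatientParams,
    group: GroupParams,
    prior: PriorConfig,
    dataset: AnalysisDataset | None,
) -> float:
    """Unnormalised log-posterior for one patient (likelihood + priors).

    Out-of-support parameter values return -inf rather than raising, so
    the value can serve directly as a Metropolis target.  ``dataset=None``
    reduces to the prior density alone.
    """
    try:
        lp = log_prior(params, group, prior) + log_hyperprior(group, prior)
    except (ValueError, FloatingPointError):
        return -np.inf
    if not np.isfinite(lp):
        return -np.inf
    if dataset is not None:
        lp += log_likelihood(params, dataset)
    return float(lp)


class ConvergenceError(RuntimeError):
    """MCMC diagnostics failed thresholds; carries the result for inspection."""

    def __init__(self, message: str, result: "PosteriorResult") -> None:
        super().__init__(message)
        self.result = result


@dataclasses.dataclass
class PosteriorResult:
    """MCMC draws plus diagnostics for one group-period fit.

    ``draws`` maps parameter names to arrays with leading axes
    (chain, draw): group scalars are (C, D); per-patient parameters are
    (C, D, P); offsets are ragged and stored per patient as
    ``offsets_<patient_id>`` with shape (C, D, M_p).
    """

    draws: Mapping[str, np.ndarray]
    patient_ids: list[str]
    group: str
    period: str
    seed: int
    sampler_settings: Mapping[str, object]
    diagnostics: pd.DataFrame
    converged: bool

    PATIENT_PARAMS = ("beta_p", "alpha_p", "baseline_p", "noise_p")
    GROUP_PARAMS = ("beta_g", "alpha_g", "sd_beta", "sd_alpha")

    def patient_draws(self, name: str, patient_id: str) -> np.ndarray:
        """Flattened (all chains pooled) draws of one patient parameter."""
        j = self.patient_ids.index(patient_id)
        return self.draws[name][:, :, j].reshape(-1)


def _quantile(x: np.ndarray, q: float) -> float:
    # equal-tailed quantiles with linear interpolation
    return float(np.quantile(x, q, method="linear"))


def summarize_posterior(result: PosteriorResult) -> pd.DataFrame:
    """Posterior mean and equal-tailed 95% interval per parameter.

    One row per group parameter and one per patient per patient-level
    parameter; columns ``parameter, patient, mean, q2.5, q97.5, rhat, ess``.
    """
    if not result.draws:
        raise ValueError("result contains no draws")
    diag = result.diagnostics.set_index(["parameter", "patient"])
    rows = []

    def _row(name: str, patient: str, x: np.ndarray) -> None:
        if x.size == 0:
            raise ValueError(f"no draws for {name}")
        key = (name, patient)
        rhat = diag.loc[key, "rhat"] if key in diag.index else np.nan
        ess = diag.loc[key, "ess"] if key in diag.index else np.nan
        rows.append(
            {
                "parameter": name,
                "patient": patient,
                "mean": float(np.mean(x)),
                "q2.5": _quantile(x, 0.025),
                "q97.5": _quantile(x, 0.975),
                "rhat": rhat,
                "ess": ess,
            }
        )

    for name in result.GROUP_PARAMS:
        if name in result.draws:
            _row(name, "", np.asarray(result.draws[name]).reshape(-1))
    for name in result.PATIENT_PARAMS:
        if name not in result.draws:
            continue
        arr = np.asarray(result.draws[name])
        for j, pid in enumerate(result.patient_ids):
            _row(name, pid, arr[:, :, j].reshape(-1))
    return pd.DataFrame(rows)


def variance_explained(observed: np.ndarray, fitted: np.ndarray) -> float:
    """Share of trace variance captured by the fitted curve, in percent.

    100 * (1 - Var(observed - fitted) / Var(observed)), clipped below at
    zero; missing samples are dropped pairwise.
    """
    observed = np.asarray(observed, dtype=float)
    fitted = np.asarray(fitted, dtype=float)
    if observed.shape != fitted.shape:
        raise ValueError("observed and fitted must have equal length")
    mask = np.isfinite(observed) & np.isfinite(fitted)
    if mask.sum() < 2:
        raise ValueError("need at least two non-missing samples")
    o = observed[mask]
    f = fitted[mask]
    vo = float(np.var(o, ddof=1))
    if vo == 0:
        raise ValueError("observed trace has zero variance")
    vr = float(np.var(o - f, ddof=1))
    return max(0.0, 100.0 * (1.0 - vr / vo))


def population_response_curve(
    result: PosteriorResult,
    carbs: float,
    grid: np.ndarray,
    levels: tuple[float, float] = (0.025, 0.975),
) -> pd.DataFrame:
    """Posterior mean and pointwise 95% band of the population response.

    The curve at time t (minutes from the meal) for a draw (beta_g,
    alpha_g) is beta_g * carbs * K(t; 0, alpha_g); quantiles are taken
    pointwise across draws.
    """
    if carbs < 0:
        raise ValueError("carbs must be >= 0")
    beta = np.asarray(result.draws["beta_g"]).reshape(-1)
    alpha = np.asarray(result.draws["alpha_g"]).reshape(-1)
    grid = np.asarray(grid, dtype=float)
    z = grid[None, :] / alpha[:, None]
    curves = beta[:, None] * carbs * np.exp(-0.5 * z * z)
    lo, hi = levels
    return pd.DataFrame(
        {
            "time_min": grid,
            "mean": curves.mean(axis=0),
            "lower": np.quantile(curves, lo, axis=0, method="linear"),
            "upper": np.quantile(curves, hi, axis=0, method="linear"),
        }
    )
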