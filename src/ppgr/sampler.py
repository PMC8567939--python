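"""Blocked MCMC for the hierarchical glucose-response model.

The posterior factorises conveniently: conditional on the response
length-scale, meal-time offsets and noise level, the model is *linear* in
(baseline_p, beta_p), so those two get exact Gibbs draws from univariate
(truncated) normal conditionals.  Everything else -- log noise, log alpha,
each meal-time offset, and the group-level parameters -- is updated by
adaptive random-walk Metropolis (scales tuned to a 44% acceptance rate
during warmup with diminishing adaptation, frozen afterwards).  log alpha_g
is conjugate-normal given the patient log alphas and is Gibbs-sampled too.

One sweep touches every parameter once; chains run independently from a
seed sequence, so runs are reproducible bit-for-bit.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import log_ndtr, logsumexp, ndtr, ndtri

from .io import AnalysisDataset
from .model import (
    OFFSET_BOUND,
    ConvergenceError,
    PosteriorResult,
    PriorConfig,
    _halfnormal_logpdf,
    _normal_logpdf,
)

__all__ = ["SamplerConfig", "fit_model", "held_out_lppd", "posterior_fitted_curve"]


@dataclasses.dataclass
class SamplerConfig:
    """MCMC settings.  Defaults: 4 chains, 1000 warmup + 1000 kept draws.

    ``rhat_max`` / ``ess_min`` gate convergence over all reported patient-
    and group-level parameters (latent offsets are nuisance and excluded);
    a failed gate raises ConvergenceError carrying the PosteriorResult
    unless ``raise_on_nonconvergence`` is off.
    """

    chains: int = 4
    warmup: int = 1000
    draws: int = 1000
    rhat_max: float = 1.05
    ess_min: float = 400.0
    raise_on_nonconvergence: bool = True
    estimate_offsets: bool = True

    def __post_init__(self) -> None:
        if self.chains < 1 or self.warmup < 1 or self.draws < 1:
            raise ValueError("chains, warmup and draws must be >= 1")


class _AdaptiveScale:
    """Robbins-Monro step-size adaptation towards a target acceptance."""

    __slots__ = ("log_scale", "target", "n")

    def __init__(self, scale: float, target: float = 0.44) -> None:
        self.log_scale = float(np.log(scale))
        self.target = target
        self.n = 0

    @property
    def scale(self) -> float:
        return float(np.exp(self.log_scale))

    def update(self, accepted: bool) -> None:
        self.n += 1
        gamma = self.n ** -0.6
        self.log_scale += gamma * ((1.0 if accepted else 0.0) - self.target)


class _PatientState:
    """Cached per-patient sampling state (basis matrix, residuals)."""

    def __init__(self, ds: AnalysisDataset, rng: np.random.Generator, prior: PriorConfig):
        mask = ds.observed_mask
        self.t = ds.times_min[mask]
        self.y = ds.glucose[mask]
        self.n = self.y.size
        self.r_meal = ds.meal_times_min.astype(float)
        self.carbs = ds.meal_carbs.astype(float)
        self.m = self.r_meal.size
        # initial values, lightly jittered per chain
        self.baseline = float(np.median(self.y)) * float(np.exp(0.02 * rng.standard_normal()))
        self.beta = max(prior.beta_g_loc * float(np.exp(0.2 * rng.standard_normal())), 1e-4)
        self.log_alpha = prior.log_alpha_g_loc + 0.1 * rng.standard_normal()
        dy = np.diff(self.y)
        s0 = float(np.std(dy) / np.sqrt(2.0)) if dy.size else 0.3
        self.log_sigma = float(np.log(max(s0, 0.05))) + 0.1 * rng.standard_normal()
        self.delta = np.zeros(self.m)
        self.B = self._basis(self.delta, np.exp(self.log_alpha))
        self.s = self.B @ self.carbs
        self.resid = self.y - self.baseline - self.beta * self.s
        # proposal scales
        self.sc_sigma = _AdaptiveScale(0.2)
        self.sc_alpha = _AdaptiveScale(0.1)
        self.sc_delta = [_AdaptiveScale(8.0) for _ in range(self.m)]

    def _basis(self, delta: np.ndarray, alpha: float) -> np.ndarray:
        z = (self.t[:, None] - (self.r_meal + delta)[None, :]) / alpha
        return np.exp(-0.5 * z * z)

    def ssr(self) -> float:
        return float(self.resid @ self.resid)


def _truncnorm_draw(rng: np.random.Generator, mean: float, sd: float, low: float) -> float:
    """One draw from Normal(mean, sd) truncated to [low, inf), by inverse CDF."""
    a = (low - mean) / sd
    u = rng.uniform(ndtr(a), 1.0)
    u = min(max(u, 1e-15), 1.0 - 1e-16)
    return mean + sd * float(ndtri(u))


def _sweep(
    states: list[_PatientState],
    hyper: dict,
    prior: PriorConfig,
    rng: np.random.Generator,
    adapt: bool,
    estimate_offsets: bool,
) -> None:
    beta_g = hyper["beta_g"]
    sd_beta = hyper["sd_beta"]
    log_alpha_g = hyper["log_alpha_g"]
    sd_alpha = hyper["sd_alpha"]
    jitter_sd = prior.jitter_sd

    for st in states:
        sigma2 = float(np.exp(2.0 * st.log_sigma))
        # --- baseline: exact Gibbs (normal prior x normal likelihood) ---
        prec = st.n / sigma2 + 1.0 / prior.baseline_scale**2
        num = float(np.sum(st.y - st.beta * st.s)) / sigma2 + prior.baseline_loc / prior.baseline_scale**2
        new_b = _truncnorm_draw(rng, num / prec, prec**-0.5, 0.0)
        st.resid += st.baseline - new_b
        st.baseline = new_b
        # --- beta: exact Gibbs, truncated-normal conditional ---
        ss = float(st.s @ st.s)
        prec = ss / sigma2 + 1.0 / sd_beta**2
        num = float(st.s @ (st.y - st.baseline)) / sigma2 + beta_g / sd_beta**2
        new_beta = _truncnorm_draw(rng, num / prec, prec**-0.5, 0.0)
        st.resid += (st.beta - new_beta) * st.s
        st.beta = new_beta
        # --- log sigma: random-walk Metropolis ---
        ssr = st.ssr()
        prop = st.log_sigma + st.sc_sigma.scale * rng.standard_normal()
        cur_lp = (
            -st.n * st.log_sigma
            - 0.5 * ssr / sigma2
            + _halfnormal_logpdf(float(np.exp(st.log_sigma)), prior.noise_scale)
            + st.log_sigma
        )
        prop_lp = (
            -st.n * prop
            - 0.5 * ssr / float(np.exp(2.0 * prop))
            + _halfnormal_logpdf(float(np.exp(prop)), prior.noise_scale)
            + prop
        )
        acc = np.log(rng.uniform()) < prop_lp - cur_lp
        if acc:
            st.log_sigma = prop
            sigma2 = float(np.exp(2.0 * prop))
        if adapt:
            st.sc_sigma.update(bool(acc))
        # --- log alpha: random-walk Metropolis (full basis refresh) ---
        prop = st.log_alpha + st.sc_alpha.scale * rng.standard_normal()
        B_new = st._basis(st.delta, float(np.exp(prop)))
        s_new = B_new @ st.carbs
        resid_new = st.y - st.baseline - st.beta * s_new
        cur_lp = -0.5 * st.ssr() / sigma2 + float(
            _normal_logpdf(st.log_alpha, log_alpha_g, sd_alpha)
        )
        prop_lp = -0.5 * float(resid_new @ resid_new) / sigma2 + float(
            _normal_logpdf(prop, log_alpha_g, sd_alpha)
        )
        acc = np.log(rng.uniform()) < prop_lp - cur_lp
        if acc:
            st.log_alpha = prop
            st.B = B_new
            st.s = s_new
            st.resid = resid_new
        if adapt:
            st.sc_alpha.update(bool(acc))
        # --- meal-time offsets: one Metropolis step each ---
        if estimate_offsets and jitter_sd > 0:
            alpha = float(np.exp(st.log_alpha))
            for j in range(st.m):
                prop = st.delta[j] + st.sc_delta[j].scale * rng.standard_normal()
                if abs(prop) > OFFSET_BOUND:
                    if adapt:
                        st.sc_delta[j].update(False)
                    continue
                z = (st.t - st.r_meal[j] - prop) / alpha
                col_new = np.exp(-0.5 * z * z)
                dresid = st.beta * st.carbs[j] * (st.B[:, j] - col_new)
                resid_new = st.resid + dresid
                dlp = (
                    -0.5 * (float(resid_new @ resid_new) - st.ssr()) / sigma2
                    - 0.5 * (prop**2 - st.delta[j] ** 2) / jitter_sd**2
                )
                acc = np.log(rng.uniform()) < dlp
                if acc:
                    st.delta[j] = prop
                    st.s += st.carbs[j] * (col_new - st.B[:, j])
                    st.B[:, j] = col_new
                    st.resid = resid_new
                if adapt:
                    st.sc_delta[j].update(bool(acc))

    # --- group level ---
    betas = np.array([st.beta for st in states])
    log_alphas = np.array([st.log_alpha for st in states])
    P = len(states)

    def beta_group_lp(bg: float, sb: float) -> float:
        if bg < 0 or sb <= 0:
            return -np.inf
        lp = float(np.sum(_normal_logpdf(betas, bg, sb))) - P * float(log_ndtr(bg / sb))
        lp += float(_normal_logpdf(bg, prior.beta_g_loc, prior.beta_g_scale))
        lp += _halfnormal_logpdf(sb, prior.sd_beta_scale)
        return lp

    # beta_g: random-walk Metropolis
    prop = beta_g + hyper["sc_beta_g"].scale * rng.standard_normal()
    acc = np.log(rng.uniform()) < beta_group_lp(prop, sd_beta) - beta_group_lp(beta_g, sd_beta)
    if acc:
        beta_g = prop
    if adapt:
        hyper["sc_beta_g"].update(bool(acc))
    # log sd_beta: random-walk Metropolis (log-scale Jacobian)
    prop = float(np.log(sd_beta)) + hyper["sc_sd_beta"].scale * rng.standard_normal()
    cur = beta_group_lp(beta_g, sd_beta) + float(np.log(sd_beta))
    new = beta_group_lp(beta_g, float(np.exp(prop))) + prop
    acc = np.log(rng.uniform()) < new - cur
    if acc:
        sd_beta = float(np.exp(prop))
    if adapt:
        hyper["sc_sd_beta"].update(bool(acc))
    # log alpha_g: conjugate Gibbs
    prec = P / sd_alpha**2 + 1.0 / prior.log_alpha_g_scale**2
    num = float(np.sum(log_alphas)) / sd_alpha**2 + prior.log_alpha_g_loc / prior.log_alpha_g_scale**2
    log_alpha_g = num / prec + prec**-0.5 * rng.standard_normal()
    # log sd_alpha: random-walk Metropolis
    prop = float(np.log(sd_alpha)) + hyper["sc_sd_alpha"].scale * rng.standard_normal()

    def sd_alpha_lp(sa: float) -> float:
        if sa <= 0:
            return -np.inf
        return float(np.sum(_normal_logpdf(log_alphas, log_alpha_g, sa))) + _halfnormal_logpdf(
            sa, prior.sd_alpha_scale
        )

    cur = sd_alpha_lp(sd_alpha) + float(np.log(sd_alpha))
    new = sd_alpha_lp(float(np.exp(prop))) + prop
    acc = np.log(rng.uniform()) < new - cur
    if acc:
        sd_alpha = float(np.exp(prop))
    if adapt:
        hyper["sc_sd_alpha"].update(bool(acc))

    hyper.update(beta_g=beta_g, sd_beta=sd_beta, log_alpha_g=log_alpha_g, sd_alpha=sd_alpha)


def _diagnostics(draws: dict, patient_ids: list[str]) -> pd.DataFrame:
    import arviz as az

    rows = []

    def _one(name: str, patient: str, x: np.ndarray) -> None:
        ds = az.convert_to_dataset(x)  # (chain, draw)
        rhat = (
            float(np.asarray(az.rhat(ds).to_array()).reshape(-1)[0])
            if x.shape[0] > 1
            else np.nan
        )
        ess = float(np.asarray(az.ess(ds).to_array()).reshape(-1)[0])
        rows.append({"parameter": name, "patient": patient, "rhat": rhat, "ess": ess})

    for name in PosteriorResult.GROUP_PARAMS:
        _one(name, "", draws[name])
    for name in PosteriorResult.PATIENT_PARAMS:
        for j, pid in enumerate(patient_ids):
            _one(name, pid, draws[name][:, :, j])
    return pd.DataFrame(rows)


def fit_model(
    datasets: Sequence[AnalysisDataset],
    prior: PriorConfig | None = None,
    config: SamplerConfig | None = None,
    seed: int = 0,
) -> PosteriorResult:
    """Fit one group-period hierarchical model by blocked MCMC.

    ``datasets`` holds one AnalysisDataset per patient (all from the same
    group and period); each must contain at least one meal.  Returns a
    PosteriorResult with draws for every patient- and group-level
    parameter plus the latent offsets, and split-R-hat / bulk-ESS
    diagnostics for the reported parameters.
    """
    prior = prior or PriorConfig()
    config = config or SamplerConfig()
    if not datasets:
        raise ValueError("need at least one patient dataset")
    for ds in datasets:
        if ds.meal_times_min.size == 0:
            raise ValueError(f"patient {ds.patient_id} has no meals")
        if not ds.observed_mask.any():
            raise ValueError(f"patient {ds.patient_id} has no observed samples")
    patient_ids = [ds.patient_id for ds in datasets]
    P = len(datasets)
    C, W, D = config.chains, config.warmup, config.draws

    draws: dict[str, np.ndarray] = {
        "beta_g": np.empty((C, D)),
        "alpha_g": np.empty((C, D)),
        "sd_beta": np.empty((C, D)),
        "sd_alpha": np.empty((C, D)),
        "beta_p": np.empty((C, D, P)),
        "alpha_p": np.empty((C, D, P)),
        "baseline_p": np.empty((C, D, P)),
        "noise_p": np.empty((C, D, P)),
    }
    for ds in datasets:
        draws[f"offsets_{ds.patient_id}"] = np.empty((C, D, ds.meal_times_min.size))

    for chain in range(C):
        rng = np.random.default_rng(np.random.SeedSequence((seed, chain)))
        states = [_PatientState(ds, rng, prior) for ds in datasets]
        hyper = {
            "beta_g": prior.beta_g_loc * float(np.exp(0.1 * rng.standard_normal())),
            "sd_beta": prior.sd_beta_scale * 0.8,
            "log_alpha_g": prior.log_alpha_g_loc + 0.05 * rng.standard_normal(),
            "sd_alpha": 0.3,
            "sc_beta_g": _AdaptiveScale(0.01),
            "sc_sd_beta": _AdaptiveScale(0.3),
            "sc_sd_alpha": _AdaptiveScale(0.3),
        }
        for i in range(W):
            _sweep(states, hyper, prior, rng, True, config.estimate_offsets)
        for i in range(D):
            _sweep(states, hyper, prior, rng, False, config.estimate_offsets)
            draws["beta_g"][chain, i] = hyper["beta_g"]
            draws["alpha_g"][chain, i] = np.exp(hyper["log_alpha_g"])
            draws["sd_beta"][chain, i] = hyper["sd_beta"]
            draws["sd_alpha"][chain, i] = hyper["sd_alpha"]
            for j, st in enumerate(states):
                draws["beta_p"][chain, i, j] = st.beta
                draws["alpha_p"][chain, i, j] = np.exp(st.log_alpha)
                draws["baseline_p"][chain, i, j] = st.baseline
                draws["noise_p"][chain, i, j] = np.exp(st.log_sigma)
                draws[f"offsets_{patient_ids[j]}"][chain, i] = st.delta

    diag = _diagnostics(draws, patient_ids)
    bad = diag[
        (diag["rhat"].fillna(0) > config.rhat_max) | (diag["ess"] < config.ess_min)
    ]
    converged = bad.empty
    result = PosteriorResult(
        draws=draws,
        patient_ids=patient_ids,
        group=getattr(datasets[0], "group", ""),
        period=datasets[0].period,
        seed=seed,
        sampler_settings=dataclasses.asdict(config),
        diagnostics=diag,
        converged=converged,
    )
    if not converged and config.raise_on_nonconvergence:
        worst = bad.iloc[0]
        raise ConvergenceError(
            f"MCMC did not converge: e.g. {worst['parameter']} "
            f"(patient '{worst['patient']}') rhat={worst['rhat']:.3f} "
            f"ess={worst['ess']:.0f}",
            result,
        )
    return result


def held_out_lppd(
    result: PosteriorResult,
    datasets: Sequence[AnalysisDataset],
    max_draws: int = 400,
) -> float:
    """Log pointwise predictive density on held-out CGM samples.

    ``datasets`` carry the held-out samples (NaN elsewhere) and the *same*
    meals, in the same order, as the datasets the model was fitted on, so
    the posterior offsets apply.  For each held-out point the predictive
    density is averaged over posterior draws (log-mean-exp), then summed.
    """
    total = 0.0
    C, D = result.draws["beta_g"].shape
    flat = C * D
    step = max(1, flat // max_draws)
    idx = np.arange(0, flat, step)
    for ds in datasets:
        j = result.patient_ids.index(ds.patient_id)
        mask = ds.observed_mask
        t = ds.times_min[mask]
        y = ds.glucose[mask]
        beta = result.draws["beta_p"][:, :, j].reshape(-1)[idx]
        alpha = result.draws["alpha_p"][:, :, j].reshape(-1)[idx]
        base = result.draws["baseline_p"][:, :, j].reshape(-1)[idx]
        sig = result.draws["noise_p"][:, :, j].reshape(-1)[idx]
        offs = result.draws[f"offsets_{ds.patient_id}"].reshape(flat, -1)[idx]
        K = len(idx)
        # (K, n) predictive means
        tau = ds.meal_times_min[None, :] + offs  # (K, m)
        z = (t[None, :, None] - tau[:, None, :]) / alpha[:, None, None]
        mu = base[:, None] + beta[:, None] * np.einsum(
            "knm,m->kn", np.exp(-0.5 * z * z), ds.meal_carbs
        )
        lp = _normal_logpdf(y[None, :], mu, sig[:, None])
        total += float(np.sum(logsumexp(lp, axis=0) - np.log(K)))
    return total


def _curve_draws(
    result: PosteriorResult, ds: AnalysisDataset, grid: np.ndarray, max_draws: int
) -> np.ndarray:
    """(K, n_grid) posterior draws of one patient's model mean curve."""
    j = result.patient_ids.index(ds.patient_id)
    C, D = result.draws["beta_g"].shape
    flat = C * D
    idx = np.arange(0, flat, max(1, flat // max_draws))
    beta = result.draws["beta_p"][:, :, j].reshape(-1)[idx]
    alpha = result.draws["alpha_p"][:, :, j].reshape(-1)[idx]
    base = result.draws["baseline_p"][:, :, j].reshape(-1)[idx]
    offs = result.draws[f"offsets_{ds.patient_id}"].reshape(flat, -1)[idx]
    tau = ds.meal_times_min[None, :] + offs
    z = (np.asarray(grid, float)[None, :, None] - tau[:, None, :]) / alpha[:, None, None]
    return base[:, None] + beta[:, None] * np.einsum(
        "knm,m->kn", np.exp(-0.5 * z * z), ds.meal_carbs
    )


def posterior_fitted_curve(
    result: PosteriorResult,
    ds: AnalysisDataset,
    grid: np.ndarray | None = None,
    max_draws: int = 200,
) -> pd.DataFrame:
    """Posterior mean and pointwise 95% band of one patient's fitted curve.

    Columns ``time_min, mean, lower, upper``; defaults to the dataset's
    own time grid.
    """
    grid = ds.times_min if grid is None else np.asarray(grid, float)
    curves = _curve_draws(result, ds, grid, max_draws)
    return pd.DataFrame(
        {
            "time_min": grid,
            "mean": curves.mean(axis=0),
            "lower": np.quantile(curves, 0.025, axis=0, method="linear"),
            "upper": np.quantile(curves, 0.975, axis=0, method="linear"),
        }
    )
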