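# Methods

## The model

`ppgr` estimates how strongly a person's interstitial glucose responds to
the carbohydrate content of their meals, from continuous-glucose-monitor
(CGM) traces sampled every 15 minutes and self-reported food diaries.
Observed glucose for patient *p* at time *t* (minutes from the start of
the diary window) is modelled as

    y_p(t) = b_p + Σ_m β_p · c_m · K(t; r_m + δ_m, α_p) + ε_p(t)

where

* `b_p` (mmol/l) is a constant between-meal baseline. A constant — rather
  than slowly varying — baseline is deliberate: a flexible baseline would
  absorb part of the meal effect and make β unidentifiable at this data
  density.
* `β_p` (mmol/l per gram) is the response height per carbohydrate gram,
  the quantity of primary interest; `c_m` is meal *m*'s carbohydrate mass.
* `K(t; τ, α) = exp(−(t−τ)²/(2α²))` is a unit-peak Gaussian bump; `α_p`
  (minutes) is the response length-scale (duration of the excursion).
  The basis lives in a single function (`response_basis`), so an
  alternative kernel shape is a one-line substitution.
* `r_m` is the *reported* meal time and `δ_m` a latent correction for
  diary timing error, `δ_m ~ N(0, jitter_sd²)` truncated to ±60 min
  (errors-in-variables). Self-reported timings are unreliable; ignoring
  that biases β downward because misplaced bumps cannot line up with the
  observed excursions.
* `ε_p(t) ~ N(0, σ_p²)` is homoscedastic sensor noise. Missing CGM
  samples are dropped from the likelihood, never imputed.

Patients within one surgery-group × period are tied hierarchically:

    β_p ~ Normal⁺(β_g, sd_β²)        (truncated at zero)
    log α_p ~ Normal(log α_g, sd_α²)

with weakly informative hyperpriors centred on published magnitudes:
β_g ~ Normal⁺(0.05, 0.05²) mmol/l/g, α_g ~ LogNormal(log 20, 0.5²) min,
b_p ~ N(5.3, 1²) mmol/l, σ_p ~ half-Normal(1), sd_β ~ half-Normal(0.03),
sd_α ~ half-Normal(0.5). One hierarchical fit is run per group × period,
matching how group means and per-patient responses are reported.
`jitter_sd` defaults to 20 min and is fixed, not sampled — letting the
offset scale float is weakly identified with only ~12 meals per trace.

## Inference

The posterior is explored with a blocked Metropolis-within-Gibbs sampler
built for this model's structure:

* Conditional on (α_p, δ, σ_p), the model is linear in (b_p, β_p), so both
  get **exact Gibbs draws** from univariate (truncated-)normal
  conditionals. This removes the two strongest posterior correlations from
  the random-walk part.
* `log σ_p`, `log α_p`, each offset `δ_m`, and the group parameters
  (β_g, log sd_β, log sd_α) use adaptive random-walk Metropolis; proposal
  scales adapt toward a 0.44 acceptance rate with diminishing
  (Robbins–Monro) steps during warmup and are frozen afterwards, so the
  kept draws target the exact posterior. `log α_g` is conjugate-normal
  given the patient log-α's and is Gibbs-sampled.
* Offset updates recompute only the affected column of the kernel matrix;
  the per-sweep cost is O(patients × samples × meals).

Defaults: 4 chains, 1000 warmup + 1000 kept sweeps, seeded per chain from
a `(seed, chain)` sequence — runs are bitwise reproducible. Convergence is
gated on split-R̂ ≤ 1.05 and bulk ESS ≥ 400 for every patient- and
group-level parameter (offsets are nuisance variables and are monitored
but not gated); a failed gate raises a typed error carrying the full
result for inspection. Interval summaries are equal-tailed 2.5%/97.5%
quantiles with linear interpolation, pooled across chains. Whether such
intervals are credible or confidence intervals is moot here: they are
posterior credible intervals.

## Synthetic cohorts

No patient-level data ship with the package, so the generator produces
cohorts with the statistical structure the analysis assumes and known
ground truth: two groups (10 RYGB, 7 OAGB patients), each with a pre- and
a post-operative period of 3 days × 96 daily samples, group-mean
(β, α) defaulting to the published pre/post values
(RYGB 0.046→0.086 mmol/l/g, 22.80→19.60 min; OAGB 0.034→0.088,
20.56→18.33).

Choices where the design was open:

* **Meal schedule** — meals uniform in waking hours (07:00–21:00) with a
  minimum 90-minute gap; 5 meals/day by default (between typical pre-op
  diary density and the 6–8 small meals recommended post-op), 10–60 g
  carbohydrate per meal, uniform.
* **Heterogeneity** — β_p truncated-normal around the group mean with
  sd = 30% of the mean; α_p log-normal (sd 0.15 on the log scale);
  baselines N(5.3, 0.4²) mmol/l.
* **Within-patient persistence** — a patient's response traits are
  correlated across the two periods through a Gaussian copula
  (`trait_corr`, default 0.9) that leaves each period's marginal
  unchanged. The design is paired: the same physiology is measured twice,
  and independent draws would imply frequent spontaneous sign reversals
  of the pre→post change that a paired study of this kind does not show.
* **Observation model** — sensor noise sd 0.3 mmol/l; diary timing error
  sd 15 min; simulated glucose clipped at the 2.2 mmol/l sensor floor
  (inactive under default baselines).

Not emulated: circadian or slow baseline drift, insulin/absorption
physiology, nutrient effects beyond carbohydrate, meal omission or
systematic (non-zero-mean) reporting bias, sensor dropout and drift.
Passing recovery tests therefore demonstrates that the *inference
machinery* is correct and calibrated under the model's own assumptions —
not that the model is an adequate description of real CGM data.

## Glycemic metrics and comparisons

Time-in-band uses half-open bands [a, b) over the thresholds 4, 5, 6,
7 mmol/l — a sample at exactly 4.0 is in-range — with percentages over
non-missing samples only ("wear time"). CV is 100·sd/mean with the n−1
standard deviation; min/max come from raw observations, never fitted
curves. Aggregated histograms pool samples across individuals (bin width
0.25 mmol/l) and normalise to unit area. Variance explained is
100·(1 − Var(resid)/Var(obs)), clipped below at zero.

The comparison battery: paired t within group, Welch t (group sizes
differ) or Mann–Whitney U between groups, and Welch t on per-patient
(post − pre) deltas for the degree of change; all two-sided, raw
p-values, no multiplicity correction. Zero-variance degenerate inputs are
flagged rather than silently returning p = 0 or 1.

## Problem sizes in the shipped checks

The test suite and `scripts/acceptance.py` run reduced-scale studies
chosen as the smallest sizes at which the statistical claims are stable:
recovery and calibration use 10-patient single-group cohorts with 1–2
chains of 300–500 warmup/kept sweeps; the held-out comparison uses 20
single-patient replicates at 2 recording days; the directionality check
fits the full default cohort across 10 seeds at 300+300 sweeps. The
acceptance script fits all four group-periods of the default cohort at
2 chains × 500+500.

## Known limitations

* β and α are partially confounded at 15-minute sampling when meals
  cluster; the hierarchical prior resolves this at the cost of some
  shrinkage toward the group mean for patients with noisy traces.
* `jitter_sd` is fixed, so badly mis-specified timing-error scales will
  mis-calibrate the offsets' posterior.
* With a single patient the group-level parameters are prior-dominated;
  fits remain valid but β_g intervals are wide.
* The Gaussian noise model ignores CGM error heteroscedasticity (sensor
  error grows at the extremes of the measurement range).
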