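# ppgr — postprandial glucose responses from CGM traces and food diaries

`ppgr` is a research package for estimating **personal glucose responses
to dietary carbohydrate** from continuous glucose monitoring (CGM) and
self-reported food diaries — the kind of data produced when study
participants wear a flash glucose sensor (one interstitial glucose sample
every 15 minutes) while keeping a 3-day diet record. It was built to
analyse paired pre-/post-operative cohorts of bariatric-surgery patients
(Roux-en-Y vs. one-anastomosis gastric bypass), but the model applies to
any meal-annotated CGM recording.

The core is a hierarchical Bayesian errors-in-variables model. Glucose
for patient *p* is a constant baseline plus one carbohydrate-scaled bump
per meal,

    y_p(t) = b_p + Σ_m β_p c_m exp(−(t − r_m − δ_m)² / 2α_p²) + ε,

where β_p (mmol/l per gram) is how much the response peak grows per gram
of carbohydrate, α_p (min) the response length-scale, and δ_m a latent
correction for the error in the reported meal time r_m — self-reported
timings are unreliable, and ignoring that biases β downward. Patient
parameters are drawn from group-level distributions (β_p ~ N⁺(β_g, sd_β²),
log α_p ~ N(log α_g, sd_α²)) and everything is estimated jointly by MCMC
(blocked Gibbs/Metropolis; exact Gibbs for the conditionally linear
baseline and β). The package also computes the standard glycemic-profile
metrics (time in range, min/mean/max, CV, pooled glucose histograms, R²
of the fit) and the pre/post and between-group comparison battery (paired
t, Welch t, Mann–Whitney U, chi-squared).

Because patient-level study data cannot be redistributed, the package
ships a synthetic-cohort generator with the same design (10 + 7 patients,
two periods, three diary days, 15-minute sampling, published group-mean
response parameters as ground truth), used by the test suite for
parameter-recovery and calibration checks. See `docs/methods.md` for the
full model, priors, sampler and generator details.

## Worked example

Simulate a small post-operative group and re-estimate its responses:

```python
from ppgr import (SimulationConfig, generate_cohort, PriorConfig,
                  SamplerConfig, fit_model, summarize_posterior)

cfg = SimulationConfig(
    n_patients_per_group={"RYGB": 4},
    group_beta_mean={("RYGB", "pre"): 0.046, ("RYGB", "post"): 0.086},
    group_alpha_mean={("RYGB", "pre"): 22.8, ("RYGB", "post"): 19.6},
    seed=42,
)
cohort = generate_cohort(cfg)
result = fit_model(
    cohort.datasets("RYGB", "post"),
    PriorConfig(jitter_sd=20.0),
    SamplerConfig(chains=2, warmup=500, draws=500,
                  raise_on_nonconvergence=False),
    seed=0,
)
summary = summarize_posterior(result)
print(summary[summary.parameter.isin(["beta_g", "alpha_g", "beta_p"])]
      .round(4).to_string(index=False))
```

prints

```
parameter patient    mean    q2.5   q97.5   rhat      ess
   beta_g          0.0786  0.0349  0.1087 1.0143 127.5739
  alpha_g         19.4664 17.0297 22.3283 1.0077 522.0954
   beta_p  RYGB01  0.0868  0.0828  0.0903 1.0019 269.0977
   beta_p  RYGB02  0.0799  0.0760  0.0839 1.0085 325.9291
   beta_p  RYGB03  0.1052  0.1021  0.1083 1.0045 492.9985
   beta_p  RYGB04  0.0502  0.0472  0.0535 1.0047 284.3007
```

Each `beta_p` row is one patient's response height with its 95% credible
interval — the generating values for this seed were 0.0853, 0.0766,
0.1061 and 0.0515 mmol/l/g, each inside its interval — and `beta_g` /
`alpha_g` are the population mean height and length-scale (mmol/l/g and
minutes). `rhat`/`ess` are split-R̂ and bulk effective sample size for
each reported parameter.

The same analysis runs end-to-end from a config file:

```bash
ppgr run --config config.yaml        # simulate → fit → metrics → compare
ppgr simulate --outdir data          # fixtures + ground-truth sidecar
ppgr metrics --cgm data/cgm.csv      # Table-style glycemic summaries
```

producing posterior-summary, fitted-curve, population-response-curve,
glycemic-summary, histogram and comparison-table CSVs plus a manifest
recording the seed and every file written.

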