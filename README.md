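# dazzletrack

Simulation and inference pipeline for a classic question in behavioural
ecology and visual psychophysics: how do the **confusion effect** (targets
in larger groups are harder to track), the **oddity effect** (an individual
whose instantaneous speed differs from its groupmates is easier to single
out) and **motion-dazzle coloration** (high-contrast stripes hypothesized
to corrupt perceived speed and heading) interact when an observer tracks
one square in a milling swarm?

The package is for researchers who want a fully synthetic, seed-reproducible
version of the tracking paradigm: because no raw human tracking data exist
for this task, a mechanistic *synthetic observer* stands in for
participants, with injectable confusion/oddity/coloration effect sizes, so
every stage of the analysis can be validated against known ground truth.

## What it contains

- `swarm_sim` — the stimulus: 1–50 squares (32 × 32 px) on correlated
  random walks inside a 268 × 268 px region for 5000 ms trials. Speeds are
  either fixed at 200 px/s or follow a clamped random walk on
  [100, 300] px/s with per-frame N(0, 40²) increments; target and cursor
  centres are recorded every 10 ms.
- `pattern_render` — trinary-noise and 100%-contrast square-wave grating
  textures (wavelength 8 px, oriented orthogonal or parallel to motion),
  plus frame rasterization.
- `observer_synth` — the synthetic observer (lagged proportional pursuit +
  motor jitter + density/oddity/coloration-dependent identity swaps) and a
  direct sampler from the analysis model for estimator tests.
- `tracking_metrics` — mean cursor–target distance over the final 4000 ms,
  natural-log transformed.
- `mixed_model` — Gaussian linear mixed models on log error with a subject
  random intercept, fitted by profiled maximum likelihood:

  log *e*ᵢⱼ = **x**ᵢⱼ′**β** + *u*ᵢ + εᵢⱼ,  *u*ᵢ ~ N(0, σᵤ²),  εᵢⱼ ~ N(0, σₑ²),

  with group size coded as orthogonal polynomials over {1, 10, 30, 50} and
  treatment-coded coloration/speed factors. Nested models are compared by
  deviance: χ² = 2(ℓ_full − ℓ_reduced) on the parameter-count difference.
  Per-subject polynomial contrasts (paired *t*, df = S − 1) and post hoc
  speed × coloration ratios with Wald CIs complete the ladder.
- `experiment` / `cli` — schedules (6 blocks = coloration × speed, 56
  trials each, 336 per subject plus 6 flagged practice trials), the
  end-to-end driver, condition summaries with within-subject CIs, and a
  thin command line (`dazzletrack simulate|render|synth|analyze|run-all`).

## Worked example

`examples/04_mixed_model.py` draws 15 subjects × 336 trials from the
analysis model with known coefficients and refits them:

```
coefficients (estimate vs truth):
  Intercept                    3.524 +/- 0.047   (truth  3.500)
  coloration[orthogonal]       0.031 +/- 0.009   (truth  0.020)
  coloration[parallel]         0.103 +/- 0.009   (truth  0.100)
  speed[variable]             -0.127 +/- 0.007   (truth -0.120)
  n^1                          0.906 +/- 0.007   (truth  0.900)
  n^2                         -0.252 +/- 0.007   (truth -0.250)
sigma_u^2 = 0.0329 (truth 0.09), sigma_e^2 = 0.0626 (truth 0.0625)
dropping the speed main effect: chi2(1) = 315.2, p = 1.6e-70
```

Every fixed effect lands within ~1 SE of its generating value; the
deviance test recovers the injected speed effect. (A single draw of 15
subject intercepts estimates σᵤ² noisily — its sampling SD is ≈ 37% at
S = 15 — which is why recovery checks summarize over many replicates.)

`examples/03_synthetic_observer.py` shows the confusion effect the
mechanistic observer produces by construction:

```
n =  1: mean error   20.5 px (log error 3.02)
n = 10: mean error   79.9 px (log error 4.18)
n = 30: mean error  107.2 px (log error 4.58)
n = 50: mean error  114.0 px (log error 4.69)
```

Tracking error rises steeply and then decelerates with group size.

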