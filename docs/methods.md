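# Methods

## The stimulus model

Each trial shows `n ∈ {1, 10, 30, 50}` squares (side 32 px) inside a
central containment region of 268 × 268 px for 5000 ms. Squares move
independently — a milling swarm, not a polarized shoal.

**Headings** follow a correlated random walk: per frame the heading gains
a wrapped-normal increment with SD `turn_sd` (default 0.35 rad at 100 Hz).
The turning distribution of the original paradigm is not restated in the
source protocol; the wrapped-normal dialect is the standard CRW
parameterization, and 0.35 rad/frame was chosen once so that paths
visibly mill inside the small arena. It is configurable.

**Speeds** are either fixed at exactly 200 px/s (constant condition) or a
clamped random walk (variable condition): the initial speed is
200 + N(0, 40²) and every frame adds another independent N(0, 40²) draw,
hard-clamped into [100, 300] px/s. Clamping is censoring (values pile up
at the bounds), not truncation or reflection — the simplest total rule;
with symmetric bounds it preserves the 200 px/s mean. Two consequences
worth knowing:

- the realized SD of a single clamped increment is 39.55 px/s, not 40
  (analytic censored-normal moment at ±2.5σ), with 1.24% of draws clamped;
- lag-1 autocorrelation of the speed series is strongly positive (≈ 0.76
  on clamp-free stretches) but cannot approach 1: inside a 200 px/s band a
  walk with 40 px/s steps is variance-limited (r > 0.9 would require a
  series SD > 89 px/s). The tests therefore check strong positive
  autocorrelation against an i.i.d.-shuffle control rather than a value
  near 1.

**Kinematics** are explicit Euler at the frame rate (default 100 Hz, so
one frame per 10 ms recording sample): displacement = speed · dt along the
heading. At the containment edge the heading reflects specularly and the
overshoot folds back; per-frame displacements (≤ 3 px) are much smaller
than the region, so one fold per axis suffices. The containment bound
applies to square *centres* (rendered squares may overhang by up to
16 px); both the bound semantics and the frame rate are configurable.

Recorded states are the post-step states at t = 10, 20, …, 5000 ms — 500
frames — with the t = 0 initial state kept separately. This makes the
analysis window (1000, 5000] hold exactly 400 samples.

Initial placement is uniform in the containment region with overlap
permitted (50 squares of 32 px cannot avoid overlap in a 268 px box);
headings are uniform on [0, 2π); the target index is uniform per trial.

## Colorations

The background and the trinary target texture are i.i.d. equiprobable
three-level {0, ½, 1} noise in element-sized blocks (default 2 px;
behaviour under test does not depend on the element size). Striped targets
are 100%-contrast square-wave gratings of wavelength 8 px evaluated
analytically on a coordinate rotated to the square's instantaneous
heading: *orthogonal* stripes have contours perpendicular to the motion,
*parallel* stripes run along it. Because the wave is evaluated, not
resampled, re-orientation is exact. Orientation is recomputed every frame
from the instantaneous heading; whether the original stimuli rotated
continuously is unknown, and this is the simplest consistent reading.
Stimuli are achromatic; no display calibration is modelled.

## The synthetic observer

No human data exist for this pipeline, so the observer is an explicitly
synthetic stand-in with two layers.

The *mechanistic* observer tracks like a simple pursuit controller: each
frame the cursor moves a fraction `pursuit_gain` (0.35) toward the
`lag_ms`-lagged (100 ms) position of the item it currently believes is the
target, plus isotropic motor jitter (SD 3 px per axis). Confusion arises
through identity swaps: each frame, with probability

    logistic(swap_base + swap_density_gain · density
             + coloration_gain[c] − oddity_gain · |z_speed(target)|)

the tracked identity switches to the item nearest the cursor other than
the currently tracked one (so the true target can be re-acquired).
`density` counts items within 64 px of the tracked item; `z_speed`
standardizes the target's speed within the group (0 when the group SD is
0, hence no oddity signal in constant-speed trials). Defaults:
swap_base −6, density gain 0.35, oddity gain 1.0, coloration offsets
{orthogonal 0, parallel 0.7, trinary 0}, subject-intercept SD 0.15
(log scale). These defaults were calibrated once so the condition-mean
pattern matches the qualitative empirical findings — error rising and
decelerating with group size, lower error under variable speed (strongest
at intermediate sizes), a steeper group-size slope for parallel stripes —
and are properties of this synthetic observer only, never estimates of
human parameters.

The *direct* sampler draws log errors straight from the analysis model
(X**β** + subject intercept + residual). It exists so estimator tests have
exact ground truth; the mechanistic observer exercises the full pipeline
end to end. Passing tests show internal consistency of the pipeline under
these generative assumptions — they cannot show that human observers
behave this way.

## Response variable

Tracking error is the arithmetic mean of per-sample Euclidean distances
between cursor and target centres over (1000, 5000] ms — 400 samples at
10 ms. Which edge samples the original "final 4000 ms" included is
undefined at the source; the half-open right-inclusive convention is a
documented choice worth ±1 sample in 400. Errors are natural-log
transformed; a mathematically perfect error of exactly 0 raises an
explicit error rather than being epsilon-padded (an observer with any
motor noise never produces it).

## Inference

All models are Gaussian linear mixed models on log error with a subject
random intercept, fitted by **maximum likelihood** (not REML, because the
deviance ladder compares models differing in fixed effects). Group size
enters as orthonormal polynomial codes over the distinct sizes present;
coloration and speed are treatment-coded (references: trinary, constant).
Term sets must respect marginality; rank deficiency is an error.

The fit profiles the likelihood over λ = σᵤ²/σₑ²: given λ, GLS reduces to
OLS on partially group-mean-centred data (y − θ_g ȳ_g with
θ_g = 1 − (1 + λ n_g)^(−1/2)), leaving a 1-D bounded optimization on
log λ (tolerance 1e-10; the λ = 0 boundary is always evaluated too, so
the fit reproduces OLS exactly when the subject variance vanishes).
A fit takes a few milliseconds at 5040 × 18, which the 1000-replicate
calibration and 500-replicate recovery suites depend on. Wald SEs come
from σ̂²(X̃′X̃)⁻¹; χ² statistics are clipped at 0; non-convergence is
reported, never swallowed. The implementation is cross-checked in tests
against statsmodels MixedLM(reml=False) and a brute-force optimizer of
the explicit joint Gaussian likelihood (agreement ≤ 1e-6).

The model-comparison ladder: quadratic vs linear group-size coding within
the all-interactions model (df 6); then, with number quadratic, the
three-way interaction (df 4) and each two-way interaction dropped from
the two-way model (df 2, 4, 2). Per-subject contrasts fit each subject's
log error against the polynomial codes within each condition (pooling the
other factor) and compare a named coefficient across a condition pair by
paired t test, df = subjects − 1 (15 subjects → df 14); the source
analysis never states its contrast machinery, and this per-subject
reading reproduces its test shape. The post hoc oddity ratio refits the
speed × coloration model on the 30-item subset only and exponentiates the
interaction coefficient with a Wald 95% CI on the log scale. No
multiple-testing correction is applied anywhere, matching the analysis
this mirrors.

## Experiment driver

Each subject receives 6 blocks (coloration × speed), each with 14
replicates of each group size in per-subject shuffled order, preceded by
6 practice trials (group size 10, trinary, constant — composition
unstated at the source, configurable) that are flagged and excluded from
analysis. Only the 336-trial total is printed in the source design; the
4 × 14 split per block is the inferred balanced allocation and is
configurable. Trials are simulated in batches grouped by condition for
speed; presentation order is recorded but does not influence the
synthetic data (no practice, fatigue or carryover effects are modelled).
All per-trial generators derive deterministically from
(master_seed, subject, trial position), so any trial can be regenerated
in isolation and batched and single runs are bit-identical.

Condition summaries use subject-mean-centred (Cousineau) within-subject
95% CIs with the Morey cell-count correction √(C/(C−1)), C = 24 cells.

## Problem sizes and numerical choices

Simulation batches are capped at 128 trials (memory locality); the frame
loops pre-draw each trial's noise from its own generator, then advance
all trials vectorized — results are identical to one-at-a-time
simulation. Calibration suites use 1000 replicates of a reduced 8 × 24
design for deviance-test type-I error, 100 replicates at the full
15 × 336 size for fixed-effect recovery, 500 replicates of the 30-item
subset for ratio recovery, and 100 synthetic subjects for the
condition-mean pattern; these sizes give Monte-Carlo error comfortably
below the assertion margins.

## Known limitations

- The observer is a deliberately minimal control model: no eye movements,
  no perceptual mechanism for stripes (the coloration effect is injected
  as a swap-propensity offset), no learning across trials.
- ML variance components are biased low by O(1/S); with 15 subjects σᵤ²
  is estimated with ~37% sampling SD, so single-run variance estimates
  are noisy by construction.
- The empirical inferential statistics of the original human experiment
  depend on data that were never deposited and are not reproduced here;
  the pipeline reproduces the design exactly and the findings
  qualitatively, by construction.
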