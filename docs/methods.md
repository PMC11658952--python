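# Methods

## Model

The state is body weight alone. Everything else is algebraic in weight,
which keeps the model usable from clinically available inputs (weight, sex,
intake, activity level) and makes the ODE scalar:

    dw/dt = (EI(t) − TEE(w, t)) / ρ

with tissue energy density ρ = 7700 kcal per kg of weight change. Total
expenditure decomposes as

    TEE = PAL · (REE − AT) + β · EI

with the adaptive-thermogenesis reduction applied to REE *before* the PAL
multiplication (activity expenditure scales with the adapted resting rate),
and diet-induced thermogenesis a fixed fraction β of intake.

### Baseline body composition

Baseline FFM (kg) is linear in starting weight, anchored at a lean
reference individual: a lean 60 kg woman at 72% FFM (85% at 70 kg for men),
with excess weight above the reference carrying 25% FFM and 75% fat. The
anchors are configuration values, not code constants: the construction —
linearity plus a lean anchor plus an excess-partition fraction — is the
model; the anchor numbers are standard literature magnitudes and can be
replaced per population. Dividing by starting weight gives baseline FFM%
(≈ 55.2% at the 93.31 kg cohort mean), which decreases with starting
weight above the anchor because excess weight is mostly fat.

### Saturating trajectories

FFM% and AT both rise with relative weight loss x = (w0 − w)/w0 and
saturate:

* FFM%, original variant: exponential rise from baseline c to c + 10 pp,
  saturating at x = 0.10.
* FFM%, refined variant: linear rise to the same ceiling, saturating at
  x = 0.20.
* AT (both variants): exponential rise from 0 to 15% of REE, saturating at
  x = 0.10.

The exponential curves use the normalised form

    f(x) = f_sat · (1 − e^(−kx)) / (1 − e^(−k·x_sat)),   k = ln(100)/x_sat,

clamped to f_sat for x ≥ x_sat. The shape constant puts the raw
exponential at 99% of its asymptote at the threshold, so the clamp
introduces a discontinuity smaller than 1e-9 in natural units while the
endpoint anchors (exactly 0 at baseline, exactly the ceiling at and beyond
the threshold) hold to machine precision. Relative loss is always measured
against the pre-intervention weight w0 and is never re-based; transient
numerical excursions above w0 are clamped to x = 0, and sustained weight
gain is outside model scope.

A consequence worth knowing: because FFM% climbs 10 points while weight
falls only 10–20%, model FFM in kilograms can *rise* during weight loss
for typical baselines. This is a faithful rendering of the stated
trajectory, not a bug; it slightly raises REE and so dampens the deficit.

### Model constants

| parameter | default | units | meaning |
|---|---|---|---|
| energy_density | 7700 | kcal/kg | deficit-to-weight conversion |
| dit_coeff | 0.05 | – | DIT fraction of intake (obese population; 0.10 lean) |
| at_ceiling | 0.15 | – | AT at saturation, fraction of REE |
| ffm_shift | 10 | pp | FFM% rise at saturation |
| sat_threshold_original | 0.10 | – | saturation loss, exponential FFM% and AT |
| sat_threshold_refined | 0.20 | – | saturation loss, linear FFM% |
| excess_ffm_frac | 0.25 | – | FFM share of excess weight |
| Cunningham | 500 + 22·FFM | kcal/d | original REE equation |
| Mifflin (FFM form) | 413 + 19.7·FFM | kcal/d | refined REE equation |
| PAL | 1.6 | – | default activity multiplier (range 1.2–2.4) |

The two named variants differ in exactly two switches (REE equation and
FFM trajectory); any cross combination is configurable. Whether the
Mifflin refinement should only ever appear together with the linear FFM
trajectory is left to the user: the presets pair them, the config does not
force it.

## Numerics

Integration is adaptive Runge–Kutta (RK45) with rtol = atol = 1e-8,
segmented at every intake discontinuity: the step from 800 to 1200 kcal/d
at week 10 (half-open convention — day 70 itself already carries
1200 kcal/d, since reintroduction starts *from* week 10) would otherwise
degrade the adaptive stepper. Within a segment, RHS evaluation times are
clamped to just inside the segment so the half-open step cannot leak the
post-switch intake into the pre-switch segment's final stage evaluations.
Daily outputs are read from the dense solution; weekly weigh-in values are
the weights at days 7, 14, … (end-of-week convention). One extra sample is
emitted just before each intake discontinuity so that trapezoidal
integration of the reported deficit reproduces the energy stored/lost to
within 0.1% — without it the step is smeared over one day of the grid.

End-weights are reproducible to well under 1 g across solver tolerances
spanning two orders of magnitude, and agree with an independent fixed-step
forward-Euler integration (dt = 0.01 d) to well under 5 g over 12 weeks;
both checks are in the test suite, with the Euler oracle written as a
plain loop independent of the scipy solver path.

Degenerate inputs: non-positive weight raises a simulation-diverged error
naming the day; a trajectory whose FFM falls below the sex-specific lean
reference emits a warning but continues (the model imposes no weight
floor); zero-deficit inputs integrate to a flat line.

## Synthetic cohort

The generator emulates the structure of a female commercial TDR cohort so
the pipeline is testable without proprietary data:

* baseline weight ~ Normal(93.31, 19.18) kg truncated below at 45 kg — a
  guard against non-physical draws placed ~2.5 SD below the mean so it
  shifts the realised mean by ≲ 0.35 kg;
* intervention length drawn from {6…12} weeks with probabilities
  (0.135, 0.16, 0.18, 0.16, 0.14, 0.14, 0.085) — mode at 8 weeks and
  smallest mass at 12, matching the enrolment pattern's two known
  proportions (≈ 18% at 8 weeks, ≈ 8.5% at 12) with the rest spread
  smoothly;
* a latent "true" trajectory simulated by the dynamic model itself, with
  intake raised by +200 kcal/d from week 8 onward (relaxed compliance; an
  invented fixture magnitude, flagged as such);
* an observed-weight overlay for glycogen-water loss: per-subject bolus b
  drawn uniformly from 1.5–2.0 kg, expressed as extra observed loss
  b·(1 − 2^(−t/half-life)) with a 5-day half-life, so the bolus is
  essentially complete within the first 7–10 days. It is water, not an
  energy store, so it never enters the energy model;
* i.i.d. Gaussian weigh-in noise, SD 0.3 kg — a realistic weekly
  scale/clothing/hydration jitter.

Everything is reproducible from the spec's single seed.

What the generator does *not* emulate: between-subject variation in PAL,
AT capacity ("thrifty"/"spendthrift" phenotypes) or adherence style;
drop-out correlated with progress; measurement error correlated over
weeks; the 600–800 kcal/d prescription range (all subjects get the
800/1200 step schedule). Passing pipeline tests therefore demonstrate
internal consistency and the qualitative error anatomy — under-prediction
of loss early from water weight, shrinking or reversing later under
compliance drift — not quantitative agreement with any real cohort. With
the default magnitudes the persistent ~1.75 kg water offset outweighs the
~0.7 kg compliance effect by week 12, so the mean weekly error rises from
about −2% at week 3 toward zero without crossing it; only the sign pattern
and ordering are claims of the package.

## Evaluation statistics

δ = (actual − predicted)/actual × 100, positive when the model
under-predicts end-weight (over-predicts loss). Cohort summaries report
mean and sample SD (n − 1; the conventional choice for cohort "mean (SD)"
reporting) of δ in percent and of the kg difference, computed per subject
and then aggregated — never δ% applied to a mean weight. Weekly profiles
use listwise per-week availability (n declines with week), no imputation.
Bland–Altman limits of agreement default to bias ± 2 SD of the paired
differences, with 1.96 available by option. Hypothesis tests (ANOVA,
paired t, normality) are deliberately out of scope: the module exposes the
paired differences for any stats package to consume.

## Problem sizes

The test suite and the acceptance script use cohorts of 100–1000 subjects
and a 245-cell subject/deficit/duration grid; each simulation is a scalar
ODE over ≤ 84 days and runs in milliseconds, so the whole suite completes
in a few seconds. These sizes give sub-0.1-percentage-point standard
errors on every cohort-level quantity asserted.
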