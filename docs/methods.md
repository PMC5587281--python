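# Methods

This note documents the models and procedures `squatcrf` implements, the
numerical choices behind them, what the synthetic generators do and do not
emulate, and the package's known limitations.

## Signal harmonization

Recordings arrive from heterogeneous devices (e.g. a belt-worn ±2 g / 20 Hz
logger, a wrist-worn ±8 g / 16 Hz module) and are brought to a canonical
20 Hz / ±2 g representation before feature extraction.

* **Resampling** is polyphase rational resampling
  (`scipy.signal.resample_poly`; up 5 / down 4 for 16→20 Hz) with its
  built-in anti-aliasing low-pass.  The useful signal content of a
  0.667 Hz squat movement with a few harmonics sits well below 4 Hz, so a
  band-limited method preserves it essentially exactly; the package's tests
  verify < 2 % change in the downstream feature between native-20 Hz and
  resampled-from-16 Hz versions of the same continuous-time signal.
  Boundaries are padded with the signal mean (`padtype="mean"`) so the 1 g
  gravity offset is not distorted at the edges; edge transients die out well
  before the first analysis window (sample 200).
* **Saturation to ±2 g happens after resampling.**  Clipping first would
  put discontinuities into the interpolator; clipping last reproduces what a
  natively ±2 g device would have recorded, up to interpolation error.
* Harmonization is idempotent: a 20 Hz recording inside ±2 g passes through
  unchanged sample-for-sample.
* Raw files are delimited text (comma or tab, auto-detected), one sample per
  row, three acceleration columns in g, named (`x`/`y`/`z` and common
  aliases) or positional; sampling rate and range are caller-supplied
  metadata, not read from the file.  No proprietary binary formats are
  parsed, and no artifact rejection beyond range saturation is attempted.

## The motion-decay feature R_FSmax

Pipeline: magnitude → windows → de-mean + low-pass per window →
cross-correlation → maximum.

* **Windows.**  The magnitude series is windowed at the 0-based half-open
  intervals [200, 350) and [650, 800) — exactly 150 samples (7.5 s) each.
  An inclusive reading of "the 200th to the 350th sample" would span 151
  samples; the half-open convention preserves the stated window length, and
  a one-sample placement shift has negligible effect on the feature.  The
  first 10 s are excluded because subjects take a few repetitions to lock
  onto the metronome.
* **Filtering.**  Each window is de-meaned, then filtered with a 4th-order
  Butterworth low-pass at 4 Hz applied forward-backward
  (`sosfiltfilt`, reflective padding).  Zero-phase filtering matters here:
  a causal filter would delay both windows, and any differential lag would
  corrupt a statistic defined as a maximum over lags.  Applied twice, the
  filter's amplitude response is |H(f)|²: ≈ 1.00 at 1 Hz and ≈ 0.004 at
  8 Hz.  Tests measure sinusoid amplitudes away from the window edges,
  where the padding transient (an edge artifact, not part of the frequency
  response) has decayed.
* **Cross-correlation** is the plain unnormalized sum
  R_FS[n] = Σ_m fp[m]·sp[n+m] with zero-padding outside the windows, over
  the full lag range −149…149.  It is deliberately not normalized by the
  segment energies: both waveform change *and* amplitude loss are
  manifestations of fatigue, and the published feature scale (group means
  ≈ 4.6 for belt-worn CAD patients to ≈ 20 for wrist-worn healthy adults)
  is only consistent with the unnormalized statistic.  A normalized variant
  (`rfs_max_normalized`, bounded by 1, scale-invariant) is exposed as a
  clearly named alternative.
* **The maximum is signed**, not the maximum of |R_FS|: anti-correlation is
  not similarity.
* Implementation note: the fast path is `np.correlate`; an independent
  double-loop oracle in the test suite pins the lag and sign conventions and
  agrees to < 1e−9 relative error.

## Prediction models and validation statistics

* **Published coefficient sets** (`PUBLISHED_MODELS`): model_1a
  (1.587, 0.01443, −0.01759, 0.674, 0.01712) over weight/age/sex/R_FSmax for
  healthy adults; model_1b (0.145, 0.0299, −0.0182, 0.18, 0.0305) for the
  normal-to-low-fitness healthy subset (relative fitness < 40 ml/min/kg);
  model_2 (4.624, 0.00311, −0.0516, 0.123) over weight/age/R_FSmax for male
  CAD patients.  Sex is coded female = 0, male = 1 — the coding consistent
  with positive sex coefficients alongside males' higher absolute V̇O2peak;
  the `predict` linearity test (male = female + 0.18 L/min under model_1b)
  documents the check.
* **Refitting is forced-entry OLS** (statsmodels) on the stated predictor
  set.  The published models retain terms with p-values up to ≈ 0.5, which
  no conventional stepwise entry threshold would admit, so reproduction
  must not re-select terms.  A configurable `stepwise_forward`
  (smallest-entry-p-below-threshold, ties broken by candidate order) is
  provided as a separate operation for de-novo model building.
* **LOOCV** refits the *fixed* predictor set on each n−1 subset and predicts
  the held-out subject.  Per-fold selection would make a single printed
  coefficient set unreproducible, so selection never runs inside folds.
  RMSE_cv is reported absolute (L/min) and as a percentage of the analyzed
  group's mean measured V̇O2peak; r_cv is the Pearson correlation of
  held-out predictions with measurements.  Note r (in-sample, fitted vs
  measured) and r_cv are distinct statistics and both are reported.
* **Bland-Altman agreement** uses the held-out differences
  (predicted − measured): bias = mean, limits of agreement = bias ± 1.96·SD
  (sample SD, n−1).  In-sample residuals of an OLS fit with intercept have
  mean exactly zero, so an in-sample "bias" would be vacuous; the held-out
  bias is small but non-zero, which is the informative quantity.
* **Partial correlation** of a predictor with V̇O2peak given the others is
  computed by residualizing both on the controls (with intercept) and
  correlating the residuals; with no controls it reduces to the Pearson
  correlation.  The test suite cross-checks against `pingouin`.
* **Fitness categories** are lower-inclusive 10 ml/min/kg bins [20,30),
  [30,40), [40,50) of relative fitness 1000·V̇O2peak/weight; values outside
  [20, 50) go to the nearest edge bin with a `clamped` flag rather than
  erroring, since they are physiologically possible.  The "normal to low"
  flag (< 40 ml/min/kg) defines the model_1b subset.  Per-category RMSE_cv
  uses that category's mean measured V̇O2peak as the percentage denominator.

## Synthetic data

### Signal generator

`simulate_squat_signal` produces an idealized stand–squat–stand recording:
the vertical axis carries 1 g plus a periodic waveform of 3 harmonics at the
0.667 Hz repetition frequency (80 bpm metronome, two beats per repetition)
with fixed relative amplitudes (1, 0.4, 0.15) — giving realistic sub-4 Hz
content so the filtering stage is meaningfully exercised — and the two
horizontal axes carry smaller phase-shifted copies.  Fatigue enters through
two knobs: `amplitude_decay` scales the waveform linearly down over the
recording, and `tempo_drift` lengthens the instantaneous period linearly
(integrated in closed form to a phase function).  White Gaussian noise
(default SD 0.05 g) is added per axis.  All randomness flows from the
per-call seed.

Default per-axis amplitudes by wearing site (wrist 0.5 g, belt 0.28 g) were
chosen once so that simulated healthy wrist-worn and CAD belt-worn cohorts
yield R_FSmax ranges bracketing the published group means (≈ 18.6 ± 7.7 and
4.6 ± 1.8 g²·samples respectively).  The fitness→decay link
`decay = clip(0.9 − 0.02·relative_fitness, 0, 0.9)` encodes only the
direction and rough scale of the fatigue–fitness relationship: a
45 ml/min/kg subject squats without decay, a 25 ml/min/kg subject loses
≈ 40 % of movement amplitude.

What the generator does **not** emulate: multi-segment body kinematics,
posture-dependent gravity rotation, missed or extra repetitions,
non-stationary noise, device timestamp jitter.  Tests passing on these
signals therefore show the pipeline's correctness and sensitivity to the
modeled fatigue effects, not robustness to every artifact of real wearables
data.

### Cohort generator

`simulate_cohort` draws weight, age, height from Gaussians (defaults:
healthy 77.4 ± 12 kg, 31.3 ± 7.8 yr; CAD 93.7 ± 11.7 kg, 56.6 ± 7.4 yr,
all male), sex from a Bernoulli, and a latent relative fitness.  R_FSmax
comes either from a linear link on the latent fitness plus noise, or — with
`via_signals=True` — by synthesizing a full recording per subject (decay
from the fitness→decay link, device conventions by group) and running the
actual feature extractor.  V̇O2peak is then the generating linear model plus
Gaussian noise (default residual SD 0.44 L/min healthy / 0.21 L/min CAD,
matching the published in-sample residual scales).  This gives cohorts with
exactly the statistical structure the models assume — which is the point:
they support exact-recovery, recovery-bias and end-to-end predictivity
tests, not claims about real populations.

### The synthetic reference cohort

`synthetic_reference_cohort` is a constructed stand-in for a reference
subject table (the original study data is not distributed with the
package).  Its group structure copies the published cohort — 30 healthy
subjects (12 F / 18 M) of whom exactly 17 fall below 40 ml/min/kg, and 18
male CAD patients — with characteristics drawn from the published group
means/SDs.  The V̇O2peak vector is then solved for, not drawn: the
normal-to-low block is model-1b fitted values plus noise orthogonal to that
block's design matrix; the 13 fit subjects' values must then supply the
cross-moments that make the full-group fit exactly model 1a, which is an
under-determined linear system intersected with per-subject plausibility
bounds (relative fitness strictly above 40, below 70).  A linear program
checks feasibility of each random draw (most draws are infeasible and are
rejected), and the feasible point is blended toward a mid-range target.
The CAD block is model-2 fitted values plus a minimal correction making the
fit exact.  By construction, forced-entry OLS on the three analysis groups
returns the three published coefficient sets to machine precision — which
is what makes the table useful for verifying the reproduction pipeline
end-to-end (filters, fitting, reporting).  Its cross-validation, agreement
and partial-correlation statistics are emergent properties of the
construction and do not reproduce any real cohort's values.

## Numerical conventions and degenerate inputs

* Rank-deficient designs raise a `SingularDesignError` (checked per LOOCV
  fold, naming the fold) rather than silently pseudo-inverting.
* Stepwise ties break on candidate order; an empty selection returns the
  intercept-only model.
* Partial correlations with (near-)constant residuals (SD < 1e−12) raise
  `UndefinedResultError`.
* Report rendering rounds coefficients/SEs to 5 decimals and metrics to 3,
  and sorts JSON keys, so repeated runs on identical inputs are
  byte-identical.
* Problem sizes in the test suite and acceptance script (e.g. 50 noise
  seeds per decay level, 100 cohorts of n = 200 for recovery bias, 20
  replicates of the n = 50 end-to-end pipeline) were chosen to make the
  Monte-Carlo assertions stable across seeds while keeping a full run in
  seconds.

## Limitations

* The published coefficient sets apply to the populations and devices they
  were derived on; the package applies them to whatever data it is given
  and leaves external validity to the user.
* Exact reproduction of a study's cross-validated statistics depends on
  conventions the package had to fix by choice (held-out vs in-sample
  Bland-Altman, fixed-set LOOCV, the half-open window convention, filter
  family and order); these choices are documented above and in the code.
* The feature assumes the metronome protocol: 45 s at 80 bpm, windows at
  fixed sample indices.  Recordings of other durations fail fast with an
  insufficient-duration error rather than being silently re-windowed.
* No repetition counting, pose estimation or gravity-axis decomposition is
  attempted; heart-rate-based models and breath-gas processing are out of
  scope.
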