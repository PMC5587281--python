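# squatcrf

Cardiorespiratory fitness (CRF) carries diagnostic and prognostic weight in
cardiology, but measuring it properly needs a maximal exercise test, and the
usual submaximal shortcuts lean on heart rate — which β-blockers, standard
therapy in coronary artery disease (CAD), blunt.  `squatcrf` implements a
heart-rate-free alternative: a 45-second squat test at a fixed metronome
tempo (80 bpm), recorded with nothing but a tri-axial accelerometer.  The
degree to which the movement pattern deteriorates over those 45 seconds —
motion decay — turns out to track aerobic capacity.

The package is for physiologists and digital-health engineers who want to
run, validate or extend this test: it extracts the motion-decay feature from
raw accelerometry, applies or refits the V̇O2peak prediction models, and
reproduces the associated validation statistics, with a synthetic-signal and
synthetic-cohort generator so that every stage is testable without any
recordings.

## The feature and the models

From a recording harmonized to 20 Hz / ±2 g, the per-sample magnitude
`‖a‖ = √(x² + y² + z²)` is computed.  Two 150-sample (7.5 s) windows are cut —
samples [200, 350) early in the test and [650, 800) late — skipping the
initial adaptation phase.  Each window is de-meaned and low-pass filtered at
4 Hz (zero-phase Butterworth), and their unnormalized cross-correlation

    R_FS[n] = Σ_m MagnFP[m] · MagnSP[n + m]

is maximized over all lags to give **R_FSmax** (units g²·samples).  A subject
who keeps the pace produces nearly identical windows and a large R_FSmax; a
fatiguing subject's late window shrinks and deforms, lowering it.

V̇O2peak (L/min) is then predicted linearly from weight (kg), age (yr), sex
(F = 0, M = 1) and R_FSmax.  Three published coefficient sets ship with the
package: `model_1a` (healthy adults), `model_1b` (healthy adults below
40 ml/min/kg relative fitness) and `model_2` (male CAD patients; no sex
term).  Validation statistics follow the standard playbook: leave-one-subject-
out cross-validation (RMSE_cv in L/min and as % of the group's mean measured
V̇O2peak; r_cv between held-out predictions and measurements), Bland-Altman
bias ± 1.96 SD limits of agreement on held-out differences, partial
correlations, and RMSE_cv per 10 ml/min/kg fitness category.

## Worked example

Simulate a squat recording with 30 % amplitude decay, extract the feature,
and apply the CAD model at its group-mean characteristics:

```console
$ squatcrf simulate signal --decay 0.3 --seed 7 --out rec.csv
$ squatcrf extract --input rec.csv --rate 20 --subject-id demo --out features.csv
15.097719
$ squatcrf predict --model 2 --weight 93.7 --age 56.6 --rfsmax 4.6
2.5606
```

The first number is R_FSmax of the simulated recording (g²·samples); the
second is the predicted V̇O2peak in L/min — 4.624 + 0.00311·93.7 −
0.0516·56.6 + 0.123·4.6 = 2.5606.

The `reproduce` command refits all three models on a subject table and emits
every headline statistic.  On the package's built-in synthetic reference
cohort (a constructed stand-in table whose exact least-squares solutions are
the published coefficient sets — see `docs/methods.md`):

```console
$ python -c "from squatcrf import synthetic_reference_cohort;
             synthetic_reference_cohort(seed=0).to_csv('ref.csv', index=False)"
$ squatcrf reproduce --table ref.csv --format text
== model_1b (healthy subjects with relative fitness < 40 ml/min/kg; n = 17) ==
  term               coef       SE        t        p  partial r
  intercept       0.14500    0.399    0.364    0.722
  weight          0.02990    0.004    7.515    0.000      0.91
  age            -0.01820    0.008   -2.211    0.047     -0.54
  sex             0.18000    0.158    1.139    0.277      0.31
  rfsmax          0.03050    0.007    4.337    0.001      0.78
  r = 0.979  adj r2 = 0.945  RMSE = 0.142 L/min
  LOOCV: RMSE_cv = 0.210 L/min (8.4%)  r_cv = 0.954
  Bland-Altman: bias = 0.004, LoA = [-0.421, 0.429] L/min
  ...
```

The coefficients are recovered exactly; the cross-validation and agreement
numbers describe this synthetic table, not any real cohort.

Library use mirrors the CLI:

```python
from squatcrf import (read_recording, compute_rfsmax,
                      PUBLISHED_MODELS, predict, loocv)

rec = read_recording("rec.csv", sampling_rate=16, range_g=8, wearing_site="wrist")
feature = compute_rfsmax(rec)          # harmonize -> magnitude -> windows -> R_FSmax
vo2 = predict(PUBLISHED_MODELS["model_1b"],
              {"weight": 70, "age": 35, "sex": "female", "rfsmax": feature})
```

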