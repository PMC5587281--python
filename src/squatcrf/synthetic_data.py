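"""Synthetic squat-test signals and synthetic subject cohorts.

Everything in this module exists so that the full pipeline — harmonization,
feature extraction, model fitting, cross-validation — can be exercised and
tested without any external recordings.

Two generators are provided:

* :func:`simulate_squat_signal` — a tri-axial recording of a metronome-paced
  squat test (80 bpm, i.e. a 0.667 Hz repetition fundamental) with a 1 g
  gravity offset, a small number of waveform harmonics, and two controllable
  fatigue effects: a linear amplitude decay over the recording and a linear
  tempo drift (period lengthening).  Both effects lower the motion-decay
  feature R_FSmax of the resulting recording.

* :func:`simulate_cohort` — a subject table whose measured V̇O2peak follows a
  linear model in weight/age/sex/R_FSmax with Gaussian noise, with predictor
  distributions defaulting to the healthy (77.4 ± 12 kg, 31.3 ± 7.8 yr) and
  CAD (93.7 ± 11.7 kg, 56.6 ± 7.4 yr, all male) group characteristics.
  R_FSmax is produced from a latent relative-fitness draw through a linear
  link, or — with ``via_signals=True`` — by actually synthesizing a recording
  per subject (decay set by :func:`fitness_decay_link`) and running the
  feature extractor on it.

:func:`synthetic_reference_cohort` builds a SYNTHETIC stand-in for a
reference subject table: its group structure (30 healthy = 12 F + 18 M, of
whom 17 below 40 ml/min/kg; 18 male CAD patients) matches the published
cohort, and its V̇O2peak values are constructed so that the exact ordinary
least squares solutions on the three analysis groups equal the published
coefficient sets.  It is a constructed object for pipeline verification, not
real data.

All randomness flows from a single per-call seed; no global state is used.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ContractError
from .features import compute_rfsmax
from .modeling import (
    PUBLISHED_MODELS,
    REQUIRED_COLUMNS,
    ModelSpec,
    design_matrix,
)
from .signal_io import AccelRecording

#: Default per-axis motion amplitude (g) by wearing site; wrist-worn sensors
#: see larger excursions than belt-worn ones during squats.
SITE_AMPLITUDE = {"wrist": 0.5, "belt": 0.28, "other": 0.4}

#: Relative amplitudes of the waveform harmonics (fundamental first).
HARMONIC_AMPLITUDES = (1.0, 0.4, 0.15)
#: Fixed phase offsets of the harmonics, radians.
HARMONIC_PHASES = (0.0, 0.7, 1.3)


# ---------------------------------------------------------------------------
# Squat-signal generator
# ---------------------------------------------------------------------------

@dataclass
class SquatSignalParams:
    """Parameters of one synthetic 45-second squat recording.

    ``squat_frequency`` defaults to 0.667 Hz: an 80 bpm metronome with two
    beats per repetition (one down, one up) gives 40 repetitions per minute.
    ``amplitude_decay`` is the fractional amplitude lost by the end of the
    recording (linear in time), ``tempo_drift`` the fractional period
    lengthening over the recording.
    """

    duration: float = 45.0  # s
    sampling_rate: float = 20.0  # Hz
    squat_frequency: float = 2.0 / 3.0  # Hz
    base_amplitude: float = 0.5  # g
    amplitude_decay: float = 0.0  # in [0, 1)
    tempo_drift: float = 0.0  # fractional period lengthening
    noise_sd: float = 0.05  # g
    harmonics: int = 3
    seed: int = 0
    range_g: float = 2.0
    wearing_site: str = "other"
    subject_id: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.amplitude_decay < 1.0:
            raise ContractError(
                f"amplitude_decay must be in [0, 1), got {self.amplitude_decay!r}"
            )
        if self.noise_sd < 0:
            raise ContractError(f"noise_sd must be non-negative, got {self.noise_sd!r}")
        if self.tempo_drift < 0:
            raise ContractError(f"tempo_drift must be non-negative, got {self.tempo_drift!r}")
        if self.duration <= 0 or self.sampling_rate <= 0 or self.base_amplitude < 0:
            raise ContractError("duration, sampling_rate must be positive; base_amplitude ≥ 0")
        if not self.squat_frequency * self.harmonics < self.sampling_rate / 2:
            raise ContractError(
                "highest harmonic must stay below the Nyquist frequency"
            )
        if not 1 <= self.harmonics <= len(HARMONIC_AMPLITUDES):
            raise ContractError(
                f"harmonics must be in 1..{len(HARMONIC_AMPLITUDES)}, got {self.harmonics!r}"
            )


def _squat_phase(t: np.ndarray, params: SquatSignalParams) -> np.ndarray:
    """Accumulated phase (radians) with the period stretched linearly in time.

    The instantaneous period is p0·(1 + tempo_drift·t/T); integrating the
    instantaneous frequency gives the closed form below.
    """
    f0, T, d = params.squat_frequency, params.duration, params.tempo_drift
    if d == 0.0:
        return 2.0 * np.pi * f0 * t
    return 2.0 * np.pi * f0 * T / d * np.log1p(d * t / T)


def simulate_squat_signal(params: SquatSignalParams) -> AccelRecording:
    """Generate one tri-axial squat-test recording.

    The vertical (gravity) axis carries 1 g plus the squat waveform; the two
    horizontal axes carry smaller, phase-shifted copies of the same waveform
    family.  The waveform amplitude shrinks linearly by ``amplitude_decay``
    over the recording and white Gaussian noise of ``noise_sd`` g is added per
    axis.  Identical parameters and seed give identical output.
    """
    rng = np.random.default_rng(params.seed)
    n = int(round(params.duration * params.sampling_rate))
    t = np.arange(n) / params.sampling_rate
    phase = _squat_phase(t, params)
    envelope = params.base_amplitude * (1.0 - params.amplitude_decay * t / params.duration)

    def waveform(extra_phase: float) -> np.ndarray:
        w = np.zeros_like(t)
        for k in range(params.harmonics):
            w += HARMONIC_AMPLITUDES[k] * np.sin((k + 1) * phase + HARMONIC_PHASES[k] + extra_phase)
        return w

    z = 1.0 + envelope * waveform(0.0)
    x = 0.30 * envelope * waveform(np.pi / 2)
    y = 0.20 * envelope * waveform(np.pi / 4)
    if params.noise_sd > 0:
        x = x + rng.normal(0.0, params.noise_sd, n)
        y = y + rng.normal(0.0, params.noise_sd, n)
        z = z + rng.normal(0.0, params.noise_sd, n)
    return AccelRecording(
        x=x,
        y=y,
        z=z,
        sampling_rate=params.sampling_rate,
        range_g=params.range_g,
        device_id="synthetic",
        wearing_site=params.wearing_site,
        subject_id=params.subject_id,
    )


def fitness_decay_link(
    rel_fitness: float, *, intercept: float = 0.9, slope: float = 0.02,
    lo: float = 0.0, hi: float = 0.9,
) -> float:
    """Map weight-normalized fitness (ml/min/kg) to an amplitude-decay fraction.

    decay = clip(intercept − slope·rel_fitness, lo, hi): fitter subjects lose
    less movement amplitude over the test.  Defaults place a 45 ml/min/kg
    subject at zero decay and a 25 ml/min/kg subject at 0.4.
    """
    return float(np.clip(intercept - slope * rel_fitness, lo, hi))


# ---------------------------------------------------------------------------
# Cohort generator
# ---------------------------------------------------------------------------

@dataclass
class CohortParams:
    """Parameters of a synthetic subject cohort.

    ``model`` supplies the generating linear model for V̇O2peak (intercept +
    coefficients over its predictor set); ``noise_sd`` is the residual SD in
    L/min.  R_FSmax comes from a latent relative-fitness draw through the
    linear link rfsmax = link_intercept + link_slope·rel_fitness + noise,
    truncated at zero.
    """

    n: int
    group: str = "healthy"
    seed: int = 0
    model: ModelSpec = None  # defaults to the published model for the group
    noise_sd: float = 0.44  # L/min
    weight_mean: float = 77.4
    weight_sd: float = 12.0
    age_mean: float = 31.3
    age_sd: float = 7.8
    height_mean: float = 175.4
    height_sd: float = 7.0
    p_male: float = 0.6
    relfit_mean: float = 36.5  # latent relative fitness, ml/min/kg
    relfit_sd: float = 6.5
    link_intercept: float = -10.6
    link_slope: float = 0.8
    link_sd: float = 4.0

    def __post_init__(self) -> None:
        if self.model is None:
            self.model = PUBLISHED_MODELS["model_1a" if self.group == "healthy" else "model_2"]
        if self.group not in ("healthy", "cad"):
            raise ContractError(f"group must be 'healthy' or 'cad', got {self.group!r}")
        if self.n < len(self.model.predictors) + 2:
            raise ContractError(
                f"n must be at least {len(self.model.predictors) + 2} "
                f"for a {len(self.model.predictors)}-predictor model, got {self.n}"
            )
        for name in ("noise_sd", "weight_sd", "age_sd", "height_sd", "relfit_sd", "link_sd"):
            if getattr(self, name) < 0:
                raise ContractError(f"{name} must be non-negative")
        if not 0.0 <= self.p_male <= 1.0:
            raise ContractError(f"p_male must be in [0, 1], got {self.p_male!r}")

    @classmethod
    def for_group(cls, group: str, n: int, seed: int = 0, **overrides) -> "CohortParams":
        """Defaults emulating the healthy or CAD group characteristics."""
        if group == "cad":
            base = dict(
                weight_mean=93.7, weight_sd=11.7, age_mean=56.6, age_sd=7.4,
                height_mean=180.8, height_sd=6.6, p_male=1.0,
                relfit_mean=27.6, relfit_sd=4.5,
                link_intercept=-0.92, link_slope=0.2, link_sd=1.5,
                noise_sd=0.21,
            )
        else:
            base = dict()
        base.update(overrides)
        return cls(n=n, group=group, seed=seed, **base)


def simulate_cohort(params: CohortParams, *, via_signals: bool = False) -> pd.DataFrame:
    """Draw a subject table with the linear V̇O2peak structure the models assume.

    With ``via_signals=True`` each subject's R_FSmax is obtained by
    synthesizing a full squat recording (decay set from the subject's latent
    fitness via :func:`fitness_decay_link`, device conventions by group:
    healthy → wrist-worn 16 Hz / ±8 g, CAD → belt-worn 20 Hz / ±2 g) and
    running the feature extractor on it; otherwise R_FSmax comes from the
    linear latent-fitness link.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n
    weight = np.clip(rng.normal(params.weight_mean, params.weight_sd, n), 40.0, 160.0)
    age = np.clip(rng.normal(params.age_mean, params.age_sd, n), 18.0, 85.0)
    height = np.clip(rng.normal(params.height_mean, params.height_sd, n), 140.0, 210.0)
    male = rng.random(n) < params.p_male
    relfit = np.clip(rng.normal(params.relfit_mean, params.relfit_sd, n), 12.0, 65.0)

    if via_signals:
        site = "wrist" if params.group == "healthy" else "belt"
        rate = 16.0 if params.group == "healthy" else 20.0
        range_g = 8.0 if params.group == "healthy" else 2.0
        amp = SITE_AMPLITUDE[site]
        seeds = rng.integers(0, 2**31 - 1, size=n)
        rfsmax = np.empty(n)
        for i in range(n):
            sig = simulate_squat_signal(
                SquatSignalParams(
                    sampling_rate=rate,
                    range_g=range_g,
                    wearing_site=site,
                    base_amplitude=amp,
                    amplitude_decay=fitness_decay_link(relfit[i]),
                    tempo_drift=0.02,
                    seed=int(seeds[i]),
                )
            )
            rfsmax[i] = compute_rfsmax(sig)
    else:
        rfsmax = params.link_intercept + params.link_slope * relfit
        if params.link_sd > 0:
            rfsmax = rfsmax + rng.normal(0.0, params.link_sd, n)
        rfsmax = np.clip(rfsmax, 0.1, None)

    prefix = "H" if params.group == "healthy" else "C"
    df = pd.DataFrame(
        {
            "subject_id": [f"{prefix}{i + 1:03d}" for i in range(n)],
            "group": params.group,
            "sex": np.where(male, "male", "female"),
            "weight": weight,
            "height": height,
            "age": age,
            "vo2peak": 0.0,
            "rfsmax": rfsmax,
        }
    )
    X = design_matrix(df, params.model.predictors)
    vo2 = X @ params.model.coefficients
    if params.noise_sd > 0:
        vo2 = vo2 + rng.normal(0.0, params.noise_sd, n)
    df["vo2peak"] = np.clip(vo2, 0.3, None)
    return df[list(REQUIRED_COLUMNS)]


# ---------------------------------------------------------------------------
# Synthetic reference cohort (stand-in, constructed)
# ---------------------------------------------------------------------------

def _constrained_targets(y_tent: np.ndarray, A: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Smallest adjustment of y_tent satisfying the linear system A y = b."""
    correction, *_ = np.linalg.lstsq(A @ A.T, b - A @ y_tent, rcond=None)
    return y_tent + A.T @ correction


def _orthogonal_noise(rng: np.random.Generator, X: np.ndarray, sd: float) -> np.ndarray:
    """Gaussian noise projected orthogonal to the column space of X."""
    e = rng.normal(0.0, sd, X.shape[0])
    beta, *_ = np.linalg.lstsq(X, e, rcond=None)
    return e - X @ beta


def synthetic_reference_cohort(seed: int = 0) -> pd.DataFrame:
    """A SYNTHETIC stand-in subject table with the published models built in.

    The table mimics the published cohort structure — 30 healthy subjects
    (12 female, 18 male) of whom exactly 17 fall below 40 ml/min/kg, plus 18
    male CAD patients — with predictor distributions drawn from the published
    group means/SDs.  V̇O2peak values are then minimally adjusted so that the
    exact least-squares solutions are, by construction, the published
    coefficient sets: the full healthy fit equals model 1a, the
    normal-to-low-fitness healthy fit equals model 1b, and the CAD fit equals
    model 2.

    This is constructed data for verifying the reproduction pipeline
    (coefficient recovery, group filters, report completeness); its
    cross-validation statistics are NOT those of the real study data.
    """
    for attempt in range(3000):
        rng = np.random.default_rng((int(seed) % (2**31), attempt))
        df = _try_reference_cohort(rng)
        if df is not None:
            return df
    raise RuntimeError("could not construct a consistent synthetic reference cohort")


def _try_reference_cohort(rng: np.random.Generator) -> pd.DataFrame | None:
    """One attempt at the constrained construction; None if the draw is
    infeasible.

    The healthy V̇O2peak vector is assembled block-wise.  The 17 normal-to-low
    subjects get model-1b fitted values plus noise orthogonal to their design
    (so the subset OLS fit is exactly the model-1b coefficient set).  The full
    healthy fit then pins down the five cross-moments the 13 fit subjects must
    supply; a linear program checks whether those moments are attainable with
    every fit subject strictly above the 40 ml/min/kg line, and the feasible
    point is blended toward a mid-range target for a natural spread.  Most
    random draws are infeasible and are simply rejected.
    """
    from scipy.optimize import linprog

    beta_1a = PUBLISHED_MODELS["model_1a"].coefficients
    beta_1b = PUBLISHED_MODELS["model_1b"].coefficients
    beta_2 = PUBLISHED_MODELS["model_2"].coefficients

    # --- healthy group: 12 F + 18 M, per-sex characteristics ---------------
    n_f, n_m = 12, 18
    weight = np.concatenate([rng.normal(67.9, 8.2, n_f), rng.normal(83.7, 9.8, n_m)])
    height = np.concatenate([rng.normal(170.1, 4.8, n_f), rng.normal(178.9, 5.9, n_m)])
    age = np.clip(np.concatenate([rng.normal(31.3, 8.4, n_f), rng.normal(31.2, 7.7, n_m)]), 19, 60)
    sex = np.array(["female"] * n_f + ["male"] * n_m)
    weight = np.clip(weight, 45, 130)
    height = np.clip(height, 150, 205)

    # designate 13 "fit" subjects (5 F, 8 M) above the 40 ml/min/kg line
    fit_idx = np.concatenate(
        [rng.choice(n_f, 5, replace=False), n_f + rng.choice(n_m, 8, replace=False)]
    )
    is_fit = np.zeros(30, dtype=bool)
    is_fit[fit_idx] = True

    rfsmax = np.concatenate([rng.normal(16.2, 5.9, n_f), rng.normal(20.2, 8.5, n_m)])
    rfsmax = np.clip(rfsmax + np.where(is_fit, 3.0, -2.0), 0.5, None)

    healthy = pd.DataFrame(
        {
            "subject_id": [f"H{i + 1:03d}" for i in range(30)],
            "group": "healthy",
            "sex": sex,
            "weight": weight,
            "height": height,
            "age": age,
            "vo2peak": 1.0,
            "rfsmax": rfsmax,
        }
    )
    X = design_matrix(healthy, PUBLISHED_MODELS["model_1a"].predictors)
    S = ~is_fit  # the 17 normal-to-low subjects
    F = is_fit
    X_S, X_F = X[S], X[F]
    w_S, w_F = weight[S], weight[F]

    # normal-to-low block: exact model-1b fit plus design-orthogonal noise
    y_S = X_S @ beta_1b + _orthogonal_noise(rng, X_S, 0.18)
    rel_S = 1000.0 * y_S / w_S
    if rel_S.max() >= 39.8 or rel_S.min() < 20.5 or y_S.min() <= 1.0:
        return None

    # fit block: must supply the remaining cross-moments of the full 1a fit
    moments = X.T @ X @ beta_1a - X_S.T @ y_S
    lo, hi = 0.0405 * w_F, 0.070 * w_F
    lp = linprog(
        np.zeros(len(w_F)), A_eq=X_F.T, b_eq=moments,
        bounds=list(zip(lo, hi)), method="highs",
    )
    if lp.status != 0:
        return None
    y_mid = _constrained_targets(
        0.0465 * w_F + rng.normal(0.0, 0.12, len(w_F)), X_F.T, moments
    )
    # blend the (possibly out-of-box) mid-range point toward the LP-feasible
    # vertex; both satisfy the equality constraints, the box is convex
    t_needed = [0.0]
    for v_mid, v_lp, b_lo, b_hi in zip(y_mid, lp.x, lo, hi):
        if v_mid < b_lo and v_lp > v_mid:
            t_needed.append((b_lo - v_mid) / (v_lp - v_mid))
        elif v_mid > b_hi and v_lp < v_mid:
            t_needed.append((v_mid - b_hi) / (v_mid - v_lp))
    t = min(1.0, max(t_needed))
    y_F = (1.0 - t) * y_mid + t * lp.x
    if np.any(y_F < lo - 1e-9) or np.any(y_F > hi + 1e-9):
        return None

    y = np.empty(30)
    y[S], y[F] = y_S, y_F
    relfit = 1000.0 * y / weight
    if relfit[S].max() >= 39.8 or relfit[F].min() <= 40.2:
        return None
    healthy["vo2peak"] = y

    # --- CAD group: 18 males ----------------------------------------------
    n_c = 18
    weight_c = np.clip(rng.normal(93.7, 11.7, n_c), 60, 140)
    height_c = np.clip(rng.normal(180.8, 6.6, n_c), 160, 205)
    age_c = np.clip(rng.normal(56.6, 7.4, n_c), 40, 75)
    rfsmax_c = np.clip(rng.normal(4.6, 1.8, n_c), 0.5, None)
    cad = pd.DataFrame(
        {
            "subject_id": [f"C{i + 1:03d}" for i in range(n_c)],
            "group": "cad",
            "sex": "male",
            "weight": weight_c,
            "height": height_c,
            "age": age_c,
            "vo2peak": 0.0,
            "rfsmax": rfsmax_c,
        }
    )
    X_c = design_matrix(cad, PUBLISHED_MODELS["model_2"].predictors)
    y_tent_c = X_c @ beta_2 + rng.normal(0.0, 0.21, n_c)
    y_c = _constrained_targets(y_tent_c, X_c.T, X_c.T @ X_c @ beta_2)
    if np.any(y_c < 0.8):
        return None
    cad["vo2peak"] = y_c

    df = pd.concat([healthy, cad], ignore_index=True)
    return df[list(REQUIRED_COLUMNS)]
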