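"""Extraction of the motion-decay feature R_FSmax from a harmonized recording.

The 45-second squat test is paced by a metronome, so a subject who resists
fatigue produces a nearly periodic acceleration signal throughout.  The
feature quantifies how well the motion pattern is preserved between an early
and a late window of the test:

1. the per-sample Euclidean norm (magnitude) of the tri-axial signal is
   computed,
2. two 150-sample (7.5 s) windows are cut — samples [200, 350) early in the
   test and [650, 800) late in the test — skipping the initial adaptation
   phase,
3. each window is de-meaned and low-pass filtered at 4 Hz (zero-phase), and
4. the unnormalized cross-correlation between the two filtered windows is
   taken; its maximum over all lags is R_FSmax.

A high R_FSmax means the late window still resembles the early one (little
motion decay, good fatigue resistance); a low value means the pattern
deteriorated.  The statistic is deliberately unnormalized — both a change in
waveform shape and a loss of movement amplitude lower it — and the maximum is
the signed maximum (anti-correlation is not similarity).  Units are
g²·samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .errors import ContractError, InsufficientDurationError, PreconditionError
from .signal_io import CANONICAL_RANGE_G, CANONICAL_RATE, AccelRecording, harmonize

#: Analysis window length in samples (7.5 s at 20 Hz).
SEGMENT_LEN = 150
#: 0-based half-open analysis windows into the magnitude series.
WINDOW_FP = (200, 350)
WINDOW_SP = (650, 800)
#: Low-pass cutoff applied to each window, Hz.
CUTOFF_HZ = 4.0
#: Butterworth filter order (applied forward-backward, so the effective
#: attenuation is squared).
FILTER_ORDER = 4


@dataclass
class MagnitudeSeries:
    """Per-sample Euclidean norm of a harmonized recording, in g, at 20 Hz."""

    values: np.ndarray
    sampling_rate: float = CANONICAL_RATE

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ContractError("magnitude values must be one-dimensional")
        if np.any(self.values < 0):
            raise ContractError("magnitude values must be non-negative")

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class SegmentPair:
    """The two analysis windows (MagnFP early, MagnSP late), raw or filtered."""

    magn_fp: np.ndarray
    magn_sp: np.ndarray
    window_fp: tuple[int, int] = WINDOW_FP
    window_sp: tuple[int, int] = WINDOW_SP
    cutoff_hz: float = CUTOFF_HZ
    filtered: bool = False

    def __post_init__(self) -> None:
        self.magn_fp = np.asarray(self.magn_fp, dtype=float)
        self.magn_sp = np.asarray(self.magn_sp, dtype=float)
        for name, seg in (("magn_fp", self.magn_fp), ("magn_sp", self.magn_sp)):
            if seg.shape != (SEGMENT_LEN,):
                raise ContractError(
                    f"{name} must have exactly {SEGMENT_LEN} samples, got {seg.shape}"
                )


@dataclass
class CrossCorrelation:
    """Full cross-correlation values over integer lags −(L−1)…(L−1)."""

    values: np.ndarray
    lags: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.lags = np.asarray(self.lags, dtype=int)
        if self.values.shape != self.lags.shape:
            raise ContractError("values and lags must have equal length")


def magnitude(rec: AccelRecording) -> MagnitudeSeries:
    """Euclidean norm per sample of a harmonized recording.

    Raises
    ------
    PreconditionError
        If the recording is not at 20 Hz / ±2 g (run :func:`harmonize` first).
    """
    if not rec.is_harmonized():
        raise PreconditionError(
            "magnitude requires a harmonized recording "
            f"(20 Hz, ±{CANONICAL_RANGE_G:g} g); got {rec.sampling_rate:g} Hz, "
            f"range ±{rec.range_g:g} g"
        )
    values = np.sqrt(rec.x**2 + rec.y**2 + rec.z**2)
    return MagnitudeSeries(values=values)


def extract_segments(magn: MagnitudeSeries) -> SegmentPair:
    """Cut the raw early/late analysis windows from the magnitude series.

    The windows are 0-based half-open: [200, 350) and [650, 800).  The first
    200 samples (10 s) are skipped so that irregularities while the subject
    settles into the metronome tempo do not enter the feature.
    """
    required = WINDOW_SP[1]
    if len(magn) < required:
        raise InsufficientDurationError(required=required, actual=len(magn))
    return SegmentPair(
        magn_fp=magn.values[WINDOW_FP[0] : WINDOW_FP[1]].copy(),
        magn_sp=magn.values[WINDOW_SP[0] : WINDOW_SP[1]].copy(),
        filtered=False,
    )


def _lowpass_sos(sampling_rate: float = CANONICAL_RATE):
    return butter(FILTER_ORDER, CUTOFF_HZ, btype="low", fs=sampling_rate, output="sos")


def preprocess_segment(segment: np.ndarray, *, sampling_rate: float = CANONICAL_RATE) -> np.ndarray:
    """De-mean then low-pass filter one analysis window.

    The filter is a 4th-order Butterworth at 4 Hz run forward-backward
    (zero phase) with reflective edge padding, so no lag is introduced that
    could bias the lag-sensitive cross-correlation maximum.
    """
    seg = np.asarray(segment, dtype=float)
    if seg.shape != (SEGMENT_LEN,):
        raise ContractError(
            f"segment must have exactly {SEGMENT_LEN} samples, got {seg.shape}"
        )
    sos = _lowpass_sos(sampling_rate)
    return sosfiltfilt(sos, seg - seg.mean(), padtype="even")


def preprocess_pair(pair: SegmentPair) -> SegmentPair:
    """Apply :func:`preprocess_segment` to both windows of a pair."""
    return SegmentPair(
        magn_fp=preprocess_segment(pair.magn_fp),
        magn_sp=preprocess_segment(pair.magn_sp),
        window_fp=pair.window_fp,
        window_sp=pair.window_sp,
        filtered=True,
    )


def cross_correlate(fp: np.ndarray, sp: np.ndarray) -> CrossCorrelation:
    """Full unnormalized cross-correlation R_FS[n] = Σ_m fp[m]·sp[n+m].

    Samples outside the windows are treated as zero, giving 2L−1 values over
    lags −(L−1)…(L−1) for window length L.
    """
    fp = np.asarray(fp, dtype=float)
    sp = np.asarray(sp, dtype=float)
    if fp.ndim != 1 or sp.ndim != 1 or fp.shape != sp.shape:
        raise ContractError(
            f"windows must be one-dimensional and equal length, got {fp.shape} vs {sp.shape}"
        )
    L = len(fp)
    # np.correlate(sp, fp, "full")[k] = Σ_m sp[m + k − (L−1)]·fp[m]  ⇒  lag n = k − (L−1)
    values = np.correlate(sp, fp, mode="full")
    lags = np.arange(-(L - 1), L)
    return CrossCorrelation(values=values, lags=lags)


def rfs_max(xc: CrossCorrelation) -> float:
    """Maximum of the cross-correlation over all lags (signed, not |·|)."""
    return float(np.max(xc.values))


def rfs_max_normalized(fp: np.ndarray, sp: np.ndarray) -> float:
    """Alternative feature: cross-correlation maximum scaled by √(E_fp·E_sp).

    This variant is scale-invariant (it ignores amplitude loss and responds
    only to waveform change); the primary feature is the unnormalized
    :func:`rfs_max`.
    """
    fp = np.asarray(fp, dtype=float)
    sp = np.asarray(sp, dtype=float)
    energy = float(np.sqrt(np.sum(fp**2) * np.sum(sp**2)))
    if energy == 0.0:
        raise ContractError("normalized feature undefined for an all-zero window")
    return rfs_max(cross_correlate(fp, sp)) / energy


def compute_rfsmax(rec: AccelRecording, *, normalize: bool = False) -> float:
    """End-to-end feature extraction from a raw or harmonized recording.

    Pipeline: harmonize → magnitude → window extraction → de-mean + 4 Hz
    low-pass per window → cross-correlation → maximum.  Deterministic for a
    fixed input.
    """
    rec = harmonize(rec)
    pair = preprocess_pair(extract_segments(magnitude(rec)))
    if normalize:
        return rfs_max_normalized(pair.magn_fp, pair.magn_sp)
    return rfs_max(cross_correlate(pair.magn_fp, pair.magn_sp))
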