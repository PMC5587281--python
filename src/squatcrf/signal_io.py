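"""Reading, validation and harmonization of raw squat-test accelerometer recordings.

Recordings from different devices (e.g. a belt-worn ±2 g / 20 Hz logger, a
wrist-worn ±8 g / 16 Hz module) are brought to a single canonical
representation — 20 Hz sampling, samples saturated to ±2 g — before any
feature extraction.  Harmonization resamples first (polyphase rational
resampling with an anti-aliasing low-pass) and saturates afterwards, so the
interpolation operates on undistorted samples.

Gravity is deliberately NOT removed here; the feature pipeline subtracts the
segment mean before filtering, which absorbs the DC component.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace
from fractions import Fraction
from pathlib import Path

import numpy as np
from scipy.signal import resample_poly

from .errors import FormatError, InvalidMetadataError

#: Canonical sampling rate after harmonization, Hz.
CANONICAL_RATE = 20.0
#: Canonical symmetric saturation bound after harmonization, g.
CANONICAL_RANGE_G = 2.0

WEARING_SITES = ("wrist", "belt", "other")


@dataclass
class AccelRecording:
    """A tri-axial acceleration time series with device metadata.

    Parameters
    ----------
    x, y, z
        Per-sample acceleration along each sensing axis, in g.  Equal length,
        at least one sample.
    sampling_rate
        Sampling frequency in Hz; must be positive.
    range_g
        Symmetric saturation bound of the device in g (e.g. 2 or 8).
    device_id, wearing_site, subject_id
        Free-text device label, wearing site (``wrist``/``belt``/``other``)
        and subject label.
    """

    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    sampling_rate: float
    range_g: float = CANONICAL_RANGE_G
    device_id: str = ""
    wearing_site: str = "other"
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        if not (self.x.ndim == self.y.ndim == self.z.ndim == 1):
            raise InvalidMetadataError("axes must be one-dimensional arrays")
        if not (len(self.x) == len(self.y) == len(self.z)):
            raise InvalidMetadataError(
                f"axis lengths differ: x={len(self.x)}, y={len(self.y)}, z={len(self.z)}"
            )
        if len(self.x) < 1:
            raise InvalidMetadataError("recording must contain at least one sample")
        if not np.isfinite(self.sampling_rate) or self.sampling_rate <= 0:
            raise InvalidMetadataError(
                f"sampling_rate must be positive, got {self.sampling_rate!r}"
            )
        if self.range_g <= 0:
            raise InvalidMetadataError(f"range_g must be positive, got {self.range_g!r}")
        if self.wearing_site not in WEARING_SITES:
            raise InvalidMetadataError(
                f"wearing_site must be one of {WEARING_SITES}, got {self.wearing_site!r}"
            )

    @property
    def n_samples(self) -> int:
        return len(self.x)

    @property
    def duration(self) -> float:
        """Recording duration in seconds."""
        return self.n_samples / self.sampling_rate

    def samples(self) -> np.ndarray:
        """Return the samples as an (n, 3) array with columns x, y, z."""
        return np.column_stack([self.x, self.y, self.z])

    def is_harmonized(self, tol: float = 1e-9) -> bool:
        """True if at the canonical 20 Hz rate with samples inside ±2 g."""
        return (
            self.sampling_rate == CANONICAL_RATE
            and self.range_g == CANONICAL_RANGE_G
            and float(np.abs(self.samples()).max()) <= CANONICAL_RANGE_G + tol
        )


# ---------------------------------------------------------------------------
# Raw-file reading
# ---------------------------------------------------------------------------

_AXIS_ALIASES = {
    "x": ("x", "x_acc", "xacc", "acc_x", "ax"),
    "y": ("y", "y_acc", "yacc", "acc_y", "ay"),
    "z": ("z", "z_acc", "zacc", "acc_z", "az"),
}


def _is_number(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False


def read_recording(
    path: str | Path,
    *,
    sampling_rate: float,
    range_g: float = CANONICAL_RANGE_G,
    device_id: str = "",
    wearing_site: str = "other",
    subject_id: str = "",
) -> AccelRecording:
    """Read a delimited-text recording (one row per sample, columns x, y, z in g).

    Comma- or tab-delimited files are auto-detected, as is an optional header
    row; columns may be named (``x``/``y``/``z`` or common aliases) or
    positional (first three).  Device metadata is supplied by the caller, not
    read from the file.

    Raises
    ------
    FormatError
        Empty file, fewer than three columns, or a non-numeric cell — the
        message names the offending 1-based file row.
    """
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise FormatError(f"{path}: empty file")

    delimiter = "\t" if "\t" in text.splitlines()[0] else ","
    rows = [
        (lineno, row)
        for lineno, row in enumerate(csv.reader(text.splitlines(), delimiter=delimiter), start=1)
        if any(cell.strip() for cell in row)
    ]

    first = [c.strip() for c in rows[0][1]]
    has_header = not all(_is_number(c) for c in first if c)
    if has_header:
        lowered = [c.lower() for c in first]
        cols: dict[str, int] = {}
        for axis, aliases in _AXIS_ALIASES.items():
            for alias in aliases:
                if alias in lowered:
                    cols[axis] = lowered.index(alias)
                    break
        if len(cols) != 3:
            if len(first) < 3:
                raise FormatError(
                    f"{path}: expected three acceleration columns, found {len(first)}"
                )
            cols = {"x": 0, "y": 1, "z": 2}
        data_rows = rows[1:]
    else:
        cols = {"x": 0, "y": 1, "z": 2}
        data_rows = rows

    if not data_rows:
        raise FormatError(f"{path}: no data rows")

    out = {"x": [], "y": [], "z": []}
    for lineno, row in data_rows:
        cells = [c.strip() for c in row]
        if len(cells) < 3:
            raise FormatError(f"{path}: row {lineno}: expected 3 columns, found {len(cells)}")
        for axis, idx in cols.items():
            token = cells[idx]
            if not _is_number(token):
                raise FormatError(
                    f"{path}: row {lineno}: non-numeric value {token!r} in column {axis}"
                )
            out[axis].append(float(token))

    return AccelRecording(
        x=np.array(out["x"]),
        y=np.array(out["y"]),
        z=np.array(out["z"]),
        sampling_rate=float(sampling_rate),
        range_g=float(range_g),
        device_id=device_id,
        wearing_site=wearing_site,
        subject_id=subject_id,
    )


def write_recording(rec: AccelRecording, path: str | Path) -> None:
    """Serialize a recording to the canonical CSV dialect (header x,y,z)."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["x", "y", "z"])
        for row in rec.samples():
            writer.writerow([repr(float(v)) for v in row])


# ---------------------------------------------------------------------------
# Harmonization
# ---------------------------------------------------------------------------

def harmonize(rec: AccelRecording) -> AccelRecording:
    """Bring a recording to the canonical 20 Hz / ±2 g convention.

    Resampling uses polyphase rational resampling (e.g. up 5 / down 4 for a
    16 Hz source) with the mean-padded boundary so a gravity-offset signal is
    not distorted at the edges; samples are then saturated to ±2 g.  An input
    already at 20 Hz and inside ±2 g is returned sample-for-sample unchanged,
    which makes the operation idempotent.
    """
    if rec.sampling_rate == CANONICAL_RATE:
        xyz = [rec.x, rec.y, rec.z]
    else:
        frac = Fraction(CANONICAL_RATE / rec.sampling_rate).limit_denominator(1000)
        up, down = frac.numerator, frac.denominator
        xyz = [resample_poly(a, up, down, padtype="mean") for a in (rec.x, rec.y, rec.z)]
    xyz = [np.clip(a, -CANONICAL_RANGE_G, CANONICAL_RANGE_G) for a in xyz]
    return replace(
        rec,
        x=xyz[0],
        y=xyz[1],
        z=xyz[2],
        sampling_rate=CANONICAL_RATE,
        range_g=CANONICAL_RANGE_G,
    )
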