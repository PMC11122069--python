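"""Core domain types and file I/O for 6-channel IMU time series.

The sensor model is a 6-degree-of-freedom IMU worn on the head: triaxial
acceleration (``ax, ay, az``, in g) and triaxial angular velocity
(``gx, gy, gz``, in rad/s) sampled at a fixed rate (100 Hz by default).

Conventions used throughout the package:

* sample indexing is 0-based;
* segments are half-open intervals ``[start, end)`` so that
  ``duration = (end - start) / fs`` and concatenation is seamless;
* every time-valued threshold is converted to samples exactly once, at
  config load, through :func:`seconds_to_samples`.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, ParseError

#: Channel order used everywhere in the package.
CHANNELS: tuple[str, ...] = ("ax", "ay", "az", "gx", "gy", "gz")

#: Column indices of the accelerometer / gyroscope channels.
ACCEL_SLICE = slice(0, 3)
GYRO_SLICE = slice(3, 6)

#: The closed six-class gesture set, in lexicographic order (the order used
#: for deterministic tie-breaking in classification).
GESTURE_CLASSES: tuple[str, ...] = (
    "nod",
    "shake_left",
    "shake_right",
    "tilt_left",
    "tilt_right",
    "tilt_up",
)


def seconds_to_samples(t: float, fs: float) -> int:
    """Convert a duration in seconds to a sample count at rate ``fs``.

    Returns 0 for ``t == 0`` and ``max(1, round(t * fs))`` otherwise, so any
    strictly positive duration maps to at least one sample.

    Raises
    ------
    ValueError
        If ``t`` is negative or ``fs`` is not strictly positive.
    """
    if t < 0:
        raise ValueError(f"duration must be non-negative, got {t}")
    if fs <= 0:
        raise ValueError(f"sampling rate must be positive, got {fs}")
    if t == 0:
        return 0
    return max(1, round(t * fs))


@dataclass(eq=False)
class ImuSequence:
    """A fixed-rate 6-channel IMU time series.

    Parameters
    ----------
    data : ndarray of shape (n, 6)
        One row per sample, columns in :data:`CHANNELS` order
        (ax, ay, az in g; gx, gy, gz in rad/s). All values must be finite.
    fs : float
        Sampling rate in Hz, strictly positive.
    """

    data: np.ndarray
    fs: float = 100.0

    def __post_init__(self) -> None:
        arr = np.asarray(self.data, dtype=float)
        if arr.ndim == 1 and arr.size == 0:
            arr = arr.reshape(0, 6)
        if arr.ndim != 2 or arr.shape[1] != 6:
            raise ValueError(f"expected (n, 6) data, got shape {arr.shape}")
        if not np.all(np.isfinite(arr)):
            raise ValueError("IMU samples must be finite")
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        self.data = arr

    def __len__(self) -> int:
        return self.data.shape[0]

    @property
    def duration_s(self) -> float:
        return len(self) / self.fs

    @property
    def accel(self) -> np.ndarray:
        """(n, 3) view of the accelerometer channels, in g."""
        return self.data[:, ACCEL_SLICE]

    @property
    def gyro(self) -> np.ndarray:
        """(n, 3) view of the gyroscope channels, in rad/s."""
        return self.data[:, GYRO_SLICE]

    def channel(self, name: str) -> np.ndarray:
        return self.data[:, CHANNELS.index(name)]


@dataclass(frozen=True)
class Segment:
    """Half-open sample-index interval ``[start, end)`` into an ImuSequence."""

    start: int
    end: int
    source_fs: float = 100.0

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"need 0 <= start < end, got [{self.start}, {self.end})")
        if self.source_fs <= 0:
            raise ValueError("source_fs must be positive")

    @property
    def duration_s(self) -> float:
        return (self.end - self.start) / self.source_fs

    @property
    def n_samples(self) -> int:
        return self.end - self.start


@dataclass(eq=False)
class LabeledSegment:
    """An extracted gesture segment with its class label."""

    data: ImuSequence
    label: str

    def __post_init__(self) -> None:
        if self.label not in GESTURE_CLASSES:
            raise ValueError(
                f"unknown label {self.label!r}; expected one of {GESTURE_CLASSES}"
            )


@dataclass(eq=False)
class GestureTemplate:
    """Per-class reference sequence built by element-wise averaging.

    ``channels`` holds the six averaged channels as an (m, 6) array, where m
    is the median length of the source segments. ``preprocessing`` is a
    fingerprint of the preprocessing applied to the source segments; it is
    checked at classification time so a template is never matched against a
    differently-conditioned input.
    """

    label: str
    channels: np.ndarray
    n_sources: int
    preprocessing: dict | None = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.channels, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 6 or arr.shape[0] < 1:
            raise ValueError(f"template channels must be (m>=1, 6), got {arr.shape}")
        if self.n_sources < 1:
            raise ValueError("n_sources must be >= 1")
        if self.label not in GESTURE_CLASSES:
            raise ValueError(f"unknown label {self.label!r}")
        self.channels = arr

    @property
    def m(self) -> int:
        return self.channels.shape[0]


# ---------------------------------------------------------------------------
# Time-series CSV
# ---------------------------------------------------------------------------

def read_timeseries_csv(path: str | Path, fs: float = 100.0) -> ImuSequence:
    """Read a 6-channel time-series CSV into an :class:`ImuSequence`.

    The header must name all six channel columns ``ax,ay,az,gx,gy,gz``; an
    optional leading time column (``t`` or ``time``) is accepted and ignored
    after a monotonicity check.
    """
    try:
        # the default float parser is fast but not round-trip exact
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty file, no header row") from exc

    cols = list(df.columns)
    if cols and cols[0] in ("t", "time"):
        tcol = pd.to_numeric(df[cols[0]], errors="coerce")
        if len(tcol) > 1 and not tcol.is_monotonic_increasing:
            raise FormatError(f"{path}: time column is not monotonically increasing")
        df = df.drop(columns=[cols[0]])

    missing = [c for c in CHANNELS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing channel column(s) {missing}")

    if len(df) == 0:
        return ImuSequence(np.empty((0, 6)), fs=fs)

    raw = df[list(CHANNELS)]
    arr = raw.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    bad = ~np.isfinite(arr)
    if bad.any():
        row, col = np.argwhere(bad)[0]
        raise ParseError(
            f"{path}: non-numeric value {raw.iat[row, col]!r} in column "
            f"{CHANNELS[col]!r} at data row {row + 1}"
        )
    return ImuSequence(arr, fs=fs)


def write_timeseries_csv(seq: ImuSequence, path: str | Path) -> None:
    """Write an :class:`ImuSequence` as CSV with full ``repr`` precision."""
    df = pd.DataFrame(seq.data, columns=list(CHANNELS))
    # repr is the shortest round-trip-exact decimal form of a float.
    df.to_csv(path, index=False, float_format=lambda v: repr(float(v)))


# ---------------------------------------------------------------------------
# Template JSON
# ---------------------------------------------------------------------------

def write_templates_json(
    templates: Iterable[GestureTemplate], path: str | Path
) -> None:
    """Serialize templates as a JSON map class-label -> template record.

    Floats are written with ``repr`` precision (17 significant digits), so a
    write/read round trip reproduces every channel value bit-exactly.
    """
    out: dict[str, dict] = {}
    for tpl in templates:
        if tpl.label in out:
            raise FormatError(f"duplicate template for class {tpl.label!r}")
        rec = {
            "m": int(tpl.m),
            "n_sources": int(tpl.n_sources),
            "channels": [tpl.channels[:, j].tolist() for j in range(6)],
        }
        if tpl.preprocessing is not None:
            rec["preprocessing"] = tpl.preprocessing
        out[tpl.label] = rec
    Path(path).write_text(json.dumps(out, indent=1))


def read_templates_json(path: str | Path) -> list[GestureTemplate]:
    """Read templates written by :func:`write_templates_json`.

    A file covering fewer than six classes is readable; completeness is the
    caller's concern (see ``TemplateSet.is_complete``). Duplicate class keys
    cannot survive JSON parsing, so they are detected on the raw text.
    """
    text = Path(path).read_text()

    seen: list[str] = []

    def _no_dupes(pairs):
        obj = {}
        for k, v in pairs:
            if k in obj:
                seen.append(k)
            obj[k] = v
        return obj

    data = json.loads(text, object_pairs_hook=_no_dupes)
    if seen:
        raise FormatError(f"duplicate class label(s) in {path}: {sorted(set(seen))}")

    templates = []
    for label, rec in data.items():
        chans = np.asarray(rec["channels"], dtype=float).T
        templates.append(
            GestureTemplate(
                label=label,
                channels=chans,
                n_sources=int(rec["n_sources"]),
                preprocessing=rec.get("preprocessing"),
            )
        )
    return templates


# ---------------------------------------------------------------------------
# Labeled-dataset directory layout (one CSV per segment + manifest)
# ---------------------------------------------------------------------------

def write_dataset_dir(
    segments: Sequence[LabeledSegment], directory: str | Path
) -> Path:
    """Write one CSV per segment plus a ``manifest.csv`` (columns file,label)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, seg in enumerate(segments):
        name = f"seg_{i:05d}_{seg.label}.csv"
        write_timeseries_csv(seg.data, directory / name)
        rows.append({"file": name, "label": seg.label})
    manifest = directory / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def read_dataset_dir(
    manifest: str | Path, fs: float = 100.0
) -> list[LabeledSegment]:
    """Read a labeled-segment dataset from its manifest CSV."""
    manifest = Path(manifest)
    df = pd.read_csv(manifest)
    for col in ("file", "label"):
        if col not in df.columns:
            raise FormatError(f"{manifest}: manifest missing column {col!r}")
    base = manifest.parent
    return [
        LabeledSegment(read_timeseries_csv(base / row.file, fs=fs), row.label)
        for row in df.itertuples()
    ]
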