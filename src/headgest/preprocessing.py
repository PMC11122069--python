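"""Signal conditioning: arctan normalization and sliding median filtering.

Two conditioning steps are available. The arctan map

    y(t) = arctan(x(t)) * 2 / pi

squashes every channel into the open interval (-1, 1) while preserving sign
and order; it is applied to all six channels before template building and
DTW matching so that no single high-amplitude channel dominates the
distance. The sliding median filter suppresses the sensor's salt-and-pepper
impulse noise before endpoint detection and matching.

The detection threshold is stated in physical units (rad/s), which is
inconsistent with thresholding arctan-compressed values, so by default the
detector runs on median-filtered, UN-normalized angular velocity and the
arctan map is reserved for the DTW path. Both choices are config flags.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigError
from .imu_io import ImuSequence, seconds_to_samples


@dataclass(frozen=True)
class PreprocessConfig:
    """Conditioning options applied before detection and matching.

    t_win_s : median-filter window length in seconds (default 0.3, the value
        a sweep over window lengths selects; 0.2 s is the other commonly
        used setting).
    normalize_for_dtw : apply the arctan map to all channels entering
        template building / DTW (default True).
    normalize_for_detection : apply the arctan map to the gyro channels
        before forming the detection magnitude (default False; see module
        docstring).
    """

    t_win_s: float = 0.3
    normalize_for_dtw: bool = True
    normalize_for_detection: bool = False

    def __post_init__(self) -> None:
        if self.t_win_s <= 0:
            raise ConfigError(f"t_win_s must be positive, got {self.t_win_s}")

    def fingerprint(self) -> dict:
        """Hashable summary of the conditioning applied to DTW inputs."""
        return {"t_win_s": self.t_win_s, "normalize": self.normalize_for_dtw}


def normalize_arctan(x: np.ndarray) -> np.ndarray:
    """Map a series through arctan(x) * 2/pi, into the open interval (-1, 1).

    The map is odd, strictly increasing, and bounded; 0 -> 0 and 1 -> 0.5.
    """
    arr = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("normalize_arctan requires finite input")
    return np.arctan(arr) * 2.0 / np.pi


def median_filter(x: np.ndarray, l: int) -> np.ndarray:
    """Sliding median filter of window length ``l`` with edge replication.

    Odd ``l``: output(t) is the median of the window of length l centered at
    t. Even ``l``: the window is ``x[t - l/2 : t + l/2 - 1]`` (inclusive) and
    the output is the mean of the two middle values. Boundaries are handled
    by replicating the first/last sample, which preserves length and avoids
    spurious onset transients that would corrupt start-time detection.
    """
    if l < 1:
        raise ValueError(f"window length must be >= 1, got {l}")
    arr = np.asarray(x, dtype=float)
    if arr.size == 0:
        raise ValueError("median_filter requires a non-empty series")
    if l == 1:
        return arr.copy()
    if l % 2 == 1:
        pad_left = pad_right = (l - 1) // 2
    else:
        pad_left, pad_right = l // 2, l // 2 - 1
    padded = np.pad(arr, (pad_left, pad_right), mode="edge")
    windows = np.lib.stride_tricks.sliding_window_view(padded, l)
    # np.median averages the two middle values for even l, as required.
    return np.median(windows, axis=1)


def filter_sequence(seq: ImuSequence, pp: PreprocessConfig) -> ImuSequence:
    """Median-filter every channel of ``seq`` with window ``t_win_s``."""
    l = seconds_to_samples(pp.t_win_s, seq.fs)
    out = np.column_stack([median_filter(seq.data[:, j], l) for j in range(6)])
    return ImuSequence(out, fs=seq.fs)


def preprocess_for_dtw(seq: ImuSequence, pp: PreprocessConfig) -> ImuSequence:
    """Condition a segment for template building / DTW matching.

    Median filtering is applied to the raw channels first; the arctan
    normalization (if enabled) comes after, so the filter operates in
    physical units.
    """
    out = filter_sequence(seq, pp)
    if pp.normalize_for_dtw:
        return ImuSequence(normalize_arctan(out.data), fs=out.fs)
    return out
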