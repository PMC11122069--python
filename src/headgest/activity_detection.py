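"""Endpoint (activity) detection for head movements.

The decision signal is the angular-velocity magnitude

    ang(t) = sqrt(gx(t)^2 + gy(t)^2 + gz(t)^2)

median-filtered to suppress impulse noise. A movement opens at the first
sample with ``ang(t) > ang_min`` and closes at the first sample ``t`` such
that the signal has stayed below ``ang_min`` for the whole trailing window
``[t - t_interval, t]`` — the quiet window must be long enough to bridge the
inter-peak trough of a biphasic (rotate-and-return) gesture, and it doubles
as the minimum separation between consecutive gestures. A closed candidate
is kept iff its duration lies strictly inside ``(t_min, t_max)``: the lower
bound rejects sharp noise spikes, the upper bound rejects abnormally long or
incomplete movements.

A literal two-point variant of the quiet-window rule — testing only the
samples at ``t`` and ``t - t_interval`` — is selectable for comparison via
``strict_quiet_window=False``; it can close a segment early when both probe
samples happen to fall in a trough.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import ConfigError, DetectionError
from .imu_io import ImuSequence, Segment, seconds_to_samples
from .preprocessing import PreprocessConfig, median_filter, normalize_arctan


@dataclass(frozen=True)
class DetectionConfig:
    """Thresholds for endpoint detection.

    ang_min : rad/s threshold on the angular-velocity magnitude (default 0.2).
    t_interval_s : quiet-window duration in seconds that must elapse below
        ang_min before a movement is declared ended (default 0.3; it must
        exceed the inter-peak trough of a biphasic gesture yet stay short
        enough to separate consecutive gestures).
    t_min_s, t_max_s : admissible duration bounds in seconds
        (defaults 0.6 and 2.5); kept durations satisfy t_min < d < t_max.
    strict_quiet_window : require the whole trailing window below threshold
        (default True) rather than only its two endpoint samples.
    """

    ang_min: float = 0.2
    t_interval_s: float = 0.3
    t_min_s: float = 0.6
    t_max_s: float = 2.5
    strict_quiet_window: bool = True

    def __post_init__(self) -> None:
        if self.ang_min <= 0:
            raise ConfigError(f"ang_min must be positive, got {self.ang_min}")
        if self.t_interval_s <= 0:
            raise ConfigError(f"t_interval_s must be positive, got {self.t_interval_s}")
        if not (0 < self.t_min_s < self.t_max_s):
            raise ConfigError(
                f"need 0 < t_min_s < t_max_s, got {self.t_min_s}, {self.t_max_s}"
            )


@dataclass(eq=False)
class SweepResult:
    """Outcome of a one-parameter detection sweep."""

    parameter: str
    grid: np.ndarray
    counts: np.ndarray
    matches: np.ndarray  # bool: count equals the expected count

    def correct_range(self) -> tuple[float, float] | None:
        """(lowest, highest) grid value achieving the expected count."""
        idx = np.nonzero(self.matches)[0]
        if idx.size == 0:
            return None
        return float(self.grid[idx[0]]), float(self.grid[idx[-1]])


def angular_magnitude(seq: ImuSequence) -> np.ndarray:
    """Euclidean norm of the three gyroscope channels, per sample (rad/s)."""
    if len(seq) == 0:
        raise ValueError("angular_magnitude requires a non-empty sequence")
    return np.linalg.norm(seq.gyro, axis=1)


def detection_signal(seq: ImuSequence, pp: PreprocessConfig) -> np.ndarray:
    """Median-filtered angular-velocity magnitude used by the detector."""
    gyro = seq.gyro
    if pp.normalize_for_detection:
        gyro = normalize_arctan(gyro)
    ang = np.linalg.norm(gyro, axis=1)
    l = seconds_to_samples(pp.t_win_s, seq.fs)
    return median_filter(ang, l)


def detect_segments(
    seq: ImuSequence, cfg: DetectionConfig, pp: PreprocessConfig
) -> list[Segment]:
    """Scan a stream left to right and return validated movement segments.

    Returned segments are pairwise disjoint, sorted, separated by at least
    ``t_interval`` of sub-threshold signal, and each has a duration strictly
    inside ``(t_min, t_max)``. While a segment is open, no nested start is
    considered; scanning resumes after the closing sample. A segment still
    open at the end of the stream is discarded (its end is unobserved).
    """
    w = seconds_to_samples(cfg.t_interval_s, seq.fs)
    if len(seq) < w:
        raise DetectionError(
            f"stream of {len(seq)} samples is shorter than the quiet window ({w})"
        )
    ang = detection_signal(seq, pp)
    below = ang < cfg.ang_min

    segments: list[Segment] = []
    open_ = False
    start = 0
    run = 0  # consecutive below-threshold samples ending at t
    for t in range(len(ang)):
        run = run + 1 if below[t] else 0
        if not open_:
            if ang[t] > cfg.ang_min:
                open_ = True
                start = t
        else:
            if cfg.strict_quiet_window:
                closed = run >= w + 1
            else:
                closed = below[t] and t - w >= 0 and below[t - w]
            if closed:
                dur = (t - start) / seq.fs
                if cfg.t_min_s < dur < cfg.t_max_s:
                    segments.append(Segment(start, t, seq.fs))
                open_ = False
    return segments


def extract(seq: ImuSequence, segments: list[Segment]) -> list[ImuSequence]:
    """Copy out the samples of each segment as independent sequences."""
    out = []
    for seg in segments:
        if seg.end > len(seq):
            raise IndexError(
                f"segment [{seg.start}, {seg.end}) out of bounds for length {len(seq)}"
            )
        out.append(ImuSequence(seq.data[seg.start : seg.end].copy(), fs=seq.fs))
    return out


_SWEEPABLE = ("ang_min", "t_interval_s", "t_min_s", "t_max_s", "t_win_s")


def sweep_parameter(
    stream: ImuSequence,
    expected_count: int,
    which: str,
    grid: np.ndarray,
    cfg: DetectionConfig,
    pp: PreprocessConfig,
) -> SweepResult:
    """Run detection once per grid value of one parameter and count segments.

    ``which`` may be any :class:`DetectionConfig` threshold or the filter
    window ``t_win_s``. Values whose detected count equals ``expected_count``
    are marked in the result.
    """
    if which not in _SWEEPABLE:
        raise ConfigError(f"unknown sweep parameter {which!r}; one of {_SWEEPABLE}")
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0 or not np.all(np.diff(grid) > 0):
        raise ConfigError("sweep grid must be non-empty and strictly increasing")

    counts = np.empty(grid.size, dtype=int)
    for i, v in enumerate(grid):
        if which == "t_win_s":
            n = len(detect_segments(stream, cfg, replace(pp, t_win_s=v)))
        else:
            n = len(detect_segments(stream, replace(cfg, **{which: v}), pp))
        counts[i] = n
    return SweepResult(
        parameter=which,
        grid=grid,
        counts=counts,
        matches=counts == expected_count,
    )
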