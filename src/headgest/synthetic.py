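"""Synthetic six-class head-gesture generator.

A head gesture is a rotate-and-return movement: the angular velocity on one
class-specific axis shows two opposing peaks (the rotation out and the
recovery), while the other gyro channels stay near zero. The generator
emulates exactly that structure:

* class -> axis: nod and tilt_up rotate about z (gz); shake_left and
  shake_right about x (gx); tilt_left and tilt_right about y (gy);
* within an axis the two classes differ by the sign of the first lobe:
  +1 for tilt_up, shake_left and tilt_left, -1 for their opposites (the
  sensor's sign convention per direction is arbitrary; only distinctness
  matters for classification, so the choice is fixed and documented here);
* the clean primary-channel waveform is a biphasic pulse
  A * [G(t; mu1, sigma) - G(t; mu2, sigma)] with Gaussian bumps at
  mu1 = 0.25 d and mu2 = 0.75 d (d = duration, sigma = 0.12 d), which
  integrates to ~0 — the head returns to where it started;
* a smooth monotone time-warp, per-channel Gaussian noise and sparse
  salt-and-pepper impulses model between-repetition and sensor variability;
* accelerometer channels carry a gravity constant (1 g on ay for the
  at-rest posture), a small class-correlated bump on the paired axis, and
  noise.

The clean pulse is evaluated on the mid-sample grid t_k = (k + 0.5)/fs so
that, with no warp, the biphasic waveform is exactly antisymmetric about the
segment midpoint.

All outputs are pure functions of (arguments, seed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .imu_io import (
    CHANNELS,
    GESTURE_CLASSES,
    ImuSequence,
    LabeledSegment,
    Segment,
)

#: Gyro channel carrying the movement, per class.
PRIMARY_AXIS: dict[str, str] = {
    "nod": "gz",
    "tilt_up": "gz",
    "shake_left": "gx",
    "shake_right": "gx",
    "tilt_left": "gy",
    "tilt_right": "gy",
}

#: Sign of the first angular-velocity lobe, per class.
FIRST_LOBE_SIGN: dict[str, int] = {
    "nod": -1,
    "tilt_up": +1,
    "shake_left": +1,
    "shake_right": -1,
    "tilt_left": +1,
    "tilt_right": -1,
}

#: Accelerometer channel paired with each gyro axis for the small
#: class-correlated linear-acceleration bump.
_PAIRED_ACCEL = {"gx": "ax", "gy": "ay", "gz": "az"}

#: Support threshold (rad/s) defining ground-truth intervals on the clean
#: (pre-noise) pulse; scoring a detector against noise-free truth means it
#: is never rewarded for fitting noise.
TRUTH_SUPPORT_THRESHOLD = 0.01

_GRAVITY_CHANNEL = "ay"  # upright at-rest posture: ~1 g on the y accel axis


@dataclass(frozen=True)
class GeneratorConfig:
    """Statistical structure of the synthetic gestures.

    Durations and amplitudes are uniform over their ranges; lobe width and
    the warp are expressed relative to the drawn duration, so short and long
    gestures share a shape family.
    """

    fs: float = 100.0
    duration_range: tuple[float, float] = (0.8, 1.6)  # s
    amplitude_range: tuple[float, float] = (0.8, 2.5)  # rad/s
    lobe_width_frac: float = 0.12  # sigma of each lobe, fraction of duration
    gyro_noise_sd: float = 0.05  # rad/s
    accel_noise_sd: float = 0.02  # g
    impulse_prob: float = 0.002  # per sample, per gyro channel
    impulse_magnitude: float = 3.0  # rad/s
    warp_strength: float = 0.15  # max relative slope deviation of the re-timing
    gap_range: tuple[float, float] = (0.8, 2.0)  # s, between stream gestures

    def __post_init__(self) -> None:
        for name in ("duration_range", "amplitude_range", "gap_range"):
            lo, hi = getattr(self, name)
            if not (0 < lo < hi):
                raise ValueError(f"{name} must be a positive non-degenerate range")
        if not 0 <= self.impulse_prob <= 1:
            raise ValueError("impulse_prob must lie in [0, 1]")
        if self.lobe_width_frac <= 0:
            raise ValueError("lobe_width_frac must be positive")
        if not 0 <= self.warp_strength < 1:
            raise ValueError("warp_strength must lie in [0, 1) to keep time monotone")


def biphasic_pulse(
    t: np.ndarray, duration: float, amplitude: float, sign: int, width_frac: float
) -> np.ndarray:
    """Clean rotate-and-return waveform: two opposing Gaussian lobes."""
    mu1, mu2 = 0.25 * duration, 0.75 * duration
    sigma = width_frac * duration
    g = lambda mu: np.exp(-((t - mu) ** 2) / (2.0 * sigma**2))
    return sign * amplitude * (g(mu1) - g(mu2))


def _gesture_arrays(
    label: str, cfg: GeneratorConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Return (data (n,6), clean primary-channel pulse (n,)) for one gesture.

    The random draws happen in a fixed order (duration, amplitude, warp,
    gyro noise, accel noise, impulses) so outputs are reproducible.
    """
    if label not in GESTURE_CLASSES:
        raise ValueError(f"unknown label {label!r}")
    d_drawn = rng.uniform(*cfg.duration_range)
    n = max(1, round(d_drawn * cfg.fs))
    d = n / cfg.fs  # effective duration on the sample grid
    amp = rng.uniform(*cfg.amplitude_range)
    warp = rng.uniform(-cfg.warp_strength, cfg.warp_strength)

    t = (np.arange(n) + 0.5) / cfg.fs
    # Smooth monotone re-timing tau(t) = t + w*(d/pi)*sin(pi t / d):
    # d tau/dt = 1 + w cos(pi t/d) > 0 for |w| < 1, and tau fixes 0 and d.
    tau = t + warp * (d / np.pi) * np.sin(np.pi * t / d)

    pulse = biphasic_pulse(tau, d, amp, FIRST_LOBE_SIGN[label], cfg.lobe_width_frac)

    data = np.zeros((n, 6))
    axis = PRIMARY_AXIS[label]
    data[:, CHANNELS.index(axis)] = pulse
    data[:, CHANNELS.index(_GRAVITY_CHANNEL)] += 1.0
    # Small class-correlated linear acceleration accompanying the rotation.
    accel_bump = 0.1 * FIRST_LOBE_SIGN[label] * np.exp(
        -((tau - 0.25 * d) ** 2) / (2.0 * (cfg.lobe_width_frac * d) ** 2)
    )
    data[:, CHANNELS.index(_PAIRED_ACCEL[axis])] += accel_bump

    data[:, 3:6] += rng.normal(0.0, cfg.gyro_noise_sd, size=(n, 3))
    data[:, 0:3] += rng.normal(0.0, cfg.accel_noise_sd, size=(n, 3))
    if cfg.impulse_prob > 0:
        mask = rng.random((n, 3)) < cfg.impulse_prob
        signs = rng.choice([-1.0, 1.0], size=(n, 3))
        data[:, 3:6] += mask * signs * cfg.impulse_magnitude
    return data, pulse


def generate_gesture(label: str, cfg: GeneratorConfig, seed) -> LabeledSegment:
    """One labeled gesture segment; deterministic for fixed (label, cfg, seed)."""
    rng = np.random.default_rng(seed)
    data, _ = _gesture_arrays(label, cfg, rng)
    return LabeledSegment(ImuSequence(data, fs=cfg.fs), label)


def _child_seeds(seed, n: int) -> np.ndarray:
    """Derive n deterministic per-item seeds (< 2**31) from a master seed."""
    return np.random.SeedSequence(seed).generate_state(n) & 0x7FFFFFFF


def generate_dataset(
    n_per_class: int, cfg: GeneratorConfig, seed
) -> list[LabeledSegment]:
    """A class-balanced corpus: n_per_class segments for each of the six classes."""
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    seeds = _child_seeds(seed, 6 * n_per_class)
    out = []
    i = 0
    for label in GESTURE_CLASSES:
        for _ in range(n_per_class):
            out.append(generate_gesture(label, cfg, int(seeds[i])))
            i += 1
    return out


def generate_stream(
    labels: list[str], cfg: GeneratorConfig, seed
) -> tuple[ImuSequence, list[tuple[Segment, str]]]:
    """A continuous recording: gestures embedded in a gravity-plus-noise
    quiet baseline, with gaps drawn from the configured range.

    Ground-truth intervals are the supra-:data:`TRUTH_SUPPORT_THRESHOLD`
    support of each clean (pre-noise) pulse, in stream sample coordinates.
    """
    if not labels:
        raise ValueError("labels must be non-empty")
    rng = np.random.default_rng(seed)
    chunks: list[np.ndarray] = []
    truth: list[tuple[Segment, str]] = []
    offset = 0

    def quiet(n: int) -> np.ndarray:
        base = np.zeros((n, 6))
        base[:, CHANNELS.index(_GRAVITY_CHANNEL)] = 1.0
        base[:, 3:6] += rng.normal(0.0, cfg.gyro_noise_sd, size=(n, 3))
        base[:, 0:3] += rng.normal(0.0, cfg.accel_noise_sd, size=(n, 3))
        if cfg.impulse_prob > 0:
            mask = rng.random((n, 3)) < cfg.impulse_prob
            signs = rng.choice([-1.0, 1.0], size=(n, 3))
            base[:, 3:6] += mask * signs * cfg.impulse_magnitude
        return base

    for label in labels:
        gap = max(1, round(rng.uniform(*cfg.gap_range) * cfg.fs))
        chunks.append(quiet(gap))
        offset += gap
        data, pulse = _gesture_arrays(label, cfg, rng)
        support = np.nonzero(np.abs(pulse) > TRUTH_SUPPORT_THRESHOLD)[0]
        truth.append(
            (
                Segment(offset + int(support[0]), offset + int(support[-1]) + 1, cfg.fs),
                label,
            )
        )
        chunks.append(data)
        offset += len(data)
    gap = max(1, round(rng.uniform(*cfg.gap_range) * cfg.fs))
    chunks.append(quiet(gap))

    return ImuSequence(np.vstack(chunks), fs=cfg.fs), truth
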