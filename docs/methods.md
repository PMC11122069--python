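# Methods

## Signal model and assumptions

A head gesture is modeled as a single rotate-and-return movement about one
body axis, recorded by a head-mounted 6-DoF IMU at a fixed sampling rate
`fs` (100 Hz default). The angular velocity on the movement axis therefore
shows two opposing peaks (out and back), and the Euclidean magnitude of the
three gyro channels, `ang(t)`, shows the same two-peak envelope regardless
of which gesture is performed — which is what makes a single scalar
threshold usable for endpoint detection across all six classes. The method
assumes the wearer is otherwise still (quiet baseline between gestures) and
never uses orientation estimation, magnetometer data, or gravity removal:
the constant gravity offset on the accelerometer channels cancels in the
pointwise DTW cost whenever both sequences carry it.

## Preprocessing

* **Median filter** (`preprocess.t_win_s`, default 0.3 s): sliding window
  with edge replication; odd windows take the middle value, even windows
  average the two middle values. Edge replication preserves length and
  avoids onset transients that a zero-padded filter would inject exactly
  where start times are measured. 0.3 s is the window a sweep over filter
  lengths selects; 0.2 s is the other defensible setting and is one config
  key away. A window much longer than ~0.4 s starts eating into the gesture
  lobes themselves.
* **Arctan normalization** `y = arctan(x)·2/π`: odd, strictly increasing,
  bounded in (−1, 1). Applied to all six channels *after* filtering and
  *only* on the template/DTW path. The detector thresholds the filtered,
  un-normalized magnitude, because `ang_min` is stated in physical rad/s
  and arctan compression would silently rescale it
  (arctan(0.2)·2/π ≈ 0.126). Both placements are selectable
  (`preprocess.normalize_for_detection`) for sensitivity experiments.

## Endpoint detection

Parameters (`detect.*`): `ang_min` = 0.2 rad/s, `t_interval_s` = 0.3 s,
`t_min_s` = 0.6 s, `t_max_s` = 2.5 s. All are converted to samples once at
config load.

A segment opens at the first sample with `ang(t) > ang_min`; while open, no
nested start is considered. It closes at the first `t` whose whole trailing
window `[t − t_interval, t]` is sub-threshold; testing the *whole* window
(rather than only its two endpoint samples) is what guarantees the quiet
really is a gesture boundary and not the mid-gesture trough — the two-point
variant remains available (`detect.strict_quiet_window: false`) and is
covered by the same brute-force oracle tests. The closing sample is the
exclusive segment end, so segments carry up to `t_interval` of trailing
quiet, and the duration gate `t_min < (end − start)/fs < t_max` is applied
to exactly that duration. A segment still open at end-of-stream is
discarded: its end was never observed.

`t_interval` trades off two failure modes: too short and the detector
splits one gesture at its trough (the trough of the default synthetic
gestures stays sub-threshold for up to ~0.26 s in the worst corner of the
parameter ranges); too long and consecutive gestures merge (gaps start at
0.8 s). 0.3 s sits between the two with margin on both sides.

`t_min` = 0.6 s and `t_max` = 2.5 s bracket plausible deliberate head
movements; the duration gate is an open interval, so a filtered pulse whose
above-threshold extent plus trailing quiet is exactly 0.6 s is rejected.

## Templates and DTW

Template length `m` is the median of the training-segment lengths; an even
count averages the two middle lengths and a half-sample result rounds down
(`m` must index a real position; rounding down also slightly favors the
positions averaged by *all* sources). Position `i` averages only the
segments of length ≥ i, so late positions of the template are supported by
fewer segments — visible as increased template noise near `m` when
durations vary widely.

The pointwise cost is the Euclidean distance in 6-space (a squared variant
is config-selectable). The cumulative recursion uses +∞ out-of-grid
neighbours; ties in its min prefer diagonal, then vertical, then horizontal
steps, which affects only the reported path, never the distance. No
Sakoe–Chiba band or length cap is imposed: segments are bounded by
`t_max · fs` = 250 samples, so the full n×m grid costs microseconds.

Classification uses the unnormalized `r(n, m)`. The per-step normalized
value `r(n, m)/k` is always computed and can be selected
(`dtw.normalize_by_path_length`); it matters when template lengths differ
strongly across classes, and under heavy noise (see Limitations). Exact
distance ties break to the lexicographically smallest label, for
determinism. Each template stores a fingerprint of the preprocessing used
to build it, and `classify` refuses inputs conditioned differently.

## Synthetic data generator

The generator emulates the structure the classifier exploits, nothing more:

| parameter | default | meaning |
|---|---|---|
| duration | U(0.8, 1.6) s | gesture length |
| amplitude | U(0.8, 2.5) rad/s | peak angular velocity |
| lobe width σ | 0.12 × duration | width of each Gaussian lobe |
| gyro / accel noise sd | 0.05 rad/s / 0.02 g | per-sample Gaussian noise |
| impulse prob / magnitude | 0.002 / 3 rad/s | salt-and-pepper outliers |
| warp strength | 0.15 | max relative slope of the smooth re-timing |
| stream gap | U(0.8, 2.0) s | quiet time between gestures |

Class → axis: nod and tilt-up rotate about z, shakes about x, lateral tilts
about y; the two classes per axis differ in the sign of the first lobe
(+ for tilt_up / shake_left / tilt_left). The per-direction sign convention
is not physically meaningful — only distinctness matters — so it is fixed
arbitrarily and documented in `headgest.synthetic`. The clean pulse
`A·[G(t; 0.25d, σ) − G(t; 0.75d, σ)]` is evaluated on the mid-sample grid
`(k + 0.5)/fs`, which makes it exactly antisymmetric about the midpoint, so
the zero-noise pulse integrates to zero at float precision (the head ends
where it started). The monotone re-timing `τ(t) = t + w·(d/π)·sin(πt/d)`
fixes both endpoints and keeps `dτ/dt > 0` for |w| < 1. Gravity sits on the
`ay` channel (upright posture). Ground-truth stream intervals are the
supra-0.01 rad/s support of the *clean* pulse: a detector scored against
noise-free truth is never rewarded for fitting noise.

Amplitude/duration statistics of real head gestures beyond these bounds are
assumptions, not measurements. What the passing tests show is that the
pipeline is correct and separates the six classes under this signal family;
they do not show robustness to sensor drift, gesture hesitations,
non-gesture head motion (walking, talking), or between-subject variability,
none of which the generator emulates.

## Numerical and testing choices

* Durations in seconds convert to samples via `max(1, round(t·fs))` (0 for
  t = 0), at one single point, so no threshold drifts between stages.
* The DTW recursion is cross-checked two independent ways: exhaustive
  enumeration of every monotone warp path on small grids, and a separately
  written textbook DP with an infinite border. The detector's scan is
  cross-checked against a literal per-sample re-test of the three rules.
* Test problem sizes (corpus of 40 segments per class for the headline
  experiment, 100 oracle streams of ≤ 2000 samples, 500 random DTW pairs)
  are chosen so the whole suite runs in seconds while the checks remain
  exhaustive where exhaustiveness is the point.

## Known limitations

* Heavy gyro noise (sd ≳ 2 rad/s, comparable to the pulse amplitudes)
  degrades accuracy, and the misclassifications scatter toward classes with
  *shorter templates* rather than toward the same-axis sibling: with every
  pointwise cost inflated by noise, the unnormalized `r(n, m)` grows with
  alignment length, biasing the argmin toward small `m`. Path-length
  normalization removes that bias at the cost of departing from the
  operative distance definition.
* Start-anchored element-wise averaging smears the second lobe across
  sources of different durations; DTW absorbs the misalignment at match
  time, but the template itself is not a barycenter in the DTW sense.
* Batch detection only: the scan is causal in structure but the
  implementation processes complete recordings, not streams.
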