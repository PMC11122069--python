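"""Template construction and DTW minimum-distance classification.

Templates
---------
For one gesture class with training segments S^1 ... S^l of lengths
collected in S_len, the template is T = (t_1, ..., t_m) with m the median of
S_len (an even count of lengths averages the two middle values; the half-way
case rounds down so m indexes a real sample position). Element-wise,

    t_i = mean over j of S^j_i,    counting only segments with length >= i,

applied to each of the six channels independently. Segments are
start-anchored: index 0 is the detected movement start.

DTW
---
For a test sequence S (length n) and template T (length m), the pointwise
cost d(s_i, t_j) is the Euclidean distance between the two 6-vectors, and
the cumulative distance obeys

    r(i, j) = d(s_i, t_j) + min(r(i-1, j), r(i-1, j-1), r(i, j-1))

with out-of-grid neighbours treated as +inf, so r(1,1) = d(s_1, t_1). The
classifier labels a segment with the class whose template minimizes the
unnormalized warp-path distance r(n, m); the per-path-step normalized value
r(n, m)/k is also computed and may be selected instead. The recovered warp
path runs from the (1,1) corner to the (n,m) corner, moves by steps in
{(1,0), (1,1), (0,1)}, and has length k with max(m, n) <= k <= m + n - 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .errors import ConfigError
from .imu_io import (
    GESTURE_CLASSES,
    GestureTemplate,
    ImuSequence,
    LabeledSegment,
    read_templates_json,
    write_templates_json,
)
from .preprocessing import PreprocessConfig, preprocess_for_dtw


@dataclass(frozen=True)
class DtwConfig:
    """Distance options for matching.

    normalize_by_path_length : classify on r(n,m)/k instead of r(n,m)
        (default False — the unnormalized cumulative distance is the
        operative quantity).
    squared_pointwise : use the squared Euclidean pointwise cost instead of
        the Euclidean distance (default False).
    """

    normalize_by_path_length: bool = False
    squared_pointwise: bool = False


@dataclass(eq=False)
class DtwResult:
    """Full output of one DTW alignment."""

    distance_matrix: np.ndarray  # (n, m) pointwise costs d
    cumulative: np.ndarray  # (n, m) cumulative costs r
    path: list[tuple[int, int]]  # 0-based (i, j) pairs, (0,0) .. (n-1,m-1)
    distance: float  # r(n, m)
    normalized_distance: float  # r(n, m) / k

    @property
    def k(self) -> int:
        return len(self.path)


@dataclass(eq=False)
class TemplateSet:
    """Mapping class label -> template; complete when all six are present."""

    templates: dict[str, GestureTemplate]

    def __init__(self, templates: Iterable[GestureTemplate] | Mapping[str, GestureTemplate]):
        if isinstance(templates, Mapping):
            templates = templates.values()
        d: dict[str, GestureTemplate] = {}
        for tpl in templates:
            if tpl.label in d:
                raise ConfigError(f"duplicate template for class {tpl.label!r}")
            d[tpl.label] = tpl
        self.templates = d

    @property
    def is_complete(self) -> bool:
        return set(self.templates) == set(GESTURE_CLASSES)

    @property
    def fingerprint(self) -> dict | None:
        for tpl in self.templates.values():
            return tpl.preprocessing
        return None

    def __getitem__(self, label: str) -> GestureTemplate:
        return self.templates[label]

    def __iter__(self):
        return iter(self.templates.values())

    def __len__(self) -> int:
        return len(self.templates)

    def save(self, path: str | Path) -> None:
        write_templates_json(self.templates.values(), path)

    @classmethod
    def load(cls, path: str | Path) -> "TemplateSet":
        return cls(read_templates_json(path))


def _as_channels(x) -> np.ndarray:
    if isinstance(x, ImuSequence):
        return x.data
    if isinstance(x, GestureTemplate):
        return x.channels
    return np.asarray(x, dtype=float)


def median_template_length(lengths: Sequence[int]) -> int:
    """Median of the segment lengths; an even count averages the two middle
    values and a half-way result rounds down (m must index a sample)."""
    med = float(np.median(np.asarray(lengths)))
    return int(np.floor(med))


def build_template(segments: Sequence[ImuSequence], label: str) -> GestureTemplate:
    """Average start-anchored segments element-wise into a class template.

    Position i of each channel averages only the segments long enough to
    reach i; positions beyond a segment's length simply do not count it.
    """
    if len(segments) == 0:
        raise ValueError("build_template requires at least one segment")
    lengths = [len(s) for s in segments]
    m = median_template_length(lengths)
    max_len = max(lengths)
    sums = np.zeros((max_len, 6))
    counts = np.zeros(max_len)
    for seg in segments:
        arr = _as_channels(seg)
        sums[: len(arr)] += arr
        counts[: len(arr)] += 1
    avg = sums[:m] / counts[:m, None]
    return GestureTemplate(label=label, channels=avg, n_sources=len(segments))


def build_template_set(
    train: Sequence[LabeledSegment], pp: PreprocessConfig
) -> TemplateSet:
    """Preprocess training segments and build one template per class present.

    Each template records the preprocessing fingerprint so that
    :func:`classify` can refuse differently-conditioned inputs.
    """
    by_label: dict[str, list[ImuSequence]] = {}
    for seg in train:
        by_label.setdefault(seg.label, []).append(preprocess_for_dtw(seg.data, pp))
    templates = []
    for label in sorted(by_label):
        tpl = build_template(by_label[label], label)
        tpl.preprocessing = pp.fingerprint()
        templates.append(tpl)
    return TemplateSet(templates)


def distance_matrix(S, T, squared: bool = False) -> np.ndarray:
    """Pairwise 6-space Euclidean costs between samples of S and positions of T."""
    a, b = _as_channels(S), _as_channels(T)
    if a.ndim != 2 or b.ndim != 2 or a.shape[1] != b.shape[1]:
        raise ValueError(
            f"channel-count mismatch: {a.shape} vs {b.shape}"
        )
    if a.shape[0] == 0 or b.shape[0] == 0:
        raise ValueError("distance_matrix requires non-empty inputs")
    metric = "sqeuclidean" if squared else "euclidean"
    return cdist(a, b, metric=metric)


def dtw(S, T, cfg: DtwConfig | None = None) -> DtwResult:
    """Align S against T and return distance, cumulative grid and warp path.

    No global path band or sequence-length cap is applied: segments are at
    most a few hundred samples, so the full n x m grid is cheap. Ties in the
    recursion's min are resolved preferring the diagonal step, then the
    vertical (advance in S), then the horizontal — this affects only the
    reported path, never the distance.
    """
    cfg = cfg or DtwConfig()
    D = distance_matrix(S, T, squared=cfg.squared_pointwise)
    n, m = D.shape

    r = np.empty((n, m))
    r[0, 0] = D[0, 0]
    r[0, 1:] = D[0, 0] + np.cumsum(D[0, 1:])
    r[1:, 0] = D[0, 0] + np.cumsum(D[1:, 0])
    # Row-wise DP; plain Python lists beat ndarray scalar indexing here.
    prev = r[0].tolist()
    Dl = D.tolist()
    for i in range(1, n):
        row_d = Dl[i]
        cur = [r[i, 0]]
        last = cur[0]
        for j in range(1, m):
            up = prev[j]
            diag = prev[j - 1]
            best = diag if diag <= up else up
            if last < best:
                best = last
            last = row_d[j] + best
            cur.append(last)
        r[i] = cur
        prev = cur

    # Backtrack with the same tie preference: diagonal, vertical, horizontal.
    path = [(n - 1, m - 1)]
    i, j = n - 1, m - 1
    while (i, j) != (0, 0):
        if i == 0:
            j -= 1
        elif j == 0:
            i -= 1
        else:
            diag, up, left = r[i - 1, j - 1], r[i - 1, j], r[i, j - 1]
            if diag <= up and diag <= left:
                i, j = i - 1, j - 1
            elif up <= left:
                i -= 1
            else:
                j -= 1
        path.append((i, j))
    path.reverse()

    dist = float(r[n - 1, m - 1])
    return DtwResult(
        distance_matrix=D,
        cumulative=r,
        path=path,
        distance=dist,
        normalized_distance=dist / len(path),
    )


def classify(
    seq: ImuSequence,
    templates: TemplateSet,
    pp: PreprocessConfig,
    cfg: DtwConfig | None = None,
) -> tuple[str, dict[str, float]]:
    """Label a raw segment by minimum DTW distance over the six templates.

    The segment is conditioned with ``pp`` (which must match the fingerprint
    stored in the templates) and compared against every template; the label
    with the smallest distance wins, exact ties going to the
    lexicographically smallest label.
    """
    cfg = cfg or DtwConfig()
    if not templates.is_complete:
        raise ConfigError(
            f"incomplete template set: have {sorted(templates.templates)}"
        )
    fp = templates.fingerprint
    if fp is not None and fp != pp.fingerprint():
        raise ConfigError(
            f"preprocessing mismatch: templates built with {fp}, "
            f"classifying with {pp.fingerprint()}"
        )
    conditioned = preprocess_for_dtw(seq, pp)
    distances: dict[str, float] = {}
    for label in sorted(templates.templates):
        res = dtw(conditioned, templates[label], cfg)
        distances[label] = (
            res.normalized_distance if cfg.normalize_by_path_length else res.distance
        )
    best = min(sorted(distances), key=distances.__getitem__)
    return best, distances
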