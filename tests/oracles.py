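"""Independent brute-force reference implementations used only by tests.

Each oracle literally re-evaluates the defining rule at every position,
with no shared code or vectorization tricks from the package, so agreement
is meaningful.
"""

from __future__ import annotations

import math

import numpy as np


def brute_median_filter(x, l: int) -> list[float]:
    """Window-by-window evaluation of the sliding median with edge replication.

    Odd l: window centered at t. Even l: window x[t - l/2 .. t + l/2 - 1],
    output the average of the two middle values.
    """
    x = list(map(float, x))
    n = len(x)
    out = []
    for t in range(n):
        if l % 2 == 1:
            lo, hi = t - (l - 1) // 2, t + (l - 1) // 2
        else:
            lo, hi = t - l // 2, t + l // 2 - 1
        window = sorted(x[min(max(k, 0), n - 1)] for k in range(lo, hi + 1))
        mid = len(window) // 2
        if len(window) % 2 == 1:
            out.append(window[mid])
        else:
            out.append(0.5 * (window[mid - 1] + window[mid]))
    return out


def brute_detect(ang, fs: float, ang_min: float, t_interval_s: float,
                 t_min_s: float, t_max_s: float, strict: bool = True):
    """Literal left-to-right scan of the start/end/validity rules.

    Opens at ang(t) > ang_min; closes at the first t whose whole trailing
    window [t - w, t] is below ang_min (strict) or whose two probe samples
    t and t - w are below (literal two-point variant); keeps a candidate iff
    t_min < duration < t_max.
    """
    w = max(1, round(t_interval_s * fs))
    segs = []
    open_ = False
    start = 0
    for t in range(len(ang)):
        if not open_:
            if ang[t] > ang_min:
                open_ = True
                start = t
        else:
            if strict:
                closed = t - w >= 0 and all(
                    ang[u] < ang_min for u in range(t - w, t + 1)
                )
            else:
                closed = ang[t] < ang_min and t - w >= 0 and ang[t - w] < ang_min
            if closed:
                dur = (t - start) / fs
                if t_min_s < dur < t_max_s:
                    segs.append((start, t))
                open_ = False
    return segs


def dtw_min_over_all_paths(D: np.ndarray) -> float:
    """Exhaustive minimization of the summed cost over every monotone,
    contiguous warp path from the (1,1) corner to the (n,m) corner."""
    n, m = D.shape
    best = [math.inf]

    def rec(i: int, j: int, acc: float) -> None:
        acc += D[i, j]
        if i == n - 1 and j == m - 1:
            if acc < best[0]:
                best[0] = acc
            return
        if i + 1 < n and j + 1 < m:
            rec(i + 1, j + 1, acc)
        if i + 1 < n:
            rec(i + 1, j, acc)
        if j + 1 < m:
            rec(i, j + 1, acc)

    rec(0, 0, 0.0)
    return best[0]


def reference_dtw_distance(a, b) -> float:
    """Textbook DP with an infinite border row/column; independent of the
    package's row-list implementation and backtracking."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n, m = len(a), len(b)
    inf = math.inf
    r = [[inf] * (m + 1) for _ in range(n + 1)]
    r[0][0] = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            d = math.dist(a[i - 1], b[j - 1])
            r[i][j] = d + min(r[i - 1][j], r[i - 1][j - 1], r[i][j - 1])
    return r[n][m]
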