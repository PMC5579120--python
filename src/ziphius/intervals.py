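"""Half-open UTC interval arithmetic shared by detection, fusion and
exposure: union, intersection, subtraction and total duration.

Intervals are (start, end) pairs of pandas Timestamps with start < end;
lists need not be sorted or disjoint on input. All outputs are sorted,
disjoint, half-open [start, end).
"""

from __future__ import annotations

import pandas as pd

__all__ = ["normalize", "union", "intersect", "subtract",
           "total_seconds", "overlap_seconds"]


def _ts(x):
    t = pd.Timestamp(x)
    return t.tz_localize("UTC") if t.tzinfo is None else t


def normalize(intervals):
    """Sort, drop empties, and merge overlapping/touching intervals."""
    ivs = sorted((( _ts(a), _ts(b)) for a, b in intervals if _ts(a) < _ts(b)))
    out = []
    for a, b in ivs:
        if out and a <= out[-1][1]:
            if b > out[-1][1]:
                out[-1] = (out[-1][0], b)
        else:
            out.append((a, b))
    return out


def union(*interval_lists):
    merged = []
    for lst in interval_lists:
        merged.extend(lst)
    return normalize(merged)


def intersect(a, b):
    a = normalize(a)
    b = normalize(b)
    out = []
    i = j = 0
    while i < len(a) and j < len(b):
        lo = max(a[i][0], b[j][0])
        hi = min(a[i][1], b[j][1])
        if lo < hi:
            out.append((lo, hi))
        if a[i][1] <= b[j][1]:
            i += 1
        else:
            j += 1
    return out


def subtract(a, b):
    """Intervals of ``a`` not covered by ``b``."""
    a = normalize(a)
    b = normalize(b)
    out = []
    j = 0
    for lo, hi in a:
        cur = lo
        while j < len(b) and b[j][1] <= cur:
            j += 1
        k = j
        while k < len(b) and b[k][0] < hi:
            if b[k][0] > cur:
                out.append((cur, b[k][0]))
            cur = max(cur, b[k][1])
            k += 1
        if cur < hi:
            out.append((cur, hi))
    return out


def total_seconds(intervals):
    return float(sum((b - a).total_seconds() for a, b in normalize(intervals)))


def overlap_seconds(interval, others):
    """Seconds of ``interval`` covered by the union of ``others``."""
    return total_seconds(intersect([interval], others))
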