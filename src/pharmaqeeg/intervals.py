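"""Half-open interval algebra on [start, end) pairs in seconds.

All operations return sorted, merged, non-overlapping interval lists and are
idempotent under re-application.
"""

from __future__ import annotations

__all__ = ["merge", "complement", "subtract", "intersect", "total_length", "clip"]


def merge(intervals):
    """Sort and merge overlapping or touching [start, end) intervals."""
    ivs = sorted((float(s), float(e)) for s, e in intervals if e > s)
    out = []
    for s, e in ivs:
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def clip(intervals, extent):
    """Clip intervals to [extent[0], extent[1])."""
    lo, hi = extent
    return merge(
        (max(s, lo), min(e, hi)) for s, e in intervals if e > lo and s < hi
    )


def complement(intervals, extent):
    """Intervals of [extent[0], extent[1]) not covered by ``intervals``."""
    lo, hi = extent
    out = []
    cursor = lo
    for s, e in clip(intervals, extent):
        if s > cursor:
            out.append((cursor, s))
        cursor = max(cursor, e)
    if cursor < hi:
        out.append((cursor, hi))
    return out


def subtract(a, b):
    """Portions of intervals ``a`` not covered by intervals ``b``."""
    a = merge(a)
    b = merge(b)
    out = []
    for s, e in a:
        cursor = s
        for bs, be in b:
            if be <= cursor or bs >= e:
                continue
            if bs > cursor:
                out.append((cursor, bs))
            cursor = max(cursor, be)
            if cursor >= e:
                break
        if cursor < e:
            out.append((cursor, e))
    return out


def intersect(a, b):
    """Intervals covered by both ``a`` and ``b``."""
    a, b = merge(a), merge(b)
    out = []
    i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if e > s:
            out.append((s, e))
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return out


def total_length(intervals) -> float:
    return sum(e - s for s, e in merge(intervals))
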