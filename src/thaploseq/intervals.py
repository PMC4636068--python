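"""Half-open interval arithmetic on a single sequence.

All intervals are 0-based half-open ``(start, end)`` tuples. "Merged"
means sorted, non-overlapping and non-adjacent; every public function
returns merged output.
"""

from __future__ import annotations

from typing import Iterable, List, Tuple

Interval = Tuple[int, int]


def merge(intervals: Iterable[Interval]) -> List[Interval]:
    """Sort and coalesce overlapping or adjacent intervals; drop empty ones."""
    ivs = sorted((int(s), int(e)) for s, e in intervals if e > s)
    out: List[Interval] = []
    for s, e in ivs:
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def clip(intervals: Iterable[Interval], lo: int, hi: int) -> List[Interval]:
    """Intersect each interval with [lo, hi); drops emptied intervals."""
    return merge((max(s, lo), min(e, hi)) for s, e in intervals)


def subtract(intervals: Iterable[Interval], holes: Iterable[Interval]) -> List[Interval]:
    """Set difference ``intervals \\ holes``; both inputs may be unmerged."""
    ivs = merge(intervals)
    hs = merge(holes)
    out: List[Interval] = []
    j = 0
    for s, e in ivs:
        cur = s
        while j < len(hs) and hs[j][1] <= cur:
            j += 1
        k = j
        while k < len(hs) and hs[k][0] < e:
            hs_s, hs_e = hs[k]
            if hs_s > cur:
                out.append((cur, hs_s))
            cur = max(cur, hs_e)
            if hs_e >= e:
                break
            k += 1
        if cur < e:
            out.append((cur, e))
    return out


def total_length(intervals: Iterable[Interval]) -> int:
    return sum(e - s for s, e in merge(intervals))


def contains(intervals: List[Interval], pos: int) -> bool:
    """Membership test against a merged interval list (binary search)."""
    import bisect

    i = bisect.bisect_right(intervals, (pos, float("inf"))) - 1
    return i >= 0 and intervals[i][0] <= pos < intervals[i][1]


def overlaps_any(intervals: List[Interval], start: int, end: int) -> bool:
    """True if [start, end) intersects any merged interval."""
    import bisect

    i = bisect.bisect_right(intervals, (start, float("inf"))) - 1
    if i >= 0 and intervals[i][1] > start:
        return True
    return i + 1 < len(intervals) and intervals[i + 1][0] < end
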