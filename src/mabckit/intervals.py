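"""Half-open interval arithmetic on sorted ``(start, end)`` float pairs.

Haplotypes are represented as sorted, disjoint lists of donor-origin
intervals in centimorgan space, so meiosis and segment queries reduce to
the set operations below.  All functions expect and return lists of
``(start, end)`` tuples with ``start < end``, sorted, non-overlapping.
"""

from __future__ import annotations

from typing import Iterable, Sequence

Interval = tuple[float, float]


def merge(ivs: Iterable[Interval]) -> list[Interval]:
    """Sort and coalesce overlapping or touching intervals."""
    out: list[Interval] = []
    for s, e in sorted(ivs):
        if e <= s:
            continue
        if out and s <= out[-1][1]:
            if e > out[-1][1]:
                out[-1] = (out[-1][0], e)
        else:
            out.append((s, e))
    return out


def clip(ivs: Sequence[Interval], lo: float, hi: float) -> list[Interval]:
    """Restrict intervals to the window ``[lo, hi)``."""
    out = []
    for s, e in ivs:
        s2, e2 = max(s, lo), min(e, hi)
        if s2 < e2:
            out.append((s2, e2))
    return out


def union(*interval_lists: Sequence[Interval]) -> list[Interval]:
    flat: list[Interval] = []
    for ivs in interval_lists:
        flat.extend(ivs)
    return merge(flat)


def intersect(a: Sequence[Interval], b: Sequence[Interval]) -> list[Interval]:
    """Intersection of two sorted disjoint interval lists (linear sweep)."""
    out: list[Interval] = []
    i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if s < e:
            out.append((s, e))
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return out


def subtract(a: Sequence[Interval], b: Sequence[Interval]) -> list[Interval]:
    """Set difference a \\ b."""
    out: list[Interval] = []
    b = merge(b)
    for s, e in a:
        cur = s
        for bs, be in b:
            if be <= cur or bs >= e:
                continue
            if bs > cur:
                out.append((cur, bs))
            cur = max(cur, be)
            if cur >= e:
                break
        if cur < e:
            out.append((cur, e))
    return out


def total_length(ivs: Iterable[Interval]) -> float:
    return sum(e - s for s, e in ivs)


def contains(ivs: Sequence[Interval], x: float) -> bool:
    """Membership of a point (half-open convention)."""
    for s, e in ivs:
        if s <= x < e:
            return True
        if s > x:
            break
    return False
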