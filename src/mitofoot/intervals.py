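"""Interval algebra on a circular genome.

All intervals are 0-based half-open ``(start, end)`` on a circle of length
``L``.  A non-wrapping interval has ``0 <= start < end <= L``; an interval
that crosses the origin is stored with ``end < start`` and denotes
``[start, L) ∪ [0, end)``.  ``(0, L)`` denotes the full circle.  Zero-length
intervals are not representable.

Overlap means sharing at least one base; half-open adjacency (``[10,30)``
next to ``[30,50)``) is *not* overlap.
"""

from __future__ import annotations

from typing import Iterable, Sequence

Interval = tuple[int, int]


def interval_length(ivl: Interval, L: int) -> int:
    """Number of bases covered by ``ivl`` on a circle of length ``L``."""
    start, end = ivl
    if start == 0 and end == L:
        return L
    n = (end - start) % L
    if n == 0:
        raise ValueError(f"zero-length interval {ivl!r}")
    return n


def normalize(ivl: Interval, L: int) -> Interval:
    """Map an interval to canonical form: start in [0, L), end in (0, L]."""
    start, end = ivl
    n = interval_length(ivl, L)
    start %= L
    if n == L:
        return (0, L)
    e = start + n
    return (start, e if e <= L else e - L)


def rotate_interval(ivl: Interval, k: int, L: int) -> Interval:
    """Shift an interval by ``k`` bases around the circle."""
    n = interval_length(ivl, L)
    return normalize(((ivl[0] + k) % L, (ivl[0] + k + n) % L), L)


def overlaps(a: Interval, b: Interval, L: int) -> bool:
    """True iff the two intervals share at least one base on the circle."""
    la, lb = interval_length(a, L), interval_length(b, L)
    if la == L or lb == L:
        return True
    sa, sb = a[0] % L, b[0] % L
    return ((sb - sa) % L) < la or ((sa - sb) % L) < lb


def circular_gap(a: Interval, b: Interval, L: int) -> int:
    """Smallest number of bases strictly between two intervals (0 if they overlap)."""
    if overlaps(a, b, L):
        return 0
    ea = (a[0] + interval_length(a, L)) % L
    eb = (b[0] + interval_length(b, L)) % L
    return min((b[0] % L - ea) % L, (a[0] % L - eb) % L)


def hull(a: Interval, b: Interval, L: int) -> Interval:
    """Union of two *overlapping* intervals (a single contiguous interval)."""
    la, lb = interval_length(a, L), interval_length(b, L)
    sa, sb = a[0] % L, b[0] % L
    d_ab = (sb - sa) % L  # offset of b's start inside/after a
    d_ba = (sa - sb) % L
    starts_in_a = d_ab < la or la == L
    starts_in_b = d_ba < lb or lb == L
    if not (starts_in_a or starts_in_b):
        raise ValueError("hull of non-overlapping intervals")
    if starts_in_a and starts_in_b:
        # mutual containment of starts: the union wraps the whole circle
        # unless one interval contains the other.
        if d_ab + lb <= la:
            return normalize(a, L)
        if d_ba + la <= lb:
            return normalize(b, L)
        return (0, L)
    if starts_in_a:
        return normalize((sa, sa + max(la, d_ab + lb)), L) if max(la, d_ab + lb) < L else (0, L)
    return normalize((sb, sb + max(lb, d_ba + la)), L) if max(lb, d_ba + la) < L else (0, L)


def merge_intervals(ivls: Iterable[Interval], L: int) -> list[Interval]:
    """Transitive closure of >=1-base overlap; result is sorted, non-overlapping.

    Adjacent-but-disjoint intervals are kept separate.
    """
    spans = []  # (start in [0,L), absolute end = start + length)
    for ivl in ivls:
        n = interval_length(ivl, L)
        if n == L:
            return [(0, L)]
        s = ivl[0] % L
        spans.append((s, s + n))
    if not spans:
        return []
    spans.sort()
    merged: list[list[int]] = [list(spans[0])]
    for s, e in spans[1:]:
        if s < merged[-1][1]:  # strict: adjacency does not merge
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    # after a start-sorted sweep only the final cluster can extend past L;
    # fold its wrapped part onto the clusters at the origin
    if merged[-1][1] > L:
        wrap_end = merged[-1][1] - L
        absorbed = False
        while len(merged) > 1 and merged[0][0] < wrap_end:
            head_s, head_e = merged.pop(0)
            wrap_end = max(wrap_end, head_e)
            absorbed = True
        if absorbed:
            merged[-1][1] = wrap_end + L
        if merged[-1][1] - merged[-1][0] >= L:
            return [(0, L)]
    return sorted(normalize((s, e if e <= L else e - L), L) for s, e in merged)


def dilate(ivl: Interval, pad: int, L: int) -> Interval:
    """Expand an interval by ``pad`` bases on each side (capped at the full circle)."""
    n = interval_length(ivl, L) + 2 * pad
    if n >= L:
        return (0, L)
    return normalize(((ivl[0] - pad) % L, (ivl[0] - pad + n) % L), L)


def coverage_mask(ivls: Sequence[Interval], L: int):
    """Boolean per-base occupancy array for a set of intervals."""
    import numpy as np

    mask = np.zeros(L, dtype=bool)
    for ivl in ivls:
        n = interval_length(ivl, L)
        s = ivl[0] % L
        idx = (np.arange(s, s + n)) % L
        mask[idx] = True
    return mask
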