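"""Interval-union arithmetic and fixed-point percentage rounding.

Coverage statistics here are defined on the union of intervals, so that a
base covered by several homology segments is counted once.  Percentages are
quantised half-up to two decimals with exact rational arithmetic, which is
the rounding convention used in every report this package writes.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of half-open intervals as a sorted, disjoint list.

    Idempotent and order-independent; zero-length intervals vanish.
    """
    ivs = sorted((s, e) for s, e in intervals if e > s)
    merged: list[tuple[int, int]] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            if e > merged[-1][1]:
                merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    return [(s, e) for s, e in merged]


def covered_length(intervals: Iterable[tuple[int, int]]) -> int:
    return sum(e - s for s, e in merge_intervals(intervals))


def wrap_intervals(
    intervals: Iterable[tuple[int, int]], length: int
) -> list[tuple[int, int]]:
    """Normalise intervals on a circle of ``length`` into [0, length) pieces.

    An interval crossing the origin is split into its two arcs, so that
    union/coverage arithmetic can stay linear.
    """
    out: list[tuple[int, int]] = []
    for s0, e0 in intervals:
        span = e0 - s0
        if span <= 0:
            raise ValueError(f"empty or inverted interval ({s0}, {e0})")
        if span >= length:
            return [(0, length)]
        s = s0 % length
        e = s + span
        if e <= length:
            out.append((s, e))
        else:
            out.append((s, length))
            out.append((0, e - length))
    return merge_intervals(out)


def percent(part: int | float, whole: int | float, decimals: int = 2) -> float:
    """``100 * part / whole`` rounded half-up to ``decimals`` places.

    Integer inputs are computed as exact rationals so printed report values
    (e.g. 147540/380980 -> 38.73) do not depend on binary float rounding.
    """
    if whole == 0:
        raise ZeroDivisionError("percentage of a zero-length whole")
    q = Decimal(1).scaleb(-decimals)
    val = Decimal(100) * Decimal(str(part)) / Decimal(str(whole))
    return float(val.quantize(q, rounding=ROUND_HALF_UP))


def round_half_up(x: float, decimals: int = 2) -> float:
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(str(x)).quantize(q, rounding=ROUND_HALF_UP))
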