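"""Half-open integer interval arithmetic on a single sequence axis.

All coordinates are 0-based, half-open ``[start, end)``. An :class:`IntervalSet`
is kept merged and sorted, so set operations (union, complement, intersection)
are linear scans.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, List, Tuple

Interval = Tuple[int, int]


def merge_intervals(intervals: Iterable[Interval]) -> List[Interval]:
    """Merge overlapping or touching half-open intervals into a sorted list."""
    ivs = sorted((int(s), int(e)) for s, e in intervals if e > s)
    merged: List[Interval] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


@dataclass(frozen=True)
class IntervalSet:
    """A merged, sorted set of half-open intervals."""

    intervals: Tuple[Interval, ...] = field(default_factory=tuple)

    @classmethod
    def from_pairs(cls, pairs: Iterable[Interval]) -> "IntervalSet":
        return cls(tuple(merge_intervals(pairs)))

    def __iter__(self) -> Iterator[Interval]:
        return iter(self.intervals)

    def __len__(self) -> int:
        return len(self.intervals)

    @property
    def total_length(self) -> int:
        return sum(e - s for s, e in self.intervals)

    def contains_interval(self, start: int, end: int) -> bool:
        """True if [start, end) lies entirely inside one member interval."""
        return any(s <= start and end <= e for s, e in self.intervals)

    def overlaps(self, start: int, end: int) -> bool:
        return any(s < end and start < e for s, e in self.intervals)

    def intersect(self, start: int, end: int) -> "IntervalSet":
        """Clip the set to the window [start, end)."""
        out = [
            (max(s, start), min(e, end))
            for s, e in self.intervals
            if s < end and start < e
        ]
        return IntervalSet.from_pairs(out)

    def complement(self, start: int, end: int) -> "IntervalSet":
        """Gaps of the set within the window [start, end)."""
        out: List[Interval] = []
        cursor = start
        for s, e in self.intervals:
            if e <= start or s >= end:
                continue
            if s > cursor:
                out.append((cursor, min(s, end)))
            cursor = max(cursor, e)
        if cursor < end:
            out.append((cursor, end))
        return IntervalSet.from_pairs(out)

    def union(self, other: "IntervalSet") -> "IntervalSet":
        return IntervalSet.from_pairs(list(self.intervals) + list(other.intervals))
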