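"""Genomic interval primitives.

All coordinates are 0-based half-open on a named sequence. GTF I/O converts
to and from the 1-based inclusive convention at the boundary; everything
internal uses these intervals, so overlap and length arithmetic is uniform.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

STRANDS = ("+", "-")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A strand-aware half-open interval [start, end) on a sequence."""

    seq_id: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """Non-zero overlap, strand-agnostic."""
        return (
            self.seq_id == other.seq_id
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.seq_id != other.seq_id:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


def total_length(intervals: Iterable[GenomicInterval]) -> int:
    return sum(iv.length for iv in intervals)


def merge_intervals(intervals: Sequence[GenomicInterval]) -> list[GenomicInterval]:
    """Union of intervals: sorted, non-overlapping (touching intervals fuse).

    All intervals must share a seq_id; strand of the first is kept.
    """
    if not intervals:
        return []
    seq_ids = {iv.seq_id for iv in intervals}
    if len(seq_ids) > 1:
        raise ValueError(f"cannot merge intervals across sequences: {sorted(seq_ids)}")
    strand = intervals[0].strand
    ordered = sorted(intervals, key=lambda iv: (iv.start, iv.end))
    merged: list[tuple[int, int]] = []
    for iv in ordered:
        if merged and iv.start <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], iv.end))
        else:
            merged.append((iv.start, iv.end))
    seq_id = ordered[0].seq_id
    return [GenomicInterval(seq_id, s, e, strand) for s, e in merged]


def intersection_length(
    a: Sequence[GenomicInterval], b: Sequence[GenomicInterval]
) -> int:
    """Total number of bases covered by both interval sets (per seq_id)."""
    n = 0
    for iv_a in a:
        for iv_b in b:
            n += iv_a.overlap_length(iv_b)
    return n


def any_overlap(a: Sequence[GenomicInterval], b: Sequence[GenomicInterval]) -> bool:
    return any(iv_a.overlaps(iv_b) for iv_a in a for iv_b in b)
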