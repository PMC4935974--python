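"""Strand-aware genomic interval arithmetic.

All coordinates are 0-based half-open (BED dialect). Overlap requires at
least one shared nucleotide on the same strand; half-open adjacency
([0,100) vs [100,200)) is not an overlap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

STRANDS = ("+", "-")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}: must be + or -")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.strand == other.strand
            and self.start < other.end
            and other.start < self.end
        )

    def intersection(self, other: "GenomicInterval") -> "GenomicInterval | None":
        if not self.overlaps(other):
            return None
        return GenomicInterval(
            self.chrom, max(self.start, other.start), min(self.end, other.end), self.strand
        )


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Merge overlapping or book-ended intervals per (chrom, strand).

    Book-ended intervals are merged because downstream users (coverage
    candidates, exon unions) care about contiguous nucleotide runs.
    """
    by_key: dict[tuple[str, str], list[GenomicInterval]] = {}
    for iv in intervals:
        by_key.setdefault((iv.chrom, iv.strand), []).append(iv)
    out: list[GenomicInterval] = []
    for (chrom, strand), ivs in by_key.items():
        ivs.sort(key=lambda iv: (iv.start, iv.end))
        cur_start, cur_end = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_end:
                cur_end = max(cur_end, iv.end)
            else:
                out.append(GenomicInterval(chrom, cur_start, cur_end, strand))
                cur_start, cur_end = iv.start, iv.end
        out.append(GenomicInterval(chrom, cur_start, cur_end, strand))
    out.sort()
    return out


def subtract_intervals(
    spans: Sequence[GenomicInterval], holes: Sequence[GenomicInterval]
) -> list[GenomicInterval]:
    """Set difference spans \\ holes, per (chrom, strand)."""
    holes_merged = merge_intervals(holes) if holes else []
    out: list[GenomicInterval] = []
    for span in spans:
        cursor = span.start
        for h in holes_merged:
            if h.chrom != span.chrom or h.strand != span.strand:
                continue
            if h.end <= cursor or h.start >= span.end:
                continue
            if h.start > cursor:
                out.append(GenomicInterval(span.chrom, cursor, h.start, span.strand))
            cursor = max(cursor, h.end)
            if cursor >= span.end:
                break
        if cursor < span.end:
            out.append(GenomicInterval(span.chrom, cursor, span.end, span.strand))
    out.sort()
    return out


def total_length(intervals: Iterable[GenomicInterval]) -> int:
    return sum(len(iv) for iv in intervals)


@dataclass
class OverlapRecord:
    """One overlapping pair from :func:`intersect_clusters`."""

    index_a: int
    index_b: int
    overlap: GenomicInterval


@dataclass
class OverlapReport:
    records: list[OverlapRecord] = field(default_factory=list)
    a_overlaps: list[bool] = field(default_factory=list)
    b_overlaps: list[bool] = field(default_factory=list)


def _chrom_dialects(intervals: Sequence[GenomicInterval]) -> set[bool]:
    return {iv.chrom.startswith("chr") for iv in intervals}


def intersect_clusters(
    a: Sequence[GenomicInterval], b: Sequence[GenomicInterval]
) -> OverlapReport:
    """All same-strand overlapping pairs between two interval sets.

    Warns (does not fail) when the two sets mix 'chr'-prefixed and bare
    chromosome naming, which usually signals mixed assemblies.
    """
    if a and b and len(_chrom_dialects(a) | _chrom_dialects(b)) > 1:
        warnings.warn(
            "interval sets mix 'chr'-prefixed and bare chromosome names; "
            "overlaps across dialects will be empty",
            stacklevel=2,
        )
    report = OverlapReport(
        a_overlaps=[False] * len(a), b_overlaps=[False] * len(b)
    )
    by_key: dict[tuple[str, str], list[tuple[int, GenomicInterval]]] = {}
    for j, iv in enumerate(b):
        by_key.setdefault((iv.chrom, iv.strand), []).append((j, iv))
    for key in by_key:
        by_key[key].sort(key=lambda t: t[1].start)
    import bisect

    for i, iv in enumerate(a):
        candidates = by_key.get((iv.chrom, iv.strand), [])
        starts = [c[1].start for c in candidates]
        # everything with start < iv.end can overlap; scan back is bounded in practice
        hi = bisect.bisect_left(starts, iv.end)
        for j, jv in candidates[:hi]:
            inter = iv.intersection(jv)
            if inter is not None:
                report.records.append(OverlapRecord(i, j, inter))
                report.a_overlaps[i] = True
                report.b_overlaps[j] = True
    return report
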