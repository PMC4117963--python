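"""Genomic coordinate model and interval algebra.

All coordinates are 0-based, half-open (BED convention) everywhere in the
package; format readers convert on input.  The algebra here (merge,
intersection, subtraction, per-interval overlap) is the foundation for peak
annotation, methylation density and DMR merging, and is deliberately simple
enough to verify against per-base-pair boolean-array oracles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np

STRANDS = ("+", "-", ".")


@dataclass
class GenomicInterval:
    """A half-open genomic span ``[start, end)`` on a named chromosome.

    Parameters
    ----------
    chrom : str
        Chromosome name.
    start : int
        0-based inclusive start (bp).
    end : int
        Exclusive end (bp); must satisfy ``0 <= start < end``.
    strand : str
        One of ``+``, ``-``, ``.`` (unstranded).
    name, score : optional
        BED columns 4-5; ``name`` doubles as the class label for repeat
        tracks and as the direction label for DMR output.
    """

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: Optional[str] = None
    score: Optional[float] = None

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlap(self, other: "GenomicInterval") -> int:
        """Overlap length in bp with another interval (0 if different chrom)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def __str__(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


@dataclass
class GenomeIndex:
    """Ordered chromosome name/length table; denominator for genome-wide
    coverage fractions."""

    chroms: list[tuple[str, int]]

    def __post_init__(self) -> None:
        names = [c for c, _ in self.chroms]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names in genome index")
        for name, length in self.chroms:
            if length <= 0:
                raise ValueError(f"chromosome {name} has non-positive length")

    @property
    def names(self) -> list[str]:
        return [c for c, _ in self.chroms]

    @property
    def total_size(self) -> int:
        return sum(l for _, l in self.chroms)

    def length(self, chrom: str) -> int:
        for name, l in self.chroms:
            if name == chrom:
                return l
        raise KeyError(f"unknown chromosome {chrom!r}")

    def __contains__(self, chrom: str) -> bool:
        return any(name == chrom for name, _ in self.chroms)

    def as_intervals(self) -> list[GenomicInterval]:
        return [GenomicInterval(c, 0, l) for c, l in self.chroms]


class IntervalSet:
    """A merged, sorted, per-chromosome set of disjoint intervals.

    This is the workhorse container for tracks (peaks, feature categories,
    repeat classes).  Construction merges overlapping and book-ended input
    intervals; strand and names are dropped.
    """

    def __init__(self, intervals: Iterable[GenomicInterval] = ()):
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for iv in intervals:
            by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        for chrom, spans in by_chrom.items():
            spans.sort()
            merged: list[list[int]] = []
            for s, e in spans:
                if merged and s <= merged[-1][1]:  # book-ended intervals join
                    merged[-1][1] = max(merged[-1][1], e)
                else:
                    merged.append([s, e])
            self._starts[chrom] = np.array([m[0] for m in merged], dtype=np.int64)
            self._ends[chrom] = np.array([m[1] for m in merged], dtype=np.int64)

    @classmethod
    def _from_arrays(cls, starts: dict[str, np.ndarray], ends: dict[str, np.ndarray]) -> "IntervalSet":
        obj = cls.__new__(cls)
        obj._starts = starts
        obj._ends = ends
        return obj

    @property
    def chroms(self) -> list[str]:
        return sorted(self._starts)

    def __len__(self) -> int:
        return sum(len(a) for a in self._starts.values())

    def __iter__(self) -> Iterator[GenomicInterval]:
        for chrom in self.chroms:
            for s, e in zip(self._starts[chrom], self._ends[chrom]):
                yield GenomicInterval(chrom, int(s), int(e))

    def to_intervals(self) -> list[GenomicInterval]:
        return list(self)

    def total_length(self) -> int:
        return int(
            sum((self._ends[c] - self._starts[c]).sum() for c in self._starts)
        )

    def overlap_length(self, chrom: str, start: int, end: int) -> int:
        """Total bp of ``[start, end)`` covered by this set."""
        if chrom not in self._starts:
            return 0
        starts, ends = self._starts[chrom], self._ends[chrom]
        i0 = int(np.searchsorted(ends, start, side="right"))
        i1 = int(np.searchsorted(starts, end, side="left"))
        if i0 >= i1:
            return 0
        s = np.maximum(starts[i0:i1], start)
        e = np.minimum(ends[i0:i1], end)
        return int(np.maximum(e - s, 0).sum())

    def covers_any(self, chrom: str, start: int, end: int) -> bool:
        return self.overlap_length(chrom, start, end) > 0

    def intersection_length(self, other: "IntervalSet") -> int:
        """Total bp shared with another set."""
        total = 0
        for chrom in self._starts:
            if chrom not in other._starts:
                continue
            for s, e in zip(self._starts[chrom], self._ends[chrom]):
                total += other.overlap_length(chrom, int(s), int(e))
        return total

    def intersection(self, other: "IntervalSet") -> "IntervalSet":
        out: list[GenomicInterval] = []
        for chrom in self._starts:
            if chrom not in other._starts:
                continue
            os, oe = other._starts[chrom], other._ends[chrom]
            for s, e in zip(self._starts[chrom], self._ends[chrom]):
                i0 = int(np.searchsorted(oe, s, side="right"))
                i1 = int(np.searchsorted(os, e, side="left"))
                for j in range(i0, i1):
                    a, b = max(int(os[j]), int(s)), min(int(oe[j]), int(e))
                    if a < b:
                        out.append(GenomicInterval(chrom, a, b))
        return IntervalSet(out)

    def subtract(self, other: "IntervalSet") -> "IntervalSet":
        """Set difference self \\ other, as a new merged set."""
        out: list[GenomicInterval] = []
        for chrom in self._starts:
            os = other._starts.get(chrom)
            oe = other._ends.get(chrom)
            for s, e in zip(self._starts[chrom], self._ends[chrom]):
                s, e = int(s), int(e)
                if os is None or len(os) == 0:
                    out.append(GenomicInterval(chrom, s, e))
                    continue
                cur = s
                i0 = int(np.searchsorted(oe, s, side="right"))
                i1 = int(np.searchsorted(os, e, side="left"))
                for j in range(i0, i1):
                    a, b = int(os[j]), int(oe[j])
                    if a > cur:
                        out.append(GenomicInterval(chrom, cur, min(a, e)))
                    cur = max(cur, b)
                    if cur >= e:
                        break
                if cur < e:
                    out.append(GenomicInterval(chrom, cur, e))
        return IntervalSet(out)

    def union(self, other: "IntervalSet") -> "IntervalSet":
        return IntervalSet(list(self) + list(other))


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Merge overlapping/book-ended intervals; sorted, disjoint output."""
    return IntervalSet(intervals).to_intervals()


def total_length(intervals: Iterable[GenomicInterval]) -> int:
    """Total bp covered by the (possibly overlapping) intervals."""
    return IntervalSet(intervals).total_length()


def validate_against_genome(
    intervals: Sequence[GenomicInterval], genome: GenomeIndex
) -> None:
    """Raise if any interval falls outside the genome's chromosome bounds."""
    for iv in intervals:
        if iv.chrom not in genome:
            raise ValueError(f"unknown chromosome {iv.chrom!r} in {iv}")
        if iv.end > genome.length(iv.chrom):
            raise ValueError(f"interval {iv} exceeds chromosome bounds")
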