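"""Genomic interval primitives and a small overlap index.

All coordinates are 0-based half-open.  File formats that use 1-based
inclusive coordinates (GTF, GFF3) are converted at the I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

import numpy as np


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval on a named chromosome.

    ``start`` is 0-based inclusive, ``end`` 0-based exclusive.  ``strand``
    is ``"+"`` or ``"-"``; ``"."`` is accepted for unstranded records.
    """

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(require 0 <= start < end)"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval", stranded: bool = False) -> bool:
        if self.chrom != other.chrom:
            return False
        if stranded and self.strand != other.strand:
            return False
        return self.start < other.end and other.start < self.end

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def shifted(self, offset: int) -> "GenomicInterval":
        return GenomicInterval(self.chrom, self.start + offset, self.end + offset, self.strand)

    def expanded(self, flank: int) -> "GenomicInterval":
        return GenomicInterval(self.chrom, max(0, self.start - flank), self.end + flank, self.strand)


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge possibly-overlapping (start, end) pairs into disjoint sorted runs."""
    out: list[tuple[int, int]] = []
    for start, end in sorted(intervals):
        if out and start <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], end))
        else:
            out.append((start, end))
    return out


class IntervalIndex:
    """Overlap queries over a static set of keyed intervals.

    Backed by start-sorted arrays with a running end maximum; adequate for
    the desk-scale instances this package targets.
    """

    def __init__(self, intervals: Sequence[tuple[int, int, object]]):
        # intervals: (start, end, payload)
        order = sorted(range(len(intervals)), key=lambda i: (intervals[i][0], intervals[i][1]))
        self._starts = np.array([intervals[i][0] for i in order], dtype=np.int64)
        self._ends = np.array([intervals[i][1] for i in order], dtype=np.int64)
        self._payloads = [intervals[i][2] for i in order]
        self._max_end = np.maximum.accumulate(self._ends) if len(order) else self._ends

    def __len__(self) -> int:
        return len(self._payloads)

    def query(self, start: int, end: int) -> Iterator[tuple[int, int, object]]:
        """Yield (start, end, payload) for every interval overlapping [start, end)."""
        if not len(self._payloads):
            return
        hi = int(np.searchsorted(self._starts, end, side="left"))
        i = hi - 1
        while i >= 0 and self._max_end[i] > start:
            if self._ends[i] > start:
                yield int(self._starts[i]), int(self._ends[i]), self._payloads[i]
            i -= 1
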