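"""Read-region distributions, binned metagene profiles, terciles, overlaps."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from targetome.genome_model import (
    CDS,
    INTERGENIC,
    INTRON,
    REGION_NAMES,
    UTR3,
    UTR5,
    AlignedRead,
    GenomeAnnotation,
    TranscriptModel,
)
from targetome.intervals import GenomicInterval, IntervalIndex

# ties in majority labelling resolve by this precedence (highest wins)
_PRECEDENCE = (CDS, UTR3, UTR5, INTRON, INTERGENIC)


@dataclass
class RegionDistribution:
    """Per-label read fractions for one library; fractions sum to 1."""

    library: str
    counts: dict[str, int]

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def fractions(self) -> dict[str, float]:
        total = self.total
        return {k: v / total for k, v in self.counts.items()} if total else dict(self.counts)


@dataclass
class BinnedProfile:
    """Normalized depth over consecutive fixed-bin regions."""

    region_order: tuple[str, ...]
    bins_per_region: int
    depth: np.ndarray
    library: str = "all"


@dataclass
class TercilePartition:
    long: list[str]
    medium: list[str]
    short: list[str]

    @property
    def sizes(self) -> tuple[int, int, int]:
        return len(self.long), len(self.medium), len(self.short)


def classify_read_regions(
    reads: Iterable[AlignedRead],
    annotation: GenomeAnnotation,
) -> dict[str, RegionDistribution]:
    """Label each read by the majority region of its matched reference bases.

    Ties resolve by the global precedence CDS > 3'UTR > 5'UTR > intron >
    intergenic.  Returns one distribution per library.
    """
    per_lib: dict[str, dict[str, int]] = {}
    for read in reads:
        label = read_region_label(read, annotation)
        counts = per_lib.setdefault(read.library, {name: 0 for name in REGION_NAMES.values()})
        counts[label] += 1
    return {lib: RegionDistribution(lib, counts) for lib, counts in sorted(per_lib.items())}


def read_region_label(read: AlignedRead, annotation: GenomeAnnotation) -> str:
    arr = annotation.region_array(read.chrom, read.strand)
    tallies = np.zeros(len(REGION_NAMES), dtype=np.int64)
    for s, e in read.match_blocks():
        s, e = max(0, s), min(len(arr), e)
        if s < e:
            tallies += np.bincount(arr[s:e], minlength=len(REGION_NAMES))
    best = tallies.max()
    if best == 0:
        return "intergenic"
    for code in _PRECEDENCE:
        if tallies[code] == best:
            return REGION_NAMES[code]
    raise AssertionError("unreachable")


def _coverage(reads: Sequence[AlignedRead], chrom: str, strand: str, length: int) -> np.ndarray:
    cov = np.zeros(length, dtype=np.float64)
    for read in reads:
        if read.chrom != chrom or read.strand != strand:
            continue
        for s, e in read.match_blocks():
            s, e = max(0, s), min(length, e)
            if s < e:
                cov[s:e] += 1
    return cov


def _region_depth(cov: np.ndarray, intervals: Sequence[GenomicInterval], strand: str) -> np.ndarray:
    parts = [cov[iv.start : iv.end] for iv in intervals]
    depth = np.concatenate(parts) if parts else np.zeros(0)
    return depth[::-1] if strand == "-" else depth


def _rebin(depth: np.ndarray, bins: int) -> np.ndarray:
    """Rescale a per-base depth vector onto ``bins`` equal-width bins,
    conserving total signal (fractional bases split proportionally)."""
    out = np.zeros(bins)
    n = len(depth)
    if n == 0:
        return out
    edges = np.linspace(0, n, bins + 1)
    for b in range(bins):
        lo, hi = edges[b], edges[b + 1]
        i0, i1 = int(np.floor(lo)), int(np.ceil(hi))
        for i in range(i0, min(i1, n)):
            frac = min(hi, i + 1) - max(lo, i)
            if frac > 0:
                out[b] += depth[i] * frac
    return out


def region_coverage_profile(
    reads: Sequence[AlignedRead],
    annotation: GenomeAnnotation,
    transcript_ids: Iterable[str],
    bins: int = 100,
    per_transcript_normalize: bool = False,
) -> BinnedProfile:
    """5'UTR/CDS/3'UTR metagene profile with ``bins`` bins per region.

    Each transcript region is rescaled to the bin grid in 5'->3'
    transcript orientation; depths are summed over transcripts and the
    full curve normalized to unit area.  With ``per_transcript_normalize``
    each transcript's contribution is first scaled to unit total.
    """
    tids = sorted(set(transcript_ids))
    if not tids:
        raise ValueError("empty transcript set")
    total = np.zeros(3 * bins)
    cov_cache: dict[tuple[str, str], np.ndarray] = {}
    for tid in tids:
        t = annotation.transcripts[tid]
        key = (t.chrom, t.strand)
        if key not in cov_cache:
            cov_cache[key] = _coverage(reads, t.chrom, t.strand, annotation.chrom_lengths[t.chrom])
        cov = cov_cache[key]
        contribution = np.zeros(3 * bins)
        for r, intervals in enumerate((t.utr5, t.cds, t.utr3)):
            depth = _region_depth(cov, intervals, t.strand)
            contribution[r * bins : (r + 1) * bins] = _rebin(depth, bins)
        if per_transcript_normalize and contribution.sum() > 0:
            contribution /= contribution.sum()
        total += contribution
    if total.sum() > 0:
        total /= total.sum()
    return BinnedProfile(region_order=("utr5", "cds", "utr3"), bins_per_region=bins, depth=total)


def tercile_partition(utr3_lengths: Mapping[str, int]) -> TercilePartition:
    """Rank transcripts by 3'UTR length (descending, ties by id) and split
    into three contiguous groups as equal as possible; the remainder goes
    to the short group."""
    n = len(utr3_lengths)
    if n < 3:
        raise ValueError(f"need >= 3 transcripts, got {n}")
    ranked = sorted(utr3_lengths, key=lambda tid: (-utr3_lengths[tid], tid))
    sizes = [n // 3] * 3
    for i in range(n % 3):  # remainder fills from the short group upward
        sizes[2 - i] += 1
    return TercilePartition(
        long=ranked[: sizes[0]],
        medium=ranked[sizes[0] : sizes[0] + sizes[1]],
        short=ranked[sizes[0] + sizes[1] :],
    )


@dataclass
class OverlapSummary:
    n_reads: int
    n_overlapping: int
    per_name: dict[str, int]

    @property
    def fraction(self) -> float:
        return self.n_overlapping / self.n_reads if self.n_reads else 0.0


def interval_overlap_summary(
    reads: Iterable[AlignedRead],
    intervals: Sequence[GenomicInterval],
    names: Sequence[str] | None = None,
    stranded: bool = False,
) -> OverlapSummary:
    """Fraction of reads overlapping any interval by >= 1 matched base.

    Each overlapping read is attributed to the single interval (by
    ``names``, e.g. repeat family or cluster id) with the largest overlap;
    ties resolve to the lexicographically first name.
    """
    if names is None:
        names = [f"interval_{i}" for i in range(len(intervals))]
    raw: dict = {}
    for i, (iv, name) in enumerate(zip(intervals, names)):
        key = (iv.chrom, iv.strand) if stranded else iv.chrom
        raw.setdefault(key, []).append((iv.start, iv.end, (i, name)))
    index = {k: IntervalIndex(v) for k, v in raw.items()}

    n_reads = n_overlap = 0
    per_name: dict[str, int] = {}
    for read in reads:
        n_reads += 1
        key = (read.chrom, read.strand) if stranded else read.chrom
        idx = index.get(key)
        if idx is None:
            continue
        overlap_by_interval: dict[tuple[int, str], int] = {}
        for bs, be in read.match_blocks():
            for s, e, payload in idx.query(bs, be):
                ov = min(be, e) - max(bs, s)
                overlap_by_interval[payload] = overlap_by_interval.get(payload, 0) + ov
        if overlap_by_interval:
            n_overlap += 1
            # largest summed overlap wins; ties -> lexicographically first name
            best = min(overlap_by_interval.items(), key=lambda kv: (-kv[1], kv[0][1], kv[0][0]))
            name = best[0][1]
            per_name[name] = per_name.get(name, 0) + 1
    return OverlapSummary(n_reads=n_reads, n_overlapping=n_overlap, per_name=dict(sorted(per_name.items())))
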