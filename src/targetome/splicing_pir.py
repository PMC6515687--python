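"""Percent intron retention (PIR), transcript-change and isoform ratios."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from targetome.genome_model import AlignedRead, GenomeAnnotation
from targetome.intervals import GenomicInterval

MIN_RETENTION_OVERLAP = 6  # intron-interior nt required for retention evidence


@dataclass
class PIRResult:
    intron_id: str
    retention: int
    exclusion: int
    condition: str

    @property
    def pir(self) -> float | None:
        """Percent intron retention; None when no informative reads."""
        total = self.retention + self.exclusion
        if total == 0:
            return None
        return 100.0 * self.retention / total


@dataclass
class IsoformRatio:
    gene_id: str
    long_evidence: float
    short_evidence: float
    condition: str

    @property
    def ratio(self) -> float:
        total = self.long_evidence + self.short_evidence
        return self.long_evidence / total if total else 0.0


def _intron_in_annotation(intron: GenomicInterval, annotation: GenomeAnnotation) -> bool:
    for t in annotation.transcripts.values():
        for iv in t.introns:
            if (iv.chrom, iv.strand, iv.start, iv.end) == (
                intron.chrom,
                intron.strand,
                intron.start,
                intron.end,
            ):
                return True
    return False


def count_isoform_evidence(
    reads: Sequence[AlignedRead],
    intron: GenomicInterval,
    annotation: GenomeAnnotation | None = None,
    min_overlap: int = MIN_RETENTION_OVERLAP,
) -> tuple[int, int]:
    """(retention, exclusion) read counts for one intron.

    Exclusion: reads with a skip segment spanning exactly this intron.
    Retention: reads overlapping the intron interior by >= ``min_overlap``
    matched nt without skipping it.
    """
    if annotation is not None and not _intron_in_annotation(intron, annotation):
        raise ValueError(
            f"intron {intron.chrom}:{intron.start}-{intron.end}({intron.strand}) "
            "is not flanked by annotated exons"
        )
    retention = exclusion = 0
    for read in reads:
        if read.chrom != intron.chrom or read.strand != intron.strand:
            continue
        if any(s == intron.start and e == intron.end for s, e in read.skip_blocks()):
            exclusion += 1
            continue
        interior = sum(
            max(0, min(e, intron.end) - max(s, intron.start)) for s, e in read.match_blocks()
        )
        if interior >= min_overlap:
            retention += 1
    return retention, exclusion


def compute_pir(retention: int, exclusion: int) -> float | None:
    """100 * retention / (retention + exclusion); None when undefined."""
    total = retention + exclusion
    if total == 0:
        return None
    return 100.0 * retention / total


def mirtron_transcript_change(
    control_counts: tuple[int, int],
    knockdown_counts: tuple[int, int],
    control_library_size: int = 1,
    knockdown_library_size: int = 1,
) -> float | None:
    """Relative whole transcript level, knockdown over control.

    Whole level = retention + exclusion evidence, per-million normalized
    by library size.  None when the control total is zero.
    """
    c_total = sum(control_counts) / (control_library_size / 1e6 if control_library_size else 1)
    k_total = sum(knockdown_counts) / (knockdown_library_size / 1e6 if knockdown_library_size else 1)
    if c_total == 0:
        return None
    return k_total / c_total


def _region_density(reads: Sequence[AlignedRead], region: GenomicInterval) -> float:
    """Mean matched-base coverage over a region (aligned nt / region nt)."""
    total = 0
    for read in reads:
        if read.chrom != region.chrom or read.strand != region.strand:
            continue
        for s, e in read.match_blocks():
            total += max(0, min(e, region.end) - max(s, region.start))
    return total / len(region)


def long_isoform_ratio(
    reads: Sequence[AlignedRead],
    long_specific_region: GenomicInterval,
    shared_region: GenomicInterval,
    gene_id: str = "",
    condition: str = "",
) -> IsoformRatio:
    """Ratio of the long isoform over both from region read densities.

    Long evidence is the density over the long-isoform-specific region;
    short evidence is the shared-region density minus long evidence,
    floored at zero.
    """
    if len(long_specific_region) == 0:
        raise ValueError("long-isoform-specific region is empty")
    long_ev = _region_density(reads, long_specific_region)
    shared_ev = _region_density(reads, shared_region)
    short_ev = max(0.0, shared_ev - long_ev)
    return IsoformRatio(gene_id, long_ev, short_ev, condition)
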