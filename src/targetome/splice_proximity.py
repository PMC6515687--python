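"""Crosslink-site distances to splice sites and junction-flank composition.

Offsets are 1-based distances into the intron from each splice site,
measured in transcript orientation: the 5' splice site is the intron end
nearer the upstream exon, the 3' splice site the end nearer the
downstream exon.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from targetome.crosslink_sites import CrosslinkSite, PositionalProfile, reverse_complement
from targetome.genome_model import GenomeAnnotation
from targetome.intervals import GenomicInterval


@dataclass
class SpliceSiteHistogram:
    side: str  # "5ss_downstream" or "3ss_upstream"
    window: int
    site_counts: np.ndarray  # index 0 -> offset 1
    residue_counts: np.ndarray

    def offset_counts(self) -> dict[int, int]:
        return {i + 1: int(c) for i, c in enumerate(self.site_counts) if c}

    @property
    def mode_offset(self) -> int | None:
        if self.site_counts.sum() == 0:
            return None
        return int(np.argmax(self.site_counts)) + 1


def unique_introns(annotation: GenomeAnnotation) -> list[GenomicInterval]:
    """Deduplicated introns across all transcripts (chrom, strand, span)."""
    seen = set()
    out = []
    for t in annotation.transcripts.values():
        for iv in t.introns:
            key = (iv.chrom, iv.strand, iv.start, iv.end)
            if key not in seen:
                seen.add(key)
                out.append(iv)
    return sorted(out, key=lambda iv: (iv.chrom, iv.start, iv.end, iv.strand))


def _intron_offsets(site_pos: int, intron: GenomicInterval) -> tuple[int, int]:
    """(offset from 5'SS, offset from 3'SS), both 1-based into the intron."""
    if intron.strand == "+":
        return site_pos - intron.start + 1, intron.end - site_pos
    return intron.end - site_pos, site_pos - intron.start + 1


def map_crosslinks_to_splice_sites(
    sites: Sequence[CrosslinkSite],
    annotation: GenomeAnnotation,
    window: int = 200,
) -> tuple[SpliceSiteHistogram, SpliceSiteHistogram]:
    """Histogram unique intronic crosslinked sites by distance into the
    intron from each splice site.

    A site within ``window`` of both ends of a short intron is assigned to
    the nearer side only (tie -> 5'SS).  Each unique genomic position
    contributes once per histogram even when transcripts share introns.
    """
    h5 = np.zeros(window, dtype=np.int64)
    h3 = np.zeros(window, dtype=np.int64)
    r5 = np.zeros(window, dtype=np.int64)
    r3 = np.zeros(window, dtype=np.int64)
    introns = unique_introns(annotation)
    counted: set[tuple[str, str, int]] = set()
    for site in sites:
        key = (site.chrom, site.strand, site.position)
        if key in counted:
            continue
        # best (smallest-offset) assignment over all host introns
        best: tuple[int, str] | None = None  # (offset, side)
        for intron in introns:
            if intron.chrom != site.chrom or intron.strand != site.strand:
                continue
            if not intron.start <= site.position < intron.end:
                continue
            off5, off3 = _intron_offsets(site.position, intron)
            if off5 <= window and (off3 > window or off5 <= off3):
                cand = (off5, "5ss")
            elif off3 <= window:
                cand = (off3, "3ss")
            else:
                continue
            if best is None or cand[0] < best[0] or (cand[0] == best[0] and cand[1] == "5ss"):
                best = cand
        if best is None:
            continue
        counted.add(key)
        off, side = best
        if side == "5ss":
            h5[off - 1] += 1
            r5[off - 1] += site.residue_count
        else:
            h3[off - 1] += 1
            r3[off - 1] += site.residue_count
    return (
        SpliceSiteHistogram("5ss_downstream", window, h5, r5),
        SpliceSiteHistogram("3ss_upstream", window, h3, r3),
    )


def splice_flank_composition(
    annotation: GenomeAnnotation,
    sites: Sequence[CrosslinkSite],
    genome: Mapping[str, str],
    flank: int = 100,
) -> dict[str, PositionalProfile]:
    """Base composition of +-flank windows at exon-intron junctions whose
    intronic side carries >= 1 crosslinked site.

    Windows are strand-oriented with the junction between offsets -1 and
    0; negative offsets are exonic, non-negative offsets intronic.
    Returned per junction side ("5ss", "3ss").
    """
    site_pos: dict[tuple[str, str], set[int]] = {}
    for s in sites:
        site_pos.setdefault((s.chrom, s.strand), set()).add(s.position)

    def intronic_hit(chrom: str, strand: str, lo: int, hi: int) -> bool:
        positions = site_pos.get((chrom, strand), ())
        return any(lo <= p < hi for p in positions)

    counts = {
        side: {b: np.zeros(2 * flank, dtype=np.int64) for b in "ACGU"}
        for side in ("5ss", "3ss")
    }
    n_kept = {"5ss": 0, "3ss": 0}
    seen: set[tuple] = set()
    for intron in unique_introns(annotation):
        chrom, strand = intron.chrom, intron.strand
        seq = genome[chrom]
        if strand == "+":
            junctions = (("5ss", intron.start, +1), ("3ss", intron.end, -1))
        else:
            junctions = (("5ss", intron.end, -1), ("3ss", intron.start, +1))
        for side, jpos, direction in junctions:
            key = (side, chrom, strand, jpos)
            if key in seen:
                continue
            seen.add(key)
            # intronic half of the window, in genomic coordinates
            if direction == +1:
                intron_lo, intron_hi = jpos, jpos + flank
                win_lo, win_hi = jpos - flank, jpos + flank
            else:
                intron_lo, intron_hi = jpos - flank, jpos
                win_lo, win_hi = jpos - flank, jpos + flank
            intron_lo = max(intron_lo, intron.start)
            intron_hi = min(intron_hi, intron.end)
            if win_lo < 0 or win_hi > len(seq):
                continue
            if not intronic_hit(chrom, strand, intron_lo, intron_hi):
                continue
            window = str(seq[win_lo:win_hi]).upper()
            if direction == -1:
                window = reverse_complement(window)
            window = window.replace("T", "U")
            arr = np.frombuffer(window.encode(), dtype=np.uint8)
            for base in "ACGU":
                counts[side][base] += arr == ord(base)
            n_kept[side] += 1
    if sum(n_kept.values()) == 0:
        raise ValueError("no junctions retained (no intronic-side crosslink sites)")
    out = {}
    for side in ("5ss", "3ss"):
        total = sum(counts[side].values())
        total[total == 0] = 1
        out[side] = PositionalProfile(
            offsets=np.arange(-flank, flank),
            values={b: counts[side][b] / total for b in "ACGU"},
            n_anchors=n_kept[side],
        )
    return out
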