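"""miRNA-relative CLIP read classification (categories I-V) and profiles.

Category rules, applied first-match-wins:
  I   within the mature miRNA with at most 1 nt total excess sequence
  II  inside the hairpin, overlapping the mature miRNA by >= 1 nt
  III inside the hairpin, no mature overlap
  IV  overlapping the hairpin boundary with >= 1 nt inside the hairpin
  V   entirely outside the hairpin, within the flank window
Form calls: mature from I, pre from II+III, pri from IV+V, each requiring
a configurable minimum read count (default 5).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from targetome.genome_model import AlignedRead
from targetome.intervals import GenomicInterval
from targetome.metagene import BinnedProfile, _rebin

CATEGORIES = ("I", "II", "III", "IV", "V")


@dataclass(frozen=True)
class MirnaHairpin:
    mirna_id: str
    hairpin: GenomicInterval
    matures: tuple[GenomicInterval, ...]
    host_context: str = "unknown"  # intronic / 3utr / exonic / intergenic

    def __post_init__(self) -> None:
        for m in self.matures:
            if not self.hairpin.contains(m):
                raise ValueError(f"{self.mirna_id}: mature interval outside hairpin")
            if m.strand != self.hairpin.strand:
                raise ValueError(f"{self.mirna_id}: mature strand mismatch")

    @property
    def strand(self) -> str:
        return self.hairpin.strand

    @property
    def midpoint(self) -> int:
        return self.hairpin.start + len(self.hairpin) // 2

    def window(self, flank: int) -> GenomicInterval:
        return self.hairpin.expanded(flank)


@dataclass(frozen=True)
class MirnaReadCategory:
    read_id: str
    mirna_id: str
    category: str


@dataclass
class MirnaFormCall:
    mirna_id: str
    counts: dict[str, int]
    forms: set[str]


def parse_mirna_gff3(path: str | Path) -> list[MirnaHairpin]:
    """Read miRBase-dialect GFF3 (miRNA_primary_transcript + miRNA features).

    Mature miRNAs attach to their hairpin via the Derives_from attribute.
    """
    hairpins: dict[str, GenomicInterval] = {}
    names: dict[str, str] = {}
    matures: dict[str, list[GenomicInterval]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 fields")
            chrom, _, ftype, start_s, end_s, _, strand, _, attrs_s = fields
            attrs = dict(kv.split("=", 1) for kv in attrs_s.split(";") if "=" in kv)
            iv = GenomicInterval(chrom, int(start_s) - 1, int(end_s), strand)
            if ftype == "miRNA_primary_transcript":
                key = attrs.get("ID", f"hairpin_{lineno}")
                hairpins[key] = iv
                names[key] = attrs.get("Name", key)
            elif ftype == "miRNA":
                parent = attrs.get("Derives_from")
                if parent is None:
                    raise ValueError(f"{path}:{lineno}: miRNA feature without Derives_from")
                matures.setdefault(parent, []).append(iv)
    return [
        MirnaHairpin(names[key], hp, tuple(sorted(matures.get(key, []))))
        for key, hp in sorted(hairpins.items())
    ]


def write_mirna_gff3(hairpins: Sequence[MirnaHairpin], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, hp in enumerate(hairpins):
            hid = f"MI{i:07d}"
            fh.write(
                f"{hp.hairpin.chrom}\t.\tmiRNA_primary_transcript\t{hp.hairpin.start + 1}\t"
                f"{hp.hairpin.end}\t.\t{hp.strand}\t.\tID={hid};Name={hp.mirna_id}\n"
            )
            for j, m in enumerate(hp.matures):
                fh.write(
                    f"{m.chrom}\t.\tmiRNA\t{m.start + 1}\t{m.end}\t.\t{m.strand}\t.\t"
                    f"ID={hid}_{j};Name={hp.mirna_id}-mat{j};Derives_from={hid}\n"
                )


def collect_hairpin_reads(
    reads: Iterable[AlignedRead],
    hairpins: Sequence[MirnaHairpin],
    flank: int = 100,
) -> list[tuple[AlignedRead, MirnaHairpin]]:
    """Retain (read, hairpin) pairs where the read overlaps the hairpin's
    +-flank window by >= 1 nt on the same strand.  A read near several
    hairpins pairs with each independently."""
    pairs = []
    for read in reads:
        for hp in hairpins:
            win = hp.window(flank)
            if (
                read.chrom == win.chrom
                and read.strand == win.strand
                and read.start < win.end
                and win.start < read.end
            ):
                pairs.append((read, hp))
    return pairs


def categorize(
    read_start: int,
    read_end: int,
    hp: MirnaHairpin,
    max_excess: int = 1,
    excess_mode: str = "total",
) -> str:
    """Category of one read span against one hairpin (first-match-wins).

    ``excess_mode`` controls the category-I excess rule: ``"total"`` sums
    the overhang across both ends, ``"per-end"`` bounds each end alone.
    """
    if excess_mode not in ("total", "per-end"):
        raise ValueError(f"unknown excess_mode {excess_mode!r}")
    h = hp.hairpin
    inside = h.start <= read_start and read_end <= h.end
    overlaps_hairpin = read_start < h.end and h.start < read_end
    for m in hp.matures:
        left = max(0, m.start - read_start)
        right = max(0, read_end - m.end)
        excess = left + right if excess_mode == "total" else max(left, right)
        # require genuine mature overlap, not a read merely near it
        if read_start < m.end and m.start < read_end and excess <= max_excess:
            return "I"
    if inside:
        if any(read_start < m.end and m.start < read_end for m in hp.matures):
            return "II"
        return "III"
    if overlaps_hairpin:
        return "IV"
    return "V"


def classify_mirna_reads(
    pairs: Sequence[tuple[AlignedRead, MirnaHairpin]],
    flank: int = 100,
    max_excess: int = 1,
    excess_mode: str = "total",
) -> list[MirnaReadCategory]:
    out = []
    for read, hp in pairs:
        win = hp.window(flank)
        if not (read.start < win.end and win.start < read.end and read.chrom == win.chrom):
            raise ValueError(
                f"read {read.read_id} does not intersect the flank window of {hp.mirna_id}"
            )
        out.append(
            MirnaReadCategory(
                read.read_id,
                hp.mirna_id,
                categorize(read.start, read.end, hp, max_excess, excess_mode),
            )
        )
    return out


def call_mirna_forms(
    categories: Iterable[MirnaReadCategory],
    min_reads: int = 5,
) -> dict[str, MirnaFormCall]:
    """Per-miRNA category counts and bound-form calls (mature/pre/pri)."""
    counts: dict[str, dict[str, int]] = {}
    for cat in categories:
        per = counts.setdefault(cat.mirna_id, {c: 0 for c in CATEGORIES})
        per[cat.category] += 1
    calls = {}
    for mirna_id in sorted(counts):
        per = counts[mirna_id]
        forms = set()
        if per["I"] >= min_reads:
            forms.add("mature")
        if per["II"] + per["III"] >= min_reads:
            forms.add("pre")
        if per["IV"] + per["V"] >= min_reads:
            forms.add("pri")
        calls[mirna_id] = MirnaFormCall(mirna_id, per, forms)
    return calls


def hairpin_meta_profile(
    reads: Sequence[AlignedRead],
    hairpins: Sequence[MirnaHairpin],
    flank: int = 200,
    bins: int = 30,
) -> BinnedProfile:
    """Read coverage in +-flank windows around hairpin midpoints, strand
    oriented, summed across hairpins, aggregated to ``bins`` bins and
    normalized to unit area."""
    width = 2 * flank
    total = np.zeros(width)
    by_key: dict[tuple[str, str], list[AlignedRead]] = {}
    for r in reads:
        by_key.setdefault((r.chrom, r.strand), []).append(r)
    for hp in hairpins:
        lo = hp.midpoint - flank
        window_cov = np.zeros(width)
        for read in by_key.get((hp.hairpin.chrom, hp.strand), []):
            for s, e in read.match_blocks():
                a, b = max(s - lo, 0), min(e - lo, width)
                if a < b:
                    window_cov[a:b] += 1
        if hp.strand == "-":
            window_cov = window_cov[::-1]
        total += window_cov
    binned = _rebin(total, bins)
    if binned.sum() > 0:
        binned /= binned.sum()
    else:
        import logging

        logging.getLogger(__name__).warning("no reads in any hairpin window; zero profile")
    return BinnedProfile(region_order=("hairpin_flank",), bins_per_region=bins, depth=binned)


@dataclass
class LengthProfile:
    percentages: dict[int, float]  # read length -> percent of reads
    n_reads: int

    def share(self, lo: int, hi: int) -> float:
        """Percentage of reads with length in [lo, hi] inclusive."""
        return sum(p for length, p in self.percentages.items() if lo <= length <= hi)


def small_rna_length_profile(lengths: Sequence[int]) -> LengthProfile:
    """Per-length percentage histogram of small-RNA read lengths."""
    if not lengths:
        raise ValueError("no reads supplied")
    counts: dict[int, int] = {}
    for n in lengths:
        counts[n] = counts.get(n, 0) + 1
    total = len(lengths)
    return LengthProfile(
        percentages={k: 100.0 * v / total for k, v in sorted(counts.items())},
        n_reads=total,
    )
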