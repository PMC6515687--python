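"""Windowed quantification of miRNA primary transcripts and differential calls.

RNA-seq read density in the +-200 nt window flanking a miRNA hairpin is
used as a proxy for the whole transcript level of that miRNA; reads fully
contained in the pre-miRNA are excluded because library size selection
removes them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from targetome.genome_model import AlignedRead, GenomeAnnotation, REGION_NAMES
from targetome.mirna_targetome import MirnaHairpin

import numpy as np


@dataclass
class MirnaWindowDensity:
    mirna_id: str
    condition: str
    read_count: int
    window_length: int
    library_size: int

    @property
    def density(self) -> float:
        """Reads per million library reads per kilobase of window."""
        return self.read_count / (self.library_size / 1e6) / (self.window_length / 1e3)


@dataclass
class DifferentialCall:
    id: str
    control: float
    knockdown: float
    log2_ratio: float
    call: str  # up / down / unchanged


def mirna_window_density(
    reads: Sequence[AlignedRead],
    hairpins: Sequence[MirnaHairpin],
    condition: str,
    flank: int = 200,
    library_size: int | None = None,
) -> dict[str, MirnaWindowDensity]:
    """Read count and normalized density per hairpin +-flank window.

    A read counts iff it overlaps the window by >= 1 nt on the same strand
    and is not fully contained in the pre-miRNA hairpin.
    """
    if library_size is None:
        library_size = len(reads)
    if library_size <= 0:
        raise ValueError("library size must be positive")
    out = {}
    for hp in hairpins:
        win = hp.window(flank)
        n = 0
        for read in reads:
            if read.chrom != win.chrom or read.strand != win.strand:
                continue
            if not (read.start < win.end and win.start < read.end):
                continue
            if hp.hairpin.start <= read.start and read.end <= hp.hairpin.end:
                continue  # absent from the modelled library (size selection)
            n += 1
        out[hp.mirna_id] = MirnaWindowDensity(
            mirna_id=hp.mirna_id,
            condition=condition,
            read_count=n,
            window_length=len(win),
            library_size=library_size,
        )
    return out


def _classify(control: float, knockdown: float, fold_min: float, pseudocount: float) -> tuple[float, str]:
    ratio = (control + pseudocount) / (knockdown + pseudocount)
    log2fc = math.log2(ratio)
    if ratio > fold_min:
        return log2fc, "down"
    if 1.0 / ratio > fold_min:
        return log2fc, "up"
    return log2fc, "unchanged"


def differential_mirna(
    control_tpm: Mapping[str, float],
    knockdown_tpm: Mapping[str, float],
    fold_min: float = 1.5,
    tpm_min: float = 1.5,
    tpm_floor_mode: str = "max",
    pseudocount: float = 0.5,
) -> dict[str, DifferentialCall]:
    """Classify mature miRNAs from small-RNA TPM values per condition.

    ``down`` iff control/knockdown exceeds ``fold_min`` AND the TPM floor
    is met (applied to max/min/mean of the two conditions); ``up``
    symmetric; otherwise ``unchanged``.
    """
    floor_fn = {"max": max, "min": min, "mean": lambda a, b: (a + b) / 2}[tpm_floor_mode]
    ids = sorted(set(control_tpm) | set(knockdown_tpm))
    out = {}
    for mid in ids:
        c = control_tpm.get(mid, 0.0)
        k = knockdown_tpm.get(mid, 0.0)
        if c < 0 or k < 0:
            raise ValueError(f"negative abundance for {mid}")
        log2fc, call = _classify(c, k, fold_min, pseudocount)
        if call != "unchanged" and not floor_fn(c, k) > tpm_min:
            call = "unchanged"
        out[mid] = DifferentialCall(mid, c, k, log2fc, call)
    return out


def differential_mirna_transcripts(
    control_density: Mapping[str, MirnaWindowDensity],
    knockdown_density: Mapping[str, MirnaWindowDensity],
    fold_min: float = 1.5,
    pseudocount: float = 0.5,
) -> dict[str, DifferentialCall]:
    """Classify miRNA transcript-level change from window densities (no
    abundance floor unless configured upstream)."""
    ids = sorted(set(control_density) & set(knockdown_density))
    out = {}
    for mid in ids:
        c, k = control_density[mid], knockdown_density[mid]
        # pseudocount applied on the read-count scale, then normalized
        c_dens = (c.read_count + pseudocount) / (c.library_size / 1e6) / (c.window_length / 1e3)
        k_dens = (k.read_count + pseudocount) / (k.library_size / 1e6) / (k.window_length / 1e3)
        log2fc = math.log2(c_dens / k_dens)
        if c_dens / k_dens > fold_min:
            call = "down"
        elif k_dens / c_dens > fold_min:
            call = "up"
        else:
            call = "unchanged"
        out[mid] = DifferentialCall(mid, c.density, k.density, log2fc, call)
    return out


def classify_mirna_origin(
    hairpins: Sequence[MirnaHairpin],
    annotation: GenomeAnnotation,
) -> dict[str, str]:
    """Host context per miRNA from the majority region label of the mature
    miRNA's bases: intronic / 3utr / exonic / intergenic."""
    out = {}
    for hp in hairpins:
        if hp.matures:
            target = hp.matures[0]
        else:
            target = hp.hairpin
        arr = annotation.region_array(target.chrom, target.strand)
        s, e = target.start, min(target.end, len(arr))
        tallies = np.bincount(arr[s:e], minlength=len(REGION_NAMES)) if s < e else np.zeros(5, dtype=int)
        if tallies.sum() == 0:
            label = "intergenic"
        else:
            code = int(np.argmax(tallies[::-1]))  # ties -> higher precedence code
            code = len(tallies) - 1 - code
            label = REGION_NAMES[code]
        out[hp.mirna_id] = {
            "intergenic": "intergenic",
            "intron": "intronic",
            "utr3": "3utr",
            "utr5": "exonic",
            "cds": "exonic",
        }[label]
    return out
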