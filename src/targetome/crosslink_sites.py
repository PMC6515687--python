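"""Deletion-based crosslink-site calling and sequence/structure context.

A crosslinked site is a unique genomic base covered by a read-level
deletion; its residue count is the number of deleted bases observed
there across all reads.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from targetome.genome_model import AlignedRead

logger = logging.getLogger(__name__)

COMPLEMENT = str.maketrans("ACGTUacgtu", "TGCAAtgcaa")
# canonical pairs on the RNA alphabet (T treated as U)
_PAIRABLE = {
    ("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G"),
}


def reverse_complement(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


@dataclass(frozen=True)
class CrosslinkSite:
    chrom: str
    position: int  # 0-based single base
    strand: str
    residue_count: int
    libraries: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.residue_count < 1:
            raise ValueError("residue_count must be >= 1")


@dataclass
class SiteSummary:
    n_sites: int
    n_residues: int


@dataclass
class PositionalProfile:
    """Per-offset values around an anchor at offset 0.

    ``values`` maps a track name (base letter or ``"pairing"``) to an
    array over ``offsets``.
    """

    offsets: np.ndarray
    values: dict[str, np.ndarray]
    n_anchors: int


def extract_deletion_sites(
    reads: Iterable[AlignedRead],
    collapse: str = "per-base",
) -> tuple[list[CrosslinkSite], SiteSummary]:
    """Call unique deletion-supported sites from CLIP reads.

    ``collapse="per-base"`` (default): every deleted base is a residue and
    every unique (chrom, strand, position) becomes one site.
    ``collapse="per-event"``: each deletion segment contributes a single
    residue anchored at its first base.
    """
    if collapse not in ("per-base", "per-event"):
        raise ValueError(f"unknown collapse mode {collapse!r}")
    residues: dict[tuple[str, str, int], int] = {}
    libs: dict[tuple[str, str, int], set[str]] = {}
    n_residues = 0
    for read in reads:
        for dstart, dend in read.deletion_blocks():
            positions = range(dstart, dend) if collapse == "per-base" else (dstart,)
            for pos in positions:
                key = (read.chrom, read.strand, pos)
                residues[key] = residues.get(key, 0) + 1
                libs.setdefault(key, set()).add(read.library)
                n_residues += 1
    sites = [
        CrosslinkSite(chrom, pos, strand, residues[(chrom, strand, pos)],
                      frozenset(libs[(chrom, strand, pos)]))
        for chrom, strand, pos in sorted(residues)
    ]
    return sites, SiteSummary(n_sites=len(sites), n_residues=n_residues)


def fetch_window(genome: Mapping[str, str], chrom: str, pos: int, flank: int, strand: str) -> str | None:
    """Strand-oriented sequence of length 2*flank+1 centred on pos; None at edges."""
    seq = genome[chrom]
    if pos - flank < 0 or pos + flank + 1 > len(seq):
        return None
    window = str(seq[pos - flank : pos + flank + 1]).upper()
    return reverse_complement(window) if strand == "-" else window


def base_composition_profile(
    sites: Sequence[CrosslinkSite],
    genome: Mapping[str, str],
    flank: int = 100,
) -> PositionalProfile:
    """Per-offset A/C/G/U fractions in +-flank windows around sites.

    Minus-strand windows are reverse-complemented so offset 0 is always
    the crosslinked base read 5'->3'.  Edge sites whose window leaves the
    chromosome are dropped with a logged count.
    """
    if not sites:
        raise ValueError("no sites supplied; composition profile undefined")
    width = 2 * flank + 1
    counts = {b: np.zeros(width, dtype=np.int64) for b in "ACGU"}
    kept = dropped = 0
    for site in sites:
        window = fetch_window(genome, site.chrom, site.position, flank, site.strand)
        if window is None:
            dropped += 1
            continue
        kept += 1
        arr = np.frombuffer(window.replace("T", "U").encode(), dtype=np.uint8)
        for base in "ACGU":
            counts[base] += arr == ord(base)
    if dropped:
        logger.info("dropped %d edge sites without a full +-%d window", dropped, flank)
    if kept == 0:
        raise ValueError("all sites fell on chromosome edges; no windows retained")
    total = sum(counts.values())
    total[total == 0] = 1
    return PositionalProfile(
        offsets=np.arange(-flank, flank + 1),
        values={b: counts[b] / total for b in "ACGU"},
        n_anchors=kept,
    )


# ---------------------------------------------------------------------------
# Maximum-base-pairing structure potential


def _pair_matrix(seq: str, min_loop: int) -> np.ndarray:
    rna = seq.upper().replace("T", "U")
    n = len(rna)
    pairable = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(i + min_loop + 1, n):
            if (rna[i], rna[j]) in _PAIRABLE:
                pairable[i, j] = True
    return pairable


def max_pairing_structure(seq: str, min_loop: int = 3) -> list[tuple[int, int]]:
    """Nussinov-style maximum base pairing over AU/GC/GU with a hairpin
    loop of at least ``min_loop`` unpaired bases.

    Returns the paired index list of one maximal structure; traceback ties
    are broken toward the leftmost pairing partner for determinism.
    """
    n = len(seq)
    if n < min_loop + 2:
        return []
    pairable = _pair_matrix(seq, min_loop)
    dp = np.zeros((n + 1, n + 1), dtype=np.int32)  # dp[i][j] over seq[i..j] inclusive
    for span in range(min_loop + 1, n):
        for i in range(0, n - span):
            j = i + span
            best = dp[i + 1, j]
            ks = np.nonzero(pairable[i, i + min_loop + 1 : j + 1])[0]
            if ks.size:
                ks = ks + i + min_loop + 1
                cand = 1 + dp[i + 1, ks - 1] + dp[ks + 1, j]
                best = max(best, int(cand.max()))
            dp[i, j] = best

    pairs: list[tuple[int, int]] = []
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if i >= j or dp[i, j] == 0:
            continue
        # pair i with its leftmost optimal partner if one exists, else skip i
        for k in range(i + min_loop + 1, j + 1):
            if pairable[i, k] and dp[i, j] == 1 + dp[i + 1, k - 1] + dp[k + 1, j]:
                pairs.append((i, k))
                stack.append((i + 1, k - 1))
                stack.append((k + 1, j))
                break
        else:
            stack.append((i + 1, j))
    return sorted(pairs)


def structure_potential_profile(
    windows: Sequence[str],
    min_loop: int = 3,
) -> PositionalProfile:
    """Fraction of windows in which each position is paired in the
    maximum-base-pairing structure (a proxy for local structure potential)."""
    if not windows:
        raise ValueError("no windows supplied")
    width = len(windows[0])
    if any(len(w) != width for w in windows):
        raise ValueError("windows must have uniform length")
    if width < 2 * (min_loop + 1):
        raise ValueError(f"windows of {width} nt too short (min loop {min_loop})")
    paired = np.zeros(width, dtype=np.int64)
    for w in windows:
        for i, j in max_pairing_structure(w, min_loop=min_loop):
            paired[i] += 1
            paired[j] += 1
    flank = width // 2
    return PositionalProfile(
        offsets=np.arange(width) - flank,
        values={"pairing": paired / len(windows)},
        n_anchors=len(windows),
    )
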