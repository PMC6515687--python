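"""Annotation and alignment model: GTF/SAM readers, region index, expression.

Internal coordinates are 0-based half-open throughout; GTF is read and
written as 1-based inclusive.  Region labels follow the fixed precedence
CDS > 3'UTR > 5'UTR > intron > intergenic so that every base resolves to
exactly one label.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

from targetome.intervals import GenomicInterval, IntervalIndex, merge_intervals

logger = logging.getLogger(__name__)

# Region label codes, ascending precedence (painting order).
INTERGENIC, INTRON, UTR5, UTR3, CDS = 0, 1, 2, 3, 4
REGION_NAMES = {INTERGENIC: "intergenic", INTRON: "intron", UTR5: "utr5", UTR3: "utr3", CDS: "cds"}
REGION_CODES = {v: k for k, v in REGION_NAMES.items()}

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")
_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


class GtfParseError(ValueError):
    pass


@dataclass
class TranscriptModel:
    """One transcript: exons plus CDS-derived UTR and intron structure."""

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: list[GenomicInterval]
    cds: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.exons = sorted(self.exons, key=lambda iv: iv.start)
        self.cds = sorted(self.cds, key=lambda iv: iv.start)
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start < a.end:
                raise ValueError(f"overlapping exons in transcript {self.transcript_id}")
        for iv in self.exons + self.cds:
            if iv.strand != self.strand or iv.chrom != self.chrom:
                raise ValueError(f"strand/chrom mismatch in transcript {self.transcript_id}")

    @property
    def start(self) -> int:
        return self.exons[0].start

    @property
    def end(self) -> int:
        return self.exons[-1].end

    @property
    def exonic_length(self) -> int:
        return sum(len(e) for e in self.exons)

    @property
    def introns(self) -> list[GenomicInterval]:
        out = []
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start > a.end:
                out.append(GenomicInterval(self.chrom, a.end, b.start, self.strand))
        return out

    def _exonic_clip(self, lo: int, hi: int) -> list[GenomicInterval]:
        out = []
        for e in self.exons:
            s, t = max(e.start, lo), min(e.end, hi)
            if s < t:
                out.append(GenomicInterval(self.chrom, s, t, self.strand))
        return out

    @property
    def utr5(self) -> list[GenomicInterval]:
        if not self.cds:
            return []
        if self.strand == "+":
            return self._exonic_clip(self.start, self.cds[0].start)
        return self._exonic_clip(self.cds[-1].end, self.end)

    @property
    def utr3(self) -> list[GenomicInterval]:
        if not self.cds:
            return []
        if self.strand == "+":
            return self._exonic_clip(self.cds[-1].end, self.end)
        return self._exonic_clip(self.start, self.cds[0].start)

    @property
    def utr3_length(self) -> int:
        return sum(len(iv) for iv in self.utr3)

    def genomic_to_transcript(self, pos: int) -> int | None:
        """Map a genomic base to 5'->3' transcript coordinates; None if intronic."""
        offset = 0
        for e in self.exons:
            if e.start <= pos < e.end:
                tx = offset + (pos - e.start)
                return tx if self.strand == "+" else self.exonic_length - 1 - tx
            offset += len(e)
        return None


class GenomeAnnotation:
    """Transcript collection with a per-base region index.

    ``chrom_lengths`` may be supplied (e.g. from a FASTA index); otherwise
    each chromosome is sized to its furthest annotated base.
    """

    def __init__(
        self,
        transcripts: Sequence[TranscriptModel],
        chrom_lengths: dict[str, int] | None = None,
    ):
        self.transcripts: dict[str, TranscriptModel] = {
            t.transcript_id: t for t in transcripts
        }
        self.genes: dict[str, list[str]] = {}
        for t in transcripts:
            self.genes.setdefault(t.gene_id, []).append(t.transcript_id)
        self.chrom_lengths = dict(chrom_lengths or {})
        for t in transcripts:
            need = t.end
            if self.chrom_lengths.get(t.chrom, 0) < need:
                self.chrom_lengths[t.chrom] = need
        self._region_arrays: dict[tuple[str, str], np.ndarray] = {}
        self._exon_index: dict[tuple[str, str], IntervalIndex] | None = None

    # -- region index ------------------------------------------------------

    def region_array(self, chrom: str, strand: str) -> np.ndarray:
        """uint8 label array for one chromosome strand (lazy, cached)."""
        key = (chrom, strand)
        if key not in self._region_arrays:
            arr = np.zeros(self.chrom_lengths.get(chrom, 0), dtype=np.uint8)
            for t in self.transcripts.values():
                if t.chrom != chrom or t.strand != strand:
                    continue
                for iv in t.introns:
                    arr[iv.start : iv.end] = np.maximum(arr[iv.start : iv.end], INTRON)
            # paint in ascending precedence so higher labels win
            for code, getter in ((UTR5, "utr5"), (UTR3, "utr3"), (CDS, "cds")):
                for t in self.transcripts.values():
                    if t.chrom != chrom or t.strand != strand:
                        continue
                    for iv in getattr(t, getter):
                        arr[iv.start : iv.end] = np.maximum(arr[iv.start : iv.end], code)
            self._region_arrays[key] = arr
        return self._region_arrays[key]

    def region_of(self, chrom: str, pos: int, strand: str) -> str:
        arr = self.region_array(chrom, strand)
        if pos >= len(arr):
            return "intergenic"
        return REGION_NAMES[int(arr[pos])]

    # -- exon overlap index ------------------------------------------------

    def exon_index(self) -> dict[tuple[str, str], IntervalIndex]:
        if self._exon_index is None:
            raw: dict[tuple[str, str], list[tuple[int, int, str]]] = {}
            for t in self.transcripts.values():
                for e in t.exons:
                    raw.setdefault((t.chrom, t.strand), []).append(
                        (e.start, e.end, t.transcript_id)
                    )
            self._exon_index = {k: IntervalIndex(v) for k, v in raw.items()}
        return self._exon_index

    def transcripts_overlapping(self, read: "AlignedRead") -> set[str]:
        """Transcript ids whose exons overlap the read's matched bases (same strand)."""
        idx = self.exon_index().get((read.chrom, read.strand))
        if idx is None:
            return set()
        hits: set[str] = set()
        for s, e in read.match_blocks():
            for _, _, tid in idx.query(s, e):
                hits.add(tid)
        return hits


# ---------------------------------------------------------------------------
# GTF I/O


def _parse_attrs(attr_field: str) -> dict[str, str]:
    return dict(_ATTR_RE.findall(attr_field))


def parse_gtf(path: str | Path, chrom_lengths: dict[str, int] | None = None) -> GenomeAnnotation:
    """Read an Ensembl-dialect GTF into a :class:`GenomeAnnotation`.

    Exon and CDS features are used; UTRs and introns are derived.  Raises
    :class:`GtfParseError` naming the offending line on malformed input.
    """
    exons: dict[str, list[GenomicInterval]] = {}
    cds: dict[str, list[GenomicInterval]] = {}
    meta: dict[str, tuple[str, str, str]] = {}  # tid -> (gene, chrom, strand)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GtfParseError(f"{path}:{lineno}: expected 9 fields, got {len(fields)}")
            chrom, _, feature, start_s, end_s, _, strand, _, attrs_s = fields
            if feature not in ("exon", "CDS"):
                continue
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError as exc:
                raise GtfParseError(f"{path}:{lineno}: non-integer coordinate") from exc
            if end1 < start1:
                raise GtfParseError(f"{path}:{lineno}: end < start")
            attrs = _parse_attrs(attrs_s)
            if "gene_id" not in attrs or "transcript_id" not in attrs:
                raise GtfParseError(f"{path}:{lineno}: missing gene_id/transcript_id")
            tid = attrs["transcript_id"]
            iv = GenomicInterval(chrom, start1 - 1, end1, strand)
            meta.setdefault(tid, (attrs["gene_id"], chrom, strand))
            (exons if feature == "exon" else cds).setdefault(tid, []).append(iv)
    transcripts = [
        TranscriptModel(tid, gene, chrom, strand, exons.get(tid, []), cds.get(tid, []))
        for tid, (gene, chrom, strand) in meta.items()
        if tid in exons
    ]
    return GenomeAnnotation(transcripts, chrom_lengths=chrom_lengths)


def write_gtf(annotation: GenomeAnnotation, path: str | Path) -> None:
    """Write exon and CDS features back out as 1-based inclusive GTF."""
    with open(path, "w") as fh:
        for tid in sorted(annotation.transcripts):
            t = annotation.transcripts[tid]
            attrs = f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}";'
            for feature, ivs in (("exon", t.exons), ("CDS", t.cds)):
                for iv in ivs:
                    fh.write(
                        f"{t.chrom}\ttargetome\t{feature}\t{iv.start + 1}\t{iv.end}\t.\t"
                        f"{t.strand}\t.\t{attrs}\n"
                    )


# ---------------------------------------------------------------------------
# Alignments


def parse_cigar(cigar: str) -> list[tuple[str, int]]:
    """CIGAR string -> [(op, length)] with ops match/insertion/deletion/skip.

    ``M``, ``=`` and ``X`` collapse to ``match``; soft/hard clips are
    dropped (they consume no reference).
    """
    if not cigar or cigar == "*":
        raise ValueError("missing CIGAR")
    segments: list[tuple[str, int]] = []
    pos = 0
    for m in _CIGAR_RE.finditer(cigar):
        pos = m.end()
        n, op = int(m.group(1)), m.group(2)
        if op in "M=X":
            segments.append(("match", n))
        elif op == "I":
            segments.append(("insertion", n))
        elif op == "D":
            segments.append(("deletion", n))
        elif op == "N":
            segments.append(("skip", n))
        # S, H, P: no reference footprint
    if pos != len(cigar):
        raise ValueError(f"malformed CIGAR {cigar!r}")
    return segments


@dataclass
class AlignedRead:
    """Strand-aware alignment with reference segments parsed from CIGAR."""

    read_id: str
    chrom: str
    start: int  # 0-based leftmost reference position
    strand: str
    segments: list[tuple[str, int]]
    library: str = "lib"

    def __post_init__(self) -> None:
        if not any(op == "match" for op, _ in self.segments):
            raise ValueError(f"read {self.read_id}: no match segment")

    @property
    def reference_span(self) -> int:
        return sum(n for op, n in self.segments if op in ("match", "deletion", "skip"))

    @property
    def end(self) -> int:
        return self.start + self.reference_span

    def _blocks(self, which: str) -> list[tuple[int, int]]:
        out, pos = [], self.start
        for op, n in self.segments:
            if op == which:
                out.append((pos, pos + n))
            if op in ("match", "deletion", "skip"):
                pos += n
        return out

    def match_blocks(self) -> list[tuple[int, int]]:
        return self._blocks("match")

    def deletion_blocks(self) -> list[tuple[int, int]]:
        return self._blocks("deletion")

    def skip_blocks(self) -> list[tuple[int, int]]:
        return self._blocks("skip")

    @property
    def aligned_length(self) -> int:
        return sum(n for op, n in self.segments if op == "match")


def _parse_sam(path: Path, library: str | None, min_mapq: int) -> Iterator[AlignedRead]:
    import pysam

    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            if rec.mapping_quality < min_mapq:
                continue
            if rec.has_tag("NH") and rec.get_tag("NH") > 1:
                continue
            segments = parse_cigar(rec.cigarstring)
            lib = library
            if lib is None:
                lib = rec.get_tag("RG") if rec.has_tag("RG") else path.stem
            yield AlignedRead(
                read_id=rec.query_name,
                chrom=rec.reference_name,
                start=rec.reference_start,
                strand="-" if rec.is_reverse else "+",
                segments=segments,
                library=lib,
            )


def _parse_tabular(path: Path, library: str | None) -> Iterator[AlignedRead]:
    # documented dialect: read_id <TAB> chrom <TAB> start(0-based) <TAB> strand <TAB> CIGAR [<TAB> library]
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) not in (5, 6):
                raise ValueError(f"{path}:{lineno}: expected 5 or 6 fields")
            read_id, chrom, start_s, strand, cigar = fields[:5]
            lib = fields[5] if len(fields) == 6 else (library or path.stem)
            yield AlignedRead(
                read_id=read_id,
                chrom=chrom,
                start=int(start_s),
                strand=strand,
                segments=parse_cigar(cigar),
                library=library or lib,
            )


def parse_alignments(
    path: str | Path,
    library: str | None = None,
    min_mapq: int = 1,
    chrom_lengths: dict[str, int] | None = None,
) -> list[AlignedRead]:
    """Read a SAM file or the tabular alignment dialect into AlignedReads.

    Unmapped, secondary, supplementary and multi-mapping records (MAPQ
    below ``min_mapq`` or NH > 1) are dropped.  If ``chrom_lengths`` is
    given, reads whose reference span exceeds the declared chromosome
    length raise a validation error.
    """
    path = Path(path)
    if path.suffix.lower() == ".sam":
        reads = list(_parse_sam(path, library, min_mapq))
    else:
        reads = list(_parse_tabular(path, library))
    if chrom_lengths:
        for r in reads:
            limit = chrom_lengths.get(r.chrom)
            if limit is not None and r.end > limit:
                raise ValueError(
                    f"read {r.read_id}: reference span [{r.start},{r.end}) exceeds "
                    f"{r.chrom} length {limit}"
                )
    return reads


def write_sam(reads: Iterable[AlignedRead], chrom_lengths: dict[str, int], path: str | Path) -> None:
    """Write reads as headered SAM (sequences emitted as N runs)."""
    op_codes = {"match": "M", "insertion": "I", "deletion": "D", "skip": "N"}
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unknown\n")
        for chrom in sorted(chrom_lengths):
            fh.write(f"@SQ\tSN:{chrom}\tLN:{chrom_lengths[chrom]}\n")
        for r in reads:
            cigar = "".join(f"{n}{op_codes[op]}" for op, n in r.segments)
            qlen = sum(n for op, n in r.segments if op in ("match", "insertion"))
            flag = 16 if r.strand == "-" else 0
            fh.write(
                f"{r.read_id}\t{flag}\t{r.chrom}\t{r.start + 1}\t255\t{cigar}\t*\t0\t0\t"
                f"{'N' * qlen}\t*\tRG:Z:{r.library}\n"
            )


def write_tabular(reads: Iterable[AlignedRead], path: str | Path) -> None:
    op_codes = {"match": "M", "insertion": "I", "deletion": "D", "skip": "N"}
    with open(path, "w") as fh:
        for r in reads:
            cigar = "".join(f"{n}{op_codes[op]}" for op, n in r.segments)
            fh.write(f"{r.read_id}\t{r.chrom}\t{r.start}\t{r.strand}\t{cigar}\t{r.library}\n")


# ---------------------------------------------------------------------------
# Expression


@dataclass
class TranscriptQuant:
    transcript_id: str
    count: int
    fpkm: float
    tpm: float
    library: str


def compute_expression(
    reads: Iterable[AlignedRead],
    annotation: GenomeAnnotation,
    level: str = "transcript",
) -> dict[str, dict[str, TranscriptQuant]]:
    """Per-library FPKM/TPM by counting same-strand exonic overlaps >= 1 nt.

    Each fragment counts once toward every overlapping transcript (no
    isoform deconvolution).  Returns ``{library: {transcript_id: quant}}``.
    With ``level="gene"`` counting is collapsed to one representative per
    gene (union of exon overlaps).
    """
    if level not in ("transcript", "gene"):
        raise ValueError(f"unknown counting level {level!r}")
    counts: dict[str, dict[str, int]] = {}
    totals: dict[str, int] = {}
    tid_to_gene = {tid: t.gene_id for tid, t in annotation.transcripts.items()}
    for read in reads:
        hits = annotation.transcripts_overlapping(read)
        if level == "gene":
            hits = {tid_to_gene[t] for t in hits}
        lib = read.library
        totals[lib] = totals.get(lib, 0) + 1
        if hits:
            per_lib = counts.setdefault(lib, {})
            for key in hits:
                per_lib[key] = per_lib.get(key, 0) + 1

    if level == "gene":
        lengths = {
            gid: sum(e1 - e0 for e0, e1 in merge_intervals(
                (e.start, e.end)
                for tid in tids
                for e in annotation.transcripts[tid].exons
            ))
            for gid, tids in annotation.genes.items()
        }
        ids = sorted(annotation.genes)
    else:
        lengths = {tid: t.exonic_length for tid, t in annotation.transcripts.items()}
        ids = sorted(annotation.transcripts)

    result: dict[str, dict[str, TranscriptQuant]] = {}
    for lib in sorted(totals):
        per_lib = counts.get(lib, {})
        total = sum(per_lib.values())
        if total == 0:
            logger.warning("library %s: no fragments overlap any transcript", lib)
        rates = {i: per_lib.get(i, 0) / lengths[i] for i in ids if lengths[i] > 0}
        rate_sum = sum(rates.values())
        result[lib] = {}
        for i in ids:
            n = per_lib.get(i, 0)
            fpkm = n * 1e9 / (total * lengths[i]) if total and lengths[i] else 0.0
            tpm = rates.get(i, 0.0) / rate_sum * 1e6 if rate_sum else 0.0
            result[lib][i] = TranscriptQuant(i, n, fpkm, tpm, lib)
    return result


def select_bound_transcripts(
    quant: dict[str, dict[str, TranscriptQuant]],
    fpkm_min: float = 0.5,
    min_libraries: int = 2,
) -> set[str]:
    """Transcripts with FPKM >= ``fpkm_min`` in at least ``min_libraries`` libraries."""
    if min_libraries > len(quant):
        raise ValueError(
            f"min_libraries={min_libraries} exceeds number of libraries ({len(quant)})"
        )
    ids: set[str] = set()
    for per_lib in quant.values():
        ids.update(per_lib)
    return {
        tid
        for tid in ids
        if sum(1 for per_lib in quant.values() if per_lib.get(tid) and per_lib[tid].fpkm >= fpkm_min)
        >= min_libraries
    }
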