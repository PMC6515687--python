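"""Synthetic genome, annotation and read simulator with planted ground truth.

Everything downstream of alignment can be exercised offline: the generator
plants crosslink sites (with reverse-transcription deletions), miRNA
hairpins in intronic / 3'UTR / intergenic contexts, per-condition miRNA
transcript levels, intron-retention fractions, and a small-RNA length
distribution.  The planted values are recorded in a SyntheticTruth object
that test suites use as the oracle.

All randomness flows through numpy Generators seeded from the config;
identical seeds produce byte-identical output files.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from targetome.genome_model import (
    AlignedRead,
    GenomeAnnotation,
    TranscriptModel,
    write_gtf,
    write_sam,
    write_tabular,
)
from targetome.intervals import GenomicInterval
from targetome.mirna_targetome import MirnaHairpin, write_mirna_gff3

BASES = np.array(list("ACGT"))
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _revcomp(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


# ---------------------------------------------------------------------------
# Configuration


@dataclass
class SimulationConfig:
    seed: int = 0
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"chr1": 70000, "chr2": 50000}
    )
    # gene models
    n_genes: int = 10
    exons_per_gene: tuple[int, int] = (2, 4)
    exon_length: tuple[int, int] = (300, 800)
    intron_length: tuple[int, int] = (600, 1500)
    utr5_length: int = 100
    utr3_length: tuple[int, int] = (100, 800)
    gene_spacing: int = 800
    intron_at_fraction: float = 0.70  # AT richness of intronic sequence
    # miRNA hairpins
    n_mirna_intronic: int = 3
    n_mirna_utr3: int = 2
    n_mirna_intergenic: int = 2
    hairpin_arm: int = 25
    hairpin_loop: int = 12
    mature_length: int = 22
    mature_offset: int = 2  # nt between hairpin 5' end and mature start
    # planted crosslink sites
    n_sites_utr3: int = 8
    n_sites_intron_5ss: int = 4
    n_sites_intron_3ss: int = 5
    splice_site_offset: int = 50  # nt into the intron from the splice site
    utr3_bias_exponent: float = 2.0  # site placement weight ~ utr3_len ** exponent
    gc_island: bool = True  # write a GC-rich patch around planted sites
    gc_island_halfwidth: int = 5
    # CLIP simulation
    clip_reads_per_site: int = 10
    clip_deletion_prob: float = 0.8
    clip_deletion_length: int = 1
    clip_read_length: tuple[int, int] = (25, 40)
    clip_background_reads: int = 300
    clip_intergenic_fraction: float = 0.1
    clip_hairpin_reads: int = 200
    category_weights: dict[str, float] = field(
        default_factory=lambda: {"I": 0.1, "II": 0.15, "III": 0.15, "IV": 0.3, "V": 0.3}
    )
    hairpin_flank: int = 100
    # RNA-seq simulation
    rnaseq_read_length: int = 100
    mirna_window_reads: int = 300  # expected window reads at level 1.0
    intron_informative_reads: int = 500  # expected informative reads at level 1.0
    rnaseq_background_per_transcript: int = 30
    mirna_control_level: tuple[float, float] = (0.8, 1.6)
    kd_ratio_cycle: tuple[float, ...] = (0.25, 0.5, 1.0, 2.0)
    pir_control: tuple[float, float] = (0.1, 0.5)
    pir_knockdown_shift: float = 0.3  # knockdown PIR = min(0.95, control + shift)
    long_isoform_fraction: dict[str, float] = field(
        default_factory=lambda: {"control": 0.7, "knockdown": 0.4}
    )
    long_isoform_coverage: float = 60.0
    long_isoform_read_length: int = 30
    # small RNA
    smallrna_n_reads: int = 5000
    # invariant non-miRNA small-RNA species, as a multiple of the control-
    # condition mature total; anchors TPM so global shifts stay visible
    smallrna_background_weight: float = 4.0
    smallrna_length_dist: dict[int, float] = field(
        default_factory=lambda: {19: 0.03, 20: 0.05, 21: 0.12, 22: 0.42, 23: 0.18,
                                 24: 0.08, 25: 0.05, 28: 0.03, 30: 0.04}
    )
    # repeats / clusters
    n_repeats: int = 6
    repeat_families: tuple[str, ...] = ("LINE1", "LTR", "SINE")
    repeat_length: int = 400
    n_clusters: int = 2
    cluster_length: int = 2000

    def validate(self) -> None:
        if not 0.0 <= self.clip_deletion_prob <= 1.0:
            raise ValueError("clip_deletion_prob must be in [0, 1]")
        if not 0.0 <= self.intron_at_fraction <= 1.0:
            raise ValueError("intron_at_fraction must be in [0, 1]")
        for lo, hi in (self.pir_control,):
            if not (0.0 <= lo <= hi <= 1.0):
                raise ValueError("pir_control bounds must be in [0, 1]")
        if abs(sum(self.smallrna_length_dist.values()) - 1.0) > 1e-6:
            raise ValueError("smallrna_length_dist must sum to 1")
        if abs(sum(self.category_weights.values()) - 1.0) > 1e-6:
            raise ValueError("category_weights must sum to 1")
        for frac in self.long_isoform_fraction.values():
            if not 0.0 <= frac <= 1.0:
                raise ValueError("long_isoform_fraction values must be in [0, 1]")


# ---------------------------------------------------------------------------
# Truth bookkeeping


@dataclass
class PlantedSite:
    chrom: str
    position: int
    strand: str
    context: str  # utr3 / intron_5ss / intron_3ss
    splice_offset: int | None = None


@dataclass
class SyntheticTruth:
    sites: list[PlantedSite] = field(default_factory=list)
    hairpin_contexts: dict[str, str] = field(default_factory=dict)
    mirna_levels: dict[str, dict[str, float]] = field(default_factory=dict)
    mature_levels: dict[str, dict[str, float]] = field(default_factory=dict)
    tx_levels: dict[str, float] = field(default_factory=dict)
    intron_pir: dict[str, dict[str, float]] = field(default_factory=dict)
    mirtron_introns: dict[str, GenomicInterval] = field(default_factory=dict)
    long_isoform: dict = field(default_factory=dict)
    clip_read_info: dict[str, dict] = field(default_factory=dict)

    def to_json(self) -> str:
        def default(o):
            if isinstance(o, GenomicInterval):
                return [o.chrom, o.start, o.end, o.strand]
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            raise TypeError(type(o))

        return json.dumps(dataclasses.asdict(self), default=default, indent=1, sort_keys=True)


@dataclass
class SyntheticDataset:
    config: SimulationConfig
    sequences: dict[str, str]
    annotation: GenomeAnnotation
    hairpins: list[MirnaHairpin]
    repeats: list[tuple[GenomicInterval, str]]
    clusters: list[tuple[GenomicInterval, str]]
    truth: SyntheticTruth

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        fa = outdir / "genome.fa"
        with open(fa, "w") as fh:
            for chrom in sorted(self.sequences):
                fh.write(f">{chrom}\n")
                seq = self.sequences[chrom]
                for i in range(0, len(seq), 70):
                    fh.write(seq[i : i + 70] + "\n")
        paths["fasta"] = fa
        gtf = outdir / "genes.gtf"
        write_gtf(self.annotation, gtf)
        paths["gtf"] = gtf
        gff = outdir / "mirna.gff3"
        write_mirna_gff3(self.hairpins, gff)
        paths["mirna_gff3"] = gff
        for name, feats in (("repeats", self.repeats), ("clusters", self.clusters)):
            bed = outdir / f"{name}.bed"
            with open(bed, "w") as fh:
                for iv, label in feats:
                    fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{label}\t0\t{iv.strand}\n")
            paths[name] = bed
        tj = outdir / "truth.json"
        tj.write_text(self.truth.to_json())
        paths["truth"] = tj
        return paths


# ---------------------------------------------------------------------------
# Genome generation


def _tx_range_to_genomic(
    exons: Sequence[GenomicInterval], strand: str, tx_start: int, tx_end: int
) -> list[GenomicInterval]:
    """Convert a transcript-coordinate range to genomic intervals."""
    walk = list(exons) if strand == "+" else list(reversed(exons))
    out = []
    offset = 0
    for e in walk:
        lo, hi = offset, offset + len(e)
        s, t = max(lo, tx_start), min(hi, tx_end)
        if s < t:
            if strand == "+":
                out.append(GenomicInterval(e.chrom, e.start + (s - lo), e.start + (t - lo), strand))
            else:
                out.append(GenomicInterval(e.chrom, e.end - (t - lo), e.end - (s - lo), strand))
        offset = hi
    return sorted(out, key=lambda iv: iv.start)


def generate_genome(config: SimulationConfig) -> SyntheticDataset:
    """Build the toy genome: sequences, gene models, hairpins, repeats,
    clusters and the planted-truth skeleton."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    truth = SyntheticTruth()

    chroms = sorted(config.chrom_lengths)
    seqs = {c: rng.choice(BASES, size=config.chrom_lengths[c]) for c in chroms}

    # ---- gene placement -------------------------------------------------
    transcripts: list[TranscriptModel] = []
    cursors = {c: config.gene_spacing for c in chroms}
    chrom_cycle = 0
    placed = 0
    for g in range(config.n_genes):
        n_ex = int(rng.integers(config.exons_per_gene[0], config.exons_per_gene[1] + 1))
        exon_lens = [int(rng.integers(*config.exon_length)) for _ in range(n_ex)]
        intron_lens = [int(rng.integers(*config.intron_length)) for _ in range(n_ex - 1)]
        utr3_len = int(rng.integers(*config.utr3_length))
        if g == 0:
            utr3_len = 600  # long-isoform demonstration gene
        if g in (1, 2):
            utr3_len = 450  # hosts for 3'UTR-embedded hairpins
        strand = "+" if g % 2 == 0 else "-"
        # keep the whole 3'UTR inside the transcript-last exon
        last = -1 if strand == "+" else 0
        exon_lens[last] = max(exon_lens[last], utr3_len + 120)
        span = sum(exon_lens) + sum(intron_lens)

        # first chromosome with room wins; error when none fits
        for _ in range(len(chroms)):
            chrom = chroms[chrom_cycle % len(chroms)]
            if cursors[chrom] + span + config.gene_spacing <= config.chrom_lengths[chrom]:
                break
            chrom_cycle += 1
        else:
            raise ValueError(
                f"gene {g} (span {span}) does not fit on any chromosome; "
                "increase chrom_lengths or reduce n_genes"
            )
        start = cursors[chrom]
        cursors[chrom] = start + span + config.gene_spacing
        chrom_cycle += 1

        exons = []
        pos = start
        for i, elen in enumerate(exon_lens):
            exons.append(GenomicInterval(chrom, pos, pos + elen, strand))
            pos += elen
            if i < n_ex - 1:
                pos += intron_lens[i]
        exonic = sum(exon_lens)
        cds_tx = (config.utr5_length, exonic - utr3_len)
        cds = _tx_range_to_genomic(exons, strand, *cds_tx)
        tid, gid = f"t{g:03d}", f"g{g:03d}"
        transcripts.append(TranscriptModel(tid, gid, chrom, strand, exons, cds))
        placed += 1

    annotation = GenomeAnnotation(transcripts, chrom_lengths=dict(config.chrom_lengths))

    # AT-biased intron sequence (splice-flank composition signal)
    at = config.intron_at_fraction / 2
    gc = (1 - config.intron_at_fraction) / 2
    for t in transcripts:
        for iv in t.introns:
            n = len(iv)
            seqs[t.chrom][iv.start : iv.end] = rng.choice(
                BASES, size=n, p=[at, gc, gc, at]
            )

    # ---- hairpins --------------------------------------------------------
    hp_len = 2 * config.hairpin_arm + config.hairpin_loop
    hairpins: list[MirnaHairpin] = []
    win_margin = config.hairpin_flank + 60  # keep category-read windows inside the host region

    def _plant_hairpin(chrom: str, start: int, strand: str, mid: str, context: str) -> None:
        arm = "".join(rng.choice(BASES, size=config.hairpin_arm))
        loop = "".join(rng.choice(BASES, size=config.hairpin_loop))
        stem_seq = arm + loop + _revcomp(arm)
        seqs[chrom][start : start + hp_len] = np.array(list(stem_seq))
        hairpin = GenomicInterval(chrom, start, start + hp_len, strand)
        if strand == "+":
            m0 = start + config.mature_offset
        else:
            m0 = start + hp_len - config.mature_offset - config.mature_length
        mature = GenomicInterval(chrom, m0, m0 + config.mature_length, strand)
        hairpins.append(MirnaHairpin(mid, hairpin, (mature,), host_context=context))
        truth.hairpin_contexts[mid] = context

    mirna_idx = 0
    intronic_host_introns: list[GenomicInterval] = []
    host_introns = [
        (t, iv)
        for t in transcripts
        for iv in t.introns
        if len(iv) >= hp_len + 2 * win_margin
    ]
    for k in range(config.n_mirna_intronic):
        t, intron = host_introns[k % len(host_introns)]
        start = intron.start + win_margin + (k // len(host_introns)) * (hp_len + 10)
        mid = f"mir{mirna_idx:03d}"
        _plant_hairpin(t.chrom, start, t.strand, mid, "intronic")
        truth.mirtron_introns[mid] = intron
        intronic_host_introns.append(intron)
        mirna_idx += 1

    # gene 0 is reserved for the long-isoform demonstration; keep its 3'UTR clean
    utr3_hosts = [
        (t, iv)
        for t in transcripts[1:]
        for iv in t.utr3
        if len(iv) >= hp_len + 2 * win_margin
    ]
    for k in range(config.n_mirna_utr3):
        t, u = utr3_hosts[k % len(utr3_hosts)]
        start = u.start + win_margin
        _plant_hairpin(t.chrom, start, t.strand, f"mir{mirna_idx:03d}", "3utr")
        mirna_idx += 1

    # intergenic: the untouched tail of each chromosome past the gene cursor
    for k in range(config.n_mirna_intergenic):
        chrom = chroms[k % len(chroms)]
        tail = cursors[chrom]
        start = tail + win_margin + k * (hp_len + 2 * win_margin)
        if start + hp_len + win_margin > config.chrom_lengths[chrom]:
            raise ValueError("no intergenic room for hairpins; enlarge chromosomes")
        _plant_hairpin(chrom, start, "+" if k % 2 == 0 else "-", f"mir{mirna_idx:03d}", "intergenic")
        mirna_idx += 1

    # ---- planted crosslink sites ----------------------------------------
    hp_exclusion = [hp.window(config.hairpin_flank + 60) for hp in hairpins]
    utr3_pool = [
        (t, iv)
        for t in transcripts
        for iv in t.utr3
        if len(iv) >= 100 and not any(iv.overlaps(w) for w in hp_exclusion)
    ]
    weights = np.array([t.utr3_length ** config.utr3_bias_exponent for t, _ in utr3_pool], dtype=float)
    weights /= weights.sum()
    used_positions: set[tuple[str, int]] = set()
    for _ in range(config.n_sites_utr3):
        for _attempt in range(50):
            i = int(rng.choice(len(utr3_pool), p=weights))
            t, iv = utr3_pool[i]
            pos = int(rng.integers(iv.start + 46, iv.end - 46))
            if (t.chrom, pos) not in used_positions:
                break
        used_positions.add((t.chrom, pos))
        truth.sites.append(PlantedSite(t.chrom, pos, t.strand, "utr3"))

    # intronic sites at a fixed offset from each splice site; hairpin-free introns preferred
    free_introns = [
        (t, iv)
        for t in transcripts
        for iv in t.introns
        if len(iv) >= 2 * config.splice_site_offset + 100
        and not any(iv.overlaps(h) for h in intronic_host_introns)
    ]
    off = config.splice_site_offset
    for j in range(config.n_sites_intron_5ss):
        t, iv = free_introns[j % len(free_introns)]
        pos = iv.start + off - 1 if t.strand == "+" else iv.end - off
        if (t.chrom, pos) in used_positions:
            continue
        used_positions.add((t.chrom, pos))
        truth.sites.append(PlantedSite(t.chrom, pos, t.strand, "intron_5ss", splice_offset=off))
    for j in range(config.n_sites_intron_3ss):
        t, iv = free_introns[(j + 1) % len(free_introns)]
        pos = iv.end - off if t.strand == "+" else iv.start + off - 1
        if (t.chrom, pos) in used_positions:
            continue
        used_positions.add((t.chrom, pos))
        truth.sites.append(PlantedSite(t.chrom, pos, t.strand, "intron_3ss", splice_offset=off))

    if config.gc_island:
        w = config.gc_island_halfwidth
        for site in truth.sites:
            patch = rng.choice(np.array(list("GC")), size=2 * w + 1)
            seqs[site.chrom][site.position - w : site.position + w + 1] = patch

    # ---- planted expression / retention parameters ----------------------
    for i, t in enumerate(sorted(transcripts, key=lambda t: t.transcript_id)):
        truth.tx_levels[t.transcript_id] = float(rng.uniform(0.5, 2.0))
    for i, hp in enumerate(hairpins):
        control = float(rng.uniform(*config.mirna_control_level))
        ratio = config.kd_ratio_cycle[i % len(config.kd_ratio_cycle)]
        truth.mirna_levels[hp.mirna_id] = {
            "control": control,
            "knockdown": control * ratio,
        }
        m_control = float(rng.uniform(20.0, 60.0))
        truth.mature_levels[hp.mirna_id] = {
            "control": m_control,
            "knockdown": m_control * ratio,
        }
    for mid, intron in sorted(truth.mirtron_introns.items()):
        p = float(rng.uniform(*config.pir_control))
        truth.intron_pir[mid] = {
            "control": p,
            "knockdown": min(0.95, p + config.pir_knockdown_shift),
        }

    # long-isoform regions on gene 0 (3'UTR split into shared + unique halves)
    t0 = transcripts[0]
    u3 = t0.utr3[-1] if t0.strand == "+" else t0.utr3[0]
    half = len(u3) // 2
    if t0.strand == "+":
        shared = GenomicInterval(u3.chrom, u3.start, u3.start + half, t0.strand)
        unique = GenomicInterval(u3.chrom, u3.start + half, u3.end, t0.strand)
    else:
        shared = GenomicInterval(u3.chrom, u3.end - half, u3.end, t0.strand)
        unique = GenomicInterval(u3.chrom, u3.start, u3.end - half, t0.strand)
    truth.long_isoform = {
        "gene": t0.gene_id,
        "shared": shared,
        "unique": unique,
        "fraction": dict(config.long_isoform_fraction),
    }

    # ---- repeats and clusters -------------------------------------------
    repeats = []
    for i in range(config.n_repeats):
        chrom = chroms[i % len(chroms)]
        start = int(rng.integers(0, config.chrom_lengths[chrom] - config.repeat_length))
        fam = config.repeat_families[i % len(config.repeat_families)]
        repeats.append(
            (GenomicInterval(chrom, start, start + config.repeat_length, "."), fam)
        )
    clusters = []
    for i in range(config.n_clusters):
        chrom = chroms[i % len(chroms)]
        start = max(0, config.chrom_lengths[chrom] - (i + 1) * (config.cluster_length + 500))
        clusters.append(
            (GenomicInterval(chrom, start, start + config.cluster_length, "."), f"cluster{i + 1}")
        )

    return SyntheticDataset(
        config=config,
        sequences={c: "".join(seqs[c]) for c in chroms},
        annotation=annotation,
        hairpins=hairpins,
        repeats=repeats,
        clusters=clusters,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# CLIP simulation


def _region_intervals(annotation: GenomeAnnotation) -> list[tuple[GenomicInterval, str]]:
    out = []
    for t in annotation.transcripts.values():
        for iv in t.utr5:
            out.append((iv, "utr5"))
        for iv in t.cds:
            out.append((iv, "cds"))
        for iv in t.utr3:
            out.append((iv, "utr3"))
        for iv in t.introns:
            out.append((iv, "intron"))
    return sorted(out, key=lambda x: (x[0].chrom, x[0].start, x[0].end))


def _intergenic_gaps(dataset: SyntheticDataset, margin: int = 200) -> list[GenomicInterval]:
    """Chromosome stretches clear of transcripts AND hairpin windows."""
    blocked: dict[str, list[tuple[int, int]]] = {c: [] for c in dataset.sequences}
    for t in dataset.annotation.transcripts.values():
        blocked[t.chrom].append((t.start - margin, t.end + margin))
    for hp in dataset.hairpins:
        w = hp.window(dataset.config.hairpin_flank + margin)
        blocked[w.chrom].append((w.start, w.end))
    gaps = []
    for chrom, spans in blocked.items():
        length = dataset.config.chrom_lengths[chrom]
        pos = 0
        for s, e in sorted(spans):
            if s - pos >= 300:
                gaps.append(GenomicInterval(chrom, pos, s, "+"))
            pos = max(pos, e)
        if length - pos >= 300:
            gaps.append(GenomicInterval(chrom, pos, length, "+"))
    return gaps


def simulate_clip_reads(
    dataset: SyntheticDataset, seed: int | None = None, library: str = "clip1"
) -> tuple[list[AlignedRead], dict[str, dict]]:
    """Simulate CLIP tags: site-derived reads carrying deletions, labelled
    background reads, and hairpin-window reads with planted categories.

    Returns (reads, per-read truth); truth records region label, source,
    and for hairpin reads the (mirna, category) pair.
    """
    config = dataset.config
    rng = np.random.default_rng(config.seed + 10_000 if seed is None else seed)
    reads: list[AlignedRead] = []
    info: dict[str, dict] = {}
    counter = 0

    def new_id() -> str:
        nonlocal counter
        counter += 1
        return f"{library}_r{counter:06d}"

    # -- site-derived reads ------------------------------------------------
    region_of_context = {"utr3": "utr3", "intron_5ss": "intron", "intron_3ss": "intron"}
    for site in dataset.truth.sites:
        for _ in range(config.clip_reads_per_site):
            length = int(rng.integers(*config.clip_read_length))
            a = int(rng.integers(2, length - 2))  # matched nt left of the site
            start = site.position - a
            rid = new_id()
            if rng.random() < config.clip_deletion_prob:
                d = config.clip_deletion_length
                segments = [("match", a), ("deletion", d), ("match", length - a)]
                has_del = True
            else:
                segments = [("match", length)]
                has_del = False
            reads.append(AlignedRead(rid, site.chrom, start, site.strand, segments, library))
            info[rid] = {
                "region": region_of_context[site.context],
                "source": "site",
                "site": site.position,
                "has_deletion": has_del,
            }

    # -- background reads --------------------------------------------------
    regions = _region_intervals(dataset.annotation)
    gaps = _intergenic_gaps(dataset)
    # exclude hairpin-window neighbourhoods so category truth stays per-pair exact
    hp_windows = [hp.window(config.hairpin_flank + 50) for hp in dataset.hairpins]
    n_bg = config.clip_background_reads
    for _ in range(n_bg):
        length = int(rng.integers(*config.clip_read_length))
        rid = new_id()
        if rng.random() < config.clip_intergenic_fraction and gaps:
            for _attempt in range(50):
                gap = gaps[int(rng.integers(len(gaps)))]
                if len(gap) > length + 2:
                    break
            start = int(rng.integers(gap.start, gap.end - length))
            strand = "+" if rng.random() < 0.5 else "-"
            reads.append(AlignedRead(rid, gap.chrom, start, strand, [("match", length)], library))
            info[rid] = {"region": "intergenic", "source": "background"}
        else:
            for _attempt in range(100):
                iv, label = regions[int(rng.integers(len(regions)))]
                if len(iv) <= length + 2:
                    continue
                start = int(rng.integers(iv.start, iv.end - length))
                probe = GenomicInterval(iv.chrom, start, start + length, iv.strand)
                if any(probe.overlaps(w, stranded=False) for w in hp_windows):
                    continue
                break
            reads.append(AlignedRead(rid, iv.chrom, start, iv.strand, [("match", length)], library))
            info[rid] = {"region": label, "source": "background"}

    # -- hairpin-window reads with planted categories ----------------------
    cats = sorted(config.category_weights)
    weights = np.array([config.category_weights[c] for c in cats])
    weights = weights / weights.sum()
    region_of_hp = {"intronic": "intron", "3utr": "utr3", "intergenic": "intergenic"}
    for _ in range(config.clip_hairpin_reads):
        hp = dataset.hairpins[int(rng.integers(len(dataset.hairpins)))]
        category = str(rng.choice(cats, p=weights))
        span = _sample_category_span(rng, hp, category, config.hairpin_flank)
        rid = new_id()
        reads.append(
            AlignedRead(rid, hp.hairpin.chrom, span[0], hp.strand, [("match", span[1] - span[0])], library)
        )
        info[rid] = {
            "region": region_of_hp[dataset.truth.hairpin_contexts[hp.mirna_id]],
            "source": "hairpin",
            "mirna": hp.mirna_id,
            "category": category,
        }
    dataset.truth.clip_read_info.update(info)
    return reads, info


def _sample_category_span(
    rng: np.random.Generator, hp: MirnaHairpin, category: str, flank: int
) -> tuple[int, int]:
    """Genomic (start, end) guaranteed to classify as ``category`` vs ``hp``."""
    h, m = hp.hairpin, hp.matures[0]
    if category == "I":
        choice = int(rng.integers(5))
        spans = [
            (m.start, m.end),
            (m.start + 1, m.end),
            (m.start, m.end - 1),
            (m.start - 1, m.end),
            (m.start, m.end + 1),
        ]
        return spans[choice]
    if category == "II":
        k = int(rng.integers(1, len(m)))
        if m.start - h.start >= 2:
            return (h.start, m.start + k)
        return (m.end - k, h.end)
    if category == "III":
        lo, hi = (m.end, h.end) if m.start - h.start < len(h) - (m.end - h.start) else (h.start, m.start)
        length = int(rng.integers(8, min(20, hi - lo)))
        start = int(rng.integers(lo, hi - length))
        return (start, start + length)
    if category == "IV":
        a = int(rng.integers(2, 30))
        b = int(rng.integers(1, 15))
        if rng.random() < 0.5:
            return (h.start - a, h.start + b)
        return (h.end - b, h.end + a)
    if category == "V":
        length = int(rng.integers(15, 31))
        if rng.random() < 0.5:
            start = int(rng.integers(h.start - flank, h.start - length + 1))
            return (start, start + length)
        start = int(rng.integers(h.end, h.end + flank - length + 1))
        return (start, start + length)
    raise ValueError(f"unknown category {category!r}")


# ---------------------------------------------------------------------------
# RNA-seq simulation


def simulate_rnaseq(
    dataset: SyntheticDataset,
    condition: str,
    seed: int | None = None,
    library: str | None = None,
) -> list[AlignedRead]:
    """RNA-seq reads for one condition.

    Window reads around non-intronic hairpins scale with the planted miRNA
    transcript level; intronic (mirtron) hairpins are covered through
    intron-retention vs junction reads split by the planted PIR; plus
    exonic background proportional to transcript levels and the
    long-isoform component on the designated gene.  Reads fully inside a
    hairpin are withheld, emulating library size selection.
    """
    config = dataset.config
    if condition not in ("control", "knockdown"):
        raise ValueError(f"unknown condition {condition!r}")
    rng = np.random.default_rng(
        (config.seed + (1 if condition == "control" else 2) * 20_000) if seed is None else seed
    )
    library = library or f"rnaseq_{condition}"
    reads: list[AlignedRead] = []
    counter = 0
    RL = config.rnaseq_read_length

    def new_id() -> str:
        nonlocal counter
        counter += 1
        return f"{library}_r{counter:06d}"

    hairpin_by_id = {hp.mirna_id: hp for hp in dataset.hairpins}

    # -- windows of non-intronic hairpins ---------------------------------
    for hp in dataset.hairpins:
        if dataset.truth.hairpin_contexts[hp.mirna_id] == "intronic":
            continue
        level = dataset.truth.mirna_levels[hp.mirna_id][condition]
        n = int(rng.poisson(level * config.mirna_window_reads))
        win = hp.window(200)
        for _ in range(n):
            start = int(rng.integers(max(0, win.start - RL + 1), win.end - 1))
            reads.append(AlignedRead(new_id(), win.chrom, start, hp.strand, [("match", RL)], library))

    # -- mirtron introns: retention / junction reads ----------------------
    for mid, intron in sorted(dataset.truth.mirtron_introns.items()):
        hp = hairpin_by_id[mid]
        level = dataset.truth.mirna_levels[mid][condition]
        pir = dataset.truth.intron_pir[mid][condition]
        n = int(rng.poisson(level * config.intron_informative_reads))
        for _ in range(n):
            if rng.random() < pir:
                start = int(rng.integers(intron.start, intron.end - RL))
                reads.append(
                    AlignedRead(new_id(), intron.chrom, start, intron.strand, [("match", RL)], library)
                )
            else:
                a = int(rng.integers(10, RL - 9))
                segments = [("match", a), ("skip", len(intron)), ("match", RL - a)]
                reads.append(
                    AlignedRead(new_id(), intron.chrom, intron.start - a, intron.strand, segments, library)
                )

    # -- exonic background proportional to planted transcript levels ------
    for tid in sorted(dataset.annotation.transcripts):
        t = dataset.annotation.transcripts[tid]
        level = dataset.truth.tx_levels[tid]
        n = int(rng.poisson(level * config.rnaseq_background_per_transcript))
        exons = [e for e in t.exons if len(e) > RL + 2]
        if not exons:
            continue
        for _ in range(n):
            e = exons[int(rng.integers(len(exons)))]
            start = int(rng.integers(e.start, e.end - RL))
            reads.append(AlignedRead(new_id(), e.chrom, start, t.strand, [("match", RL)], library))

    # -- long-isoform component on gene 0 ---------------------------------
    li = dataset.truth.long_isoform
    if li:
        frac = li["fraction"][condition]
        shared, unique = li["shared"], li["unique"]
        cov = config.long_isoform_coverage
        L = len(shared) + len(unique)
        rl = config.long_isoform_read_length
        lo = min(shared.start, unique.start)
        hi = max(shared.end, unique.end)
        n_long = int(rng.poisson(cov * frac * L / rl))
        n_short = int(rng.poisson(cov * (1 - frac) * len(shared) / rl))
        for _ in range(n_long):
            start = int(rng.integers(lo, hi - rl))
            reads.append(AlignedRead(new_id(), shared.chrom, start, shared.strand, [("match", rl)], library))
        for _ in range(n_short):
            start = int(rng.integers(shared.start, shared.end - rl))
            reads.append(AlignedRead(new_id(), shared.chrom, start, shared.strand, [("match", rl)], library))

    # library size selection: drop anything fully inside a hairpin
    kept = []
    for r in reads:
        if any(
            hp.hairpin.chrom == r.chrom
            and hp.hairpin.start <= r.start
            and r.end <= hp.hairpin.end
            for hp in dataset.hairpins
        ):
            continue
        kept.append(r)
    return kept


# ---------------------------------------------------------------------------
# small RNA simulation


@dataclass(frozen=True)
class SmallRnaRead:
    read_id: str
    mirna_id: str
    length: int
    sequence: str


def simulate_small_rna(
    dataset: SyntheticDataset, condition: str, seed: int | None = None
) -> list[SmallRnaRead]:
    """Small-RNA reads: multinomial per-miRNA counts around planted mature
    levels, lengths from the configured distribution."""
    config = dataset.config
    if condition not in ("control", "knockdown"):
        raise ValueError(f"unknown condition {condition!r}")
    rng = np.random.default_rng(
        (config.seed + (1 if condition == "control" else 2) * 30_000) if seed is None else seed
    )
    mids = sorted(dataset.truth.mature_levels)
    levels = np.array([dataset.truth.mature_levels[m][condition] for m in mids], dtype=float)
    control_total = sum(v["control"] for v in dataset.truth.mature_levels.values())
    background = config.smallrna_background_weight * control_total
    if levels.sum() + background == 0:
        return []
    mids = mids + ["_background"]
    levels = np.append(levels, background)
    counts = rng.multinomial(config.smallrna_n_reads, levels / levels.sum())
    lengths = sorted(config.smallrna_length_dist)
    lprobs = np.array([config.smallrna_length_dist[k] for k in lengths])
    hairpin_by_id = {hp.mirna_id: hp for hp in dataset.hairpins}
    out = []
    i = 0
    for mid, n in zip(mids, counts):
        if mid == "_background":
            raw = "".join(rng.choice(BASES, size=40))
        else:
            hp = hairpin_by_id[mid]
            m = hp.matures[0]
            raw = dataset.sequences[m.chrom][m.start : m.end + 15]
            if hp.strand == "-":
                raw = _revcomp(dataset.sequences[m.chrom][max(0, m.start - 15) : m.end])
        for _ in range(int(n)):
            length = int(rng.choice(lengths, p=lprobs))
            seq = raw[:length].ljust(length, "A")
            out.append(SmallRnaRead(f"sr{i:06d}", mid, length, seq))
            i += 1
    return out


def small_rna_tpm(reads: Sequence[SmallRnaRead]) -> dict[str, float]:
    """Per-miRNA TPM within a small-RNA library (count-based)."""
    counts: dict[str, int] = {}
    for r in reads:
        counts[r.mirna_id] = counts.get(r.mirna_id, 0) + 1
    total = sum(counts.values())
    return {m: c / total * 1e6 for m, c in sorted(counts.items())}


def write_reads(
    reads: Sequence[AlignedRead],
    chrom_lengths: dict[str, int],
    path: str | Path,
    dialect: str = "sam",
) -> None:
    if dialect == "sam":
        write_sam(reads, chrom_lengths, path)
    elif dialect == "tsv":
        write_tabular(reads, path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
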