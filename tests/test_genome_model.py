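import re

import numpy as np
import pytest

from targetome.genome_model import (
    AlignedRead,
    GenomeAnnotation,
    GtfParseError,
    TranscriptModel,
    TranscriptQuant,
    compute_expression,
    parse_alignments,
    parse_cigar,
    parse_gtf,
    select_bound_transcripts,
    write_gtf,
    write_sam,
)
from targetome.intervals import GenomicInterval
from targetome.synthetic_data import SimulationConfig, generate_genome, simulate_clip_reads


def _gtf_line(chrom, feature, start1, end1, strand, gene, tx):
    return (
        f"{chrom}\tsrc\t{feature}\t{start1}\t{end1}\t.\t{strand}\t.\t"
        f'gene_id "{gene}"; transcript_id "{tx}";\n'
    )


class TestParseGtf:
    def test_two_exons_one_cds_plus_strand(self, tmp_path):
        # exons [100,200) and [300,400); CDS [150,200)+[300,350) in 0-based terms
        p = tmp_path / "a.gtf"
        p.write_text(
            _gtf_line("chr1", "exon", 101, 200, "+", "g1", "t1")
            + _gtf_line("chr1", "exon", 301, 400, "+", "g1", "t1")
            + _gtf_line("chr1", "CDS", 151, 200, "+", "g1", "t1")
            + _gtf_line("chr1", "CDS", 301, 350, "+", "g1", "t1")
        )
        ann = parse_gtf(p)
        t = ann.transcripts["t1"]
        assert t.introns == [GenomicInterval("chr1", 200, 300, "+")]
        assert t.utr5 == [GenomicInterval("chr1", 100, 150, "+")]
        assert t.utr3 == [GenomicInterval("chr1", 350, 400, "+")]
        assert t.utr3_length == 50

    def test_minus_strand_utr3_lies_5prime_in_genomic_coords(self, tmp_path):
        p = tmp_path / "m.gtf"
        p.write_text(
            _gtf_line("chr1", "exon", 101, 400, "-", "g1", "t1")
            + _gtf_line("chr1", "CDS", 151, 350, "-", "g1", "t1")
        )
        t = parse_gtf(p).transcripts["t1"]
        # on the minus strand the 3'UTR is genomically left of the CDS
        assert t.utr3 == [GenomicInterval("chr1", 100, 150, "-")]
        assert t.utr5 == [GenomicInterval("chr1", 350, 400, "-")]

    def test_intron_set_matches_gap_oracle_on_synthetic_gtf(self, tmp_path):
        ds = generate_genome(SimulationConfig(seed=3, n_genes=12))
        path = tmp_path / "g.gtf"
        write_gtf(ds.annotation, path)
        ann = parse_gtf(path)
        assert len(ann.transcripts) >= 12
        for tid, t in ann.transcripts.items():
            # brute force: gaps between sorted exons
            exons = sorted((e.start, e.end) for e in t.exons)
            gaps = [
                (a_end, b_start)
                for (_, a_end), (b_start, _) in zip(exons, exons[1:])
                if b_start > a_end
            ]
            assert [(iv.start, iv.end) for iv in t.introns] == gaps

    def test_malformed_line_names_line_number(self, tmp_path):
        p = tmp_path / "bad.gtf"
        p.write_text(_gtf_line("chr1", "exon", 1, 10, "+", "g", "t") + "chr1\tonly\tthree\n")
        with pytest.raises(GtfParseError, match=r":2"):
            parse_gtf(p)

    def test_end_before_start_rejected(self, tmp_path):
        p = tmp_path / "bad.gtf"
        p.write_text(_gtf_line("chr1", "exon", 50, 10, "+", "g", "t"))
        with pytest.raises(GtfParseError, match="end < start"):
            parse_gtf(p)

    def test_roundtrip_identity(self, tmp_path, dataset):
        p1, p2 = tmp_path / "a.gtf", tmp_path / "b.gtf"
        write_gtf(dataset.annotation, p1)
        ann = parse_gtf(p1)
        write_gtf(ann, p2)
        assert p1.read_bytes() == p2.read_bytes()
        for tid, t in dataset.annotation.transcripts.items():
            t2 = ann.transcripts[tid]
            assert t.exons == t2.exons and t.cds == t2.cds


class TestCigarAndAlignments:
    def test_simple_match(self):
        assert parse_cigar("20M") == [("match", 20)]
        r = AlignedRead("r", "chr1", 100, "+", parse_cigar("20M"))
        assert r.reference_span == 20

    def test_deletion_placement(self):
        r = AlignedRead("r", "chr1", 100, "+", parse_cigar("10M2D8M"))
        assert r.deletion_blocks() == [(110, 112)]
        assert r.reference_span == 20

    def test_bad_cigar(self):
        with pytest.raises(ValueError):
            parse_cigar("10Mxx")
        with pytest.raises(ValueError):
            parse_cigar("*")

    def test_reference_span_against_independent_reparser(self):
        rng = np.random.default_rng(7)
        ops = "MIDN"
        for _ in range(1000):
            n_ops = rng.integers(1, 5)
            cigar = "10M" + "".join(
                f"{rng.integers(1, 20)}{ops[rng.integers(len(ops))]}" for _ in range(n_ops)
            )
            segs = parse_cigar(cigar)
            span = sum(n for n, op in re.findall(r"(\d+)([MIDN])", cigar)
                       for n in [int(n)] if op in "MDN")
            assert sum(n for op, n in segs if op in ("match", "deletion", "skip")) == span

    def test_sam_filters_multimappers_and_unmapped(self, tmp_path):
        sam = tmp_path / "x.sam"
        sam.write_text(
            "@HD\tVN:1.6\n@SQ\tSN:chr1\tLN:1000\n"
            "keep\t0\tchr1\t101\t30\t10M\t*\t0\t0\tNNNNNNNNNN\t*\n"
            "multi\t0\tchr1\t201\t30\t10M\t*\t0\t0\tNNNNNNNNNN\t*\tNH:i:3\n"
            "lowq\t0\tchr1\t301\t0\t10M\t*\t0\t0\tNNNNNNNNNN\t*\n"
            "unmapped\t4\t*\t0\t0\t*\t*\t0\t0\tNNNNNNNNNN\t*\n"
        )
        reads = parse_alignments(sam)
        assert [r.read_id for r in reads] == ["keep"]

    def test_span_validation_against_declared_lengths(self, tmp_path, dataset):
        reads = [AlignedRead("r1", "chr1", 100, "+", [("match", 50)])]
        sam = tmp_path / "y.sam"
        write_sam(reads, {"chr1": 120}, sam)
        with pytest.raises(ValueError, match="exceeds"):
            parse_alignments(sam, chrom_lengths={"chr1": 120})


def _single_transcript_annotation(length=1000):
    t = TranscriptModel("t1", "g1", "chr1", "+", [GenomicInterval("chr1", 0, length, "+")])
    return GenomeAnnotation([t], chrom_lengths={"chr1": length + 100})


class TestExpression:
    def test_closed_form_fpkm(self):
        ann = _single_transcript_annotation(1000)
        reads = [
            AlignedRead(f"r{i}", "chr1", 10 * i, "+", [("match", 30)], "lib1") for i in range(100)
        ]
        quant = compute_expression(reads, ann)
        q = quant["lib1"]["t1"]
        assert q.count == 100
        assert q.fpkm == pytest.approx(1e6)
        assert q.tpm == pytest.approx(1e6)

    def test_no_overlap_zero(self):
        ann = _single_transcript_annotation(1000)
        reads = [AlignedRead("r", "chr2", 0, "+", [("match", 30)], "lib1")]
        q = compute_expression(reads, ann)["lib1"]["t1"]
        assert q.fpkm == 0 and q.tpm == 0

    def test_wrong_strand_not_counted(self):
        ann = _single_transcript_annotation(1000)
        reads = [AlignedRead("r", "chr1", 10, "-", [("match", 30)], "lib1")]
        assert compute_expression(reads, ann)["lib1"]["t1"].count == 0

    def test_against_bruteforce_recount(self, dataset, rnaseq):
        ann = dataset.annotation
        reads = rnaseq["control"][:800]
        quant = compute_expression(reads, ann)
        lib = next(iter(quant))
        # brute-force: for each transcript scan all reads for >=1 exonic-nt overlap
        counted_total = 0
        expected_counts = {}
        for tid, t in ann.transcripts.items():
            n = 0
            for r in reads:
                if r.chrom != t.chrom or r.strand != t.strand:
                    continue
                hit = any(
                    bs < e.end and e.start < be
                    for bs, be in r.match_blocks()
                    for e in t.exons
                )
                n += hit
            expected_counts[tid] = n
        total = sum(expected_counts.values())
        for tid, n in expected_counts.items():
            q = quant[lib][tid]
            assert q.count == n
            expected_fpkm = n * 1e9 / (total * t_len) if (t_len := ann.transcripts[tid].exonic_length) and total else 0.0
            assert q.fpkm == pytest.approx(expected_fpkm)

    def test_gene_level_counting_switch(self, dataset, rnaseq):
        reads = rnaseq["control"][:400]
        quant = compute_expression(reads, dataset.annotation, level="gene")
        lib = next(iter(quant))
        assert set(quant[lib]) == set(dataset.annotation.genes)
        with pytest.raises(ValueError):
            compute_expression(reads, dataset.annotation, level="exon")

    def test_tpm_sums_to_million(self, dataset, rnaseq):
        quant = compute_expression(rnaseq["control"][:500], dataset.annotation)
        for lib in quant:
            assert sum(q.tpm for q in quant[lib].values()) == pytest.approx(1e6)


def _quant_from_matrix(matrix):
    # rows: transcripts, cols: libraries, values: FPKM
    out = {}
    for j in range(matrix.shape[1]):
        out[f"lib{j}"] = {
            f"t{i}": TranscriptQuant(f"t{i}", 1, float(matrix[i, j]), 0.0, f"lib{j}")
            for i in range(matrix.shape[0])
        }
    return out


class TestSelectBoundTranscripts:
    def test_two_of_three_at_threshold_retained(self):
        quant = _quant_from_matrix(np.array([[0.5, 0.5, 0.1]]))
        assert select_bound_transcripts(quant, 0.5, 2) == {"t0"}

    def test_single_passing_library_not_retained(self):
        quant = _quant_from_matrix(np.array([[0.4, 0.6, 0.3]]))
        assert select_bound_transcripts(quant, 0.5, 2) == set()

    def test_min_libraries_exceeds_supply(self):
        quant = _quant_from_matrix(np.array([[1.0]]))
        with pytest.raises(ValueError):
            select_bound_transcripts(quant, 0.5, 2)

    def test_random_matrix_matches_row_scan(self):
        rng = np.random.default_rng(42)
        m = rng.uniform(0, 1, size=(100, 3))
        got = select_bound_transcripts(_quant_from_matrix(m), 0.5, 2)
        expected = {f"t{i}" for i in range(100) if (m[i] >= 0.5).sum() >= 2}
        assert got == expected


class TestRegionIndex:
    def test_labels_partition_chromosome(self, dataset):
        ann = dataset.annotation
        for chrom, length in ann.chrom_lengths.items():
            for strand in "+-":
                arr = ann.region_array(chrom, strand)
                assert len(arr) == length
                assert int(np.bincount(arr, minlength=5).sum()) == length

    def test_cds_beats_utr_in_precedence(self):
        # two same-strand transcripts disagreeing over base 50: CDS wins
        t1 = TranscriptModel(
            "a", "g1", "chr1", "+",
            [GenomicInterval("chr1", 0, 100, "+")], [GenomicInterval("chr1", 10, 90, "+")],
        )
        t2 = TranscriptModel(
            "b", "g2", "chr1", "+",
            [GenomicInterval("chr1", 40, 200, "+")], [GenomicInterval("chr1", 100, 150, "+")],
        )
        ann = GenomeAnnotation([t1, t2])
        assert ann.region_of("chr1", 50, "+") == "cds"
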