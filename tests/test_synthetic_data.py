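import hashlib
from pathlib import Path

import numpy as np
import pytest
from scipy import stats

from targetome.genome_model import parse_alignments, parse_gtf, write_sam
from targetome.mirna_targetome import parse_mirna_gff3
from targetome.synthetic_data import (
    SimulationConfig,
    generate_genome,
    simulate_clip_reads,
    simulate_rnaseq,
    simulate_small_rna,
)


def _tree_digest(root: Path) -> str:
    h = hashlib.sha256()
    for p in sorted(root.rglob("*")):
        if p.is_file():
            h.update(p.name.encode())
            h.update(p.read_bytes())
    return h.hexdigest()


class TestGenerateGenome:
    def test_same_seed_identical_bytes(self, tmp_path):
        digests = []
        for sub in ("a", "b"):
            ds = generate_genome(SimulationConfig(seed=1))
            ds.write(tmp_path / sub)
            digests.append(_tree_digest(tmp_path / sub))
        assert digests[0] == digests[1]

    def test_requested_intronic_hairpin_count(self):
        ds = generate_genome(SimulationConfig(seed=4, n_mirna_intronic=5))
        intronic = [m for m, c in ds.truth.hairpin_contexts.items() if c == "intronic"]
        assert len(intronic) == 5

    def test_hairpin_arms_reverse_complement(self, dataset):
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        arm = dataset.config.hairpin_arm
        for hp in dataset.hairpins:
            seq = dataset.sequences[hp.hairpin.chrom][hp.hairpin.start : hp.hairpin.end]
            left, right = seq[:arm], seq[-arm:]
            assert right == "".join(comp[b] for b in reversed(left))

    def test_capacity_error(self):
        cfg = SimulationConfig(seed=0, chrom_lengths={"chr1": 4000}, n_genes=5)
        with pytest.raises(ValueError, match="does not fit"):
            generate_genome(cfg)

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(clip_deletion_prob=1.5).validate()

    def test_outputs_parse_through_readers(self, tmp_path, dataset):
        paths = dataset.write(tmp_path)
        ann = parse_gtf(paths["gtf"])
        assert set(ann.transcripts) == set(dataset.annotation.transcripts)
        hairpins = parse_mirna_gff3(paths["mirna_gff3"])
        assert [h.mirna_id for h in hairpins] == [h.mirna_id for h in dataset.hairpins]
        assert [h.hairpin for h in hairpins] == [h.hairpin for h in dataset.hairpins]
        fasta = paths["fasta"].read_text().split(">")
        assert len([b for b in fasta if b]) == len(dataset.sequences)


class TestSimulateClip:
    def test_deletion_probability_one(self):
        ds = generate_genome(SimulationConfig(seed=6, clip_deletion_prob=1.0))
        reads, info = simulate_clip_reads(ds, seed=60)
        site_reads = [r for r in reads if info[r.read_id]["source"] == "site"]
        assert site_reads
        for r in site_reads:
            blocks = r.deletion_blocks()
            assert len(blocks) == 1
            assert blocks[0][0] == info[r.read_id]["site"]

    def test_deletion_probability_zero(self):
        ds = generate_genome(SimulationConfig(seed=6, clip_deletion_prob=0.0))
        reads, _ = simulate_clip_reads(ds, seed=61)
        assert all(not r.deletion_blocks() for r in reads)

    def test_deletion_fraction_within_binomial_ci(self):
        cfg = SimulationConfig(seed=7, clip_deletion_prob=0.3, clip_reads_per_site=120)
        ds = generate_genome(cfg)
        reads, info = simulate_clip_reads(ds, seed=70)
        site_reads = [r for r in reads if info[r.read_id]["source"] == "site"]
        n = len(site_reads)
        assert n >= 2000
        k = sum(bool(r.deletion_blocks()) for r in site_reads)
        lo, hi = stats.binom.interval(0.99, n, 0.3)
        assert lo <= k <= hi

    def test_region_truth_consistent(self, dataset, clip):
        from targetome.metagene import read_region_label

        reads, info = clip
        for r in reads:
            assert read_region_label(r, dataset.annotation) == info[r.read_id]["region"]

    def test_sam_roundtrip(self, tmp_path, dataset, clip):
        reads, _ = clip
        path = tmp_path / "clip.sam"
        write_sam(reads, dataset.config.chrom_lengths, path)
        back = parse_alignments(path)
        key = lambda r: (r.read_id, r.chrom, r.start, r.strand, tuple(r.segments))
        assert sorted(map(key, back)) == sorted(map(key, reads))


class TestSimulateRnaseq:
    def test_zero_level_mirna_no_window_reads(self):
        ds = generate_genome(SimulationConfig(seed=8))
        # force one intergenic miRNA to zero in both conditions
        mid = next(m for m, c in ds.truth.hairpin_contexts.items() if c == "intergenic")
        ds.truth.mirna_levels[mid] = {"control": 0.0, "knockdown": 0.0}
        reads = simulate_rnaseq(ds, "control", seed=80)
        hp = next(h for h in ds.hairpins if h.mirna_id == mid)
        win = hp.window(200)
        in_window = [
            r for r in reads
            if r.chrom == win.chrom and r.strand == win.strand
            and r.start < win.end and win.start < r.end
        ]
        assert in_window == []  # intergenic window has no background either

    def test_pir_one_no_junction_reads(self):
        cfg = SimulationConfig(seed=9, pir_control=(1.0, 1.0), pir_knockdown_shift=0.0)
        ds = generate_genome(cfg)
        reads = simulate_rnaseq(ds, "control", seed=90)
        for intron in ds.truth.mirtron_introns.values():
            for r in reads:
                assert not any(
                    s == intron.start and e == intron.end for s, e in r.skip_blocks()
                )

    def test_unknown_condition(self, dataset):
        with pytest.raises(ValueError):
            simulate_rnaseq(dataset, "mock")

    def test_level_ratio_recovered(self):
        cfg = SimulationConfig(seed=10, mirna_window_reads=800, pir_knockdown_shift=0.0)
        ds = generate_genome(cfg)
        mid = next(m for m, c in ds.truth.hairpin_contexts.items() if c == "intergenic")
        ds.truth.mirna_levels[mid] = {"control": 1.0, "knockdown": 0.5}
        hp = next(h for h in ds.hairpins if h.mirna_id == mid)
        win = hp.window(200)
        counts = {}
        for i, cond in enumerate(("control", "knockdown")):
            reads = simulate_rnaseq(ds, cond, seed=100 + i)
            counts[cond] = sum(
                1 for r in reads
                if r.chrom == win.chrom and r.strand == win.strand
                and r.start < win.end and win.start < r.end
            )
        log2 = np.log2(counts["control"] / counts["knockdown"])
        assert abs(log2 - 1.0) < 0.35  # |log2 0.5 ratio| within sampling error

    def test_no_reads_fully_inside_hairpins(self, dataset, rnaseq):
        for reads in rnaseq.values():
            for hp in dataset.hairpins:
                h = hp.hairpin
                assert not any(
                    r.chrom == h.chrom and h.start <= r.start and r.end <= h.end
                    for r in reads
                )


class TestSimulateSmallRna:
    def test_degenerate_length_distribution(self):
        cfg = SimulationConfig(seed=12, smallrna_length_dist={22: 1.0}, smallrna_n_reads=500)
        ds = generate_genome(cfg)
        reads = simulate_small_rna(ds, "control", seed=120)
        assert reads and all(r.length == 22 for r in reads)

    def test_zero_level_mirna_zero_reads(self):
        ds = generate_genome(SimulationConfig(seed=13))
        mid = sorted(ds.truth.mature_levels)[0]
        ds.truth.mature_levels[mid] = {"control": 0.0, "knockdown": 0.0}
        reads = simulate_small_rna(ds, "control", seed=130)
        assert not any(r.mirna_id == mid for r in reads)

    def test_two_fold_count_ratio(self):
        ds = generate_genome(SimulationConfig(seed=14, smallrna_n_reads=20000))
        mids = sorted(ds.truth.mature_levels)[:2]
        for m in sorted(ds.truth.mature_levels):
            ds.truth.mature_levels[m]["control"] = 0.0
        ds.truth.mature_levels[mids[0]]["control"] = 20.0
        ds.truth.mature_levels[mids[1]]["control"] = 10.0
        reads = simulate_small_rna(ds, "control", seed=140)
        counts = {m: sum(r.mirna_id == m for r in reads) for m in mids}
        assert counts[mids[0]] / counts[mids[1]] == pytest.approx(2.0, rel=0.15)

    def test_determinism(self, dataset):
        a = simulate_small_rna(dataset, "control", seed=1)
        b = simulate_small_rna(dataset, "control", seed=1)
        assert a == b
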