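import numpy as np
import pytest

from targetome.genome_model import AlignedRead
from targetome.intervals import GenomicInterval
from targetome.mirna_targetome import (
    CATEGORIES,
    MirnaHairpin,
    MirnaReadCategory,
    call_mirna_forms,
    categorize,
    classify_mirna_reads,
    collect_hairpin_reads,
    hairpin_meta_profile,
    small_rna_length_profile,
)


@pytest.fixture
def hairpin():
    # hairpin [1000, 1062), mature [1002, 1024), + strand
    return MirnaHairpin(
        "mirX",
        GenomicInterval("chr1", 1000, 1062, "+"),
        (GenomicInterval("chr1", 1002, 1024, "+"),),
    )


def _read(rid, start, length, strand="+", lib="clip"):
    return AlignedRead(rid, "chr1", start, strand, [("match", length)], lib)


class TestCollectHairpinReads:
    def test_read_ending_at_window_start_excluded(self, hairpin):
        # window starts at 900; read [870, 900) does not overlap
        pairs = collect_hairpin_reads([_read("r", 870, 30)], [hairpin], flank=100)
        assert pairs == []

    def test_one_nt_overlap_retained(self, hairpin):
        pairs = collect_hairpin_reads([_read("r", 871, 30)], [hairpin], flank=100)
        assert len(pairs) == 1

    def test_wrong_strand_excluded(self, hairpin):
        assert collect_hairpin_reads([_read("r", 1000, 30, "-")], [hairpin]) == []

    def test_bruteforce_window_intersection(self, dataset, clip):
        reads, _ = clip
        flank = 100
        pairs = collect_hairpin_reads(reads, dataset.hairpins, flank=flank)
        got = {(r.read_id, hp.mirna_id) for r, hp in pairs}
        expected = set()
        for r in reads:
            for hp in dataset.hairpins:
                w = hp.window(flank)
                if (
                    r.chrom == w.chrom
                    and r.strand == w.strand
                    and r.start < w.end
                    and w.start < r.end
                ):
                    expected.add((r.read_id, hp.mirna_id))
        assert got == expected


class TestCategorize:
    def test_read_equal_to_mature_is_I(self, hairpin):
        assert categorize(1002, 1024, hairpin) == "I"

    def test_one_nt_excess_still_I(self, hairpin):
        assert categorize(1001, 1024, hairpin) == "I"

    def test_two_nt_excess_not_I(self, hairpin):
        assert categorize(1001, 1025, hairpin) == "II"

    def test_inside_hairpin_overlapping_mature_is_II(self, hairpin):
        assert categorize(1000, 1030, hairpin) == "II"

    def test_loop_read_is_III(self, hairpin):
        assert categorize(1030, 1050, hairpin) == "III"

    def test_straddling_boundary_is_IV(self, hairpin):
        assert categorize(1057, 1067, hairpin) == "IV"

    def test_outside_hairpin_is_V(self, hairpin):
        assert categorize(1070, 1090, hairpin) == "V"

    def test_per_end_excess_mode(self, hairpin):
        # 1 nt excess at each end: total=2 -> II, per-end max=1 -> I
        assert categorize(1001, 1025, hairpin, excess_mode="total") == "II"
        assert categorize(1001, 1025, hairpin, excess_mode="per-end") == "I"
        with pytest.raises(ValueError):
            categorize(1001, 1025, hairpin, excess_mode="both")

    def test_pair_outside_window_raises(self, hairpin):
        with pytest.raises(ValueError):
            classify_mirna_reads([(_read("r", 2000, 20), hairpin)], flank=100)

    def test_simulated_truth_agreement(self, dataset, clip):
        reads, info = clip
        pairs = collect_hairpin_reads(reads, dataset.hairpins, flank=100)
        got = {
            (c.read_id, c.mirna_id): c.category
            for c in classify_mirna_reads(pairs, flank=100)
        }
        checked = 0
        for rid, i in info.items():
            if "category" in i:
                assert got[(rid, i["mirna"])] == i["category"]
                checked += 1
        assert checked == dataset.config.clip_hairpin_reads


def _cats(mirna_id, **counts):
    out = []
    i = 0
    for cat, n in counts.items():
        for _ in range(n):
            out.append(MirnaReadCategory(f"r{i}", mirna_id, cat))
            i += 1
    return out


class TestFormCalls:
    def test_five_category_I_reads_mature_only(self):
        calls = call_mirna_forms(_cats("m", I=5))
        assert calls["m"].forms == {"mature"}

    def test_pre_from_II_plus_III(self):
        calls = call_mirna_forms(_cats("m", II=3, III=2))
        assert calls["m"].forms == {"pre"}

    def test_below_threshold_no_forms(self):
        calls = call_mirna_forms(_cats("m", I=4, IV=2, V=2))
        assert calls["m"].forms == set()

    def test_category_counts_partition_pairs(self, dataset, clip):
        reads, _ = clip
        pairs = collect_hairpin_reads(reads, dataset.hairpins, flank=100)
        cats = classify_mirna_reads(pairs, flank=100)
        calls = call_mirna_forms(cats)
        per_mirna = {}
        for _, hp in pairs:
            per_mirna[hp.mirna_id] = per_mirna.get(hp.mirna_id, 0) + 1
        for mid, call in calls.items():
            assert sum(call.counts.values()) == per_mirna[mid]

    def test_monotonic_in_min_reads(self, dataset, clip):
        reads, _ = clip
        pairs = collect_hairpin_reads(reads, dataset.hairpins, flank=100)
        cats = classify_mirna_reads(pairs, flank=100)
        previous = None
        for threshold in range(1, 11):
            calls = call_mirna_forms(cats, min_reads=threshold)
            forms = {m: set(c.forms) for m, c in calls.items()}
            if previous is not None:
                for m in forms:
                    assert forms[m] <= previous[m]
            previous = forms


class TestHairpinMetaProfile:
    def test_uniform_coverage_flat(self, hairpin):
        reads = [_read(f"r{i}", 700 + i, 1) for i in range(700)]
        prof = hairpin_meta_profile(reads, [hairpin], flank=200, bins=30)
        assert prof.depth.sum() == pytest.approx(1.0)
        assert np.allclose(prof.depth, 1 / 30, atol=1e-9)

    def test_single_read_at_midpoint(self, hairpin):
        mid = hairpin.midpoint
        prof = hairpin_meta_profile([_read("r", mid - 2, 5)], [hairpin], flank=200, bins=30)
        center = prof.depth[14:16].sum()
        assert center == pytest.approx(1.0)

    def test_distal_reads_depress_central_bins(self, hairpin):
        mid = hairpin.midpoint
        reads = [_read(f"l{i}", mid - 180 + i, 20) for i in range(40)]
        reads += [_read(f"r{i}", mid + 80 + i, 20) for i in range(40)]
        prof = hairpin_meta_profile(reads, [hairpin], flank=200, bins=30)
        central = prof.depth[13:17].mean()
        distal = np.concatenate([prof.depth[:6], prof.depth[-6:]]).mean()
        assert distal > central

    def test_empty_reads_zero_profile(self, hairpin):
        prof = hairpin_meta_profile([], [hairpin])
        assert prof.depth.sum() == 0

    def test_minus_strand_profile_mirrors(self):
        hp_plus = MirnaHairpin(
            "p", GenomicInterval("chr1", 1000, 1062, "+"),
            (GenomicInterval("chr1", 1002, 1024, "+"),),
        )
        hp_minus = MirnaHairpin(
            "m", GenomicInterval("chr1", 1000, 1062, "-"),
            (GenomicInterval("chr1", 1038, 1060, "-"),),
        )
        # read upstream of the + hairpin midpoint == read downstream on -
        mid = hp_plus.midpoint
        prof_p = hairpin_meta_profile([_read("a", mid - 100, 20, "+")], [hp_plus])
        prof_m = hairpin_meta_profile([_read("b", mid + 80, 20, "-")], [hp_minus])
        assert np.allclose(prof_p.depth, prof_m.depth)


class TestSmallRnaLengthProfile:
    def test_share_two_thirds(self):
        prof = small_rna_length_profile([22, 22, 30])
        assert prof.share(21, 25) == pytest.approx(66.6667, abs=1e-3)

    def test_all_22(self):
        assert small_rna_length_profile([22] * 10).share(21, 25) == 100.0

    def test_percentages_sum_100(self, small_rna):
        lengths = [r.length for r in small_rna["control"]]
        prof = small_rna_length_profile(lengths)
        assert sum(prof.percentages.values()) == pytest.approx(100.0)
        # brute-force tally
        for length, pct in prof.percentages.items():
            assert pct == pytest.approx(100 * lengths.count(length) / len(lengths))

    def test_empty_error(self):
        with pytest.raises(ValueError):
            small_rna_length_profile([])
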