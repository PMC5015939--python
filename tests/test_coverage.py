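import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from plastidseq import (
    FeatureAnnotation,
    GenomicInterval,
    StrandedCoverage,
    feature_rpkm,
    per_nucleotide_coverage,
    rpkm,
    windowed_coverage,
)
from plastidseq.coverage import CoverageError, window_starts

from conftest import make_header, make_read


class TestPerNucleotideCoverage:
    def test_single_ungapped_read(self):
        header = make_header(length=200)
        cov = per_nucleotide_coverage([make_read(header, 0, "60M")], 200)
        expected = np.zeros(200, dtype=int)
        expected[:60] = 1
        assert np.array_equal(cov.plus_depth, expected)
        assert not cov.minus_depth.any()

    def test_gap_block_contributes_no_depth(self):
        header = make_header(length=300)
        cov = per_nucleotide_coverage([make_read(header, 0, "30M100N30M")], 300)
        assert cov.plus_depth[:30].sum() == 30
        assert cov.plus_depth[30:130].sum() == 0
        assert cov.plus_depth[130:160].sum() == 30

    def test_empty_stream_gives_zero_tracks(self):
        cov = per_nucleotide_coverage([], 100)
        assert not cov.plus_depth.any() and not cov.minus_depth.any()

    def test_read_past_genome_end_rejected(self):
        header = make_header(length=1000)
        with pytest.raises(CoverageError, match="beyond"):
            per_nucleotide_coverage([make_read(header, 70, "60M")], 100)

    def test_reverse_reads_land_on_minus_track(self):
        header = make_header(length=100)
        cov = per_nucleotide_coverage([make_read(header, 0, "50M", reverse=True)], 100)
        assert cov.minus_depth[:50].sum() == 50 and not cov.plus_depth.any()

    def test_conservation_total_depth_equals_total_aligned_length(self, sim_bundle):
        _, _, _, _, reads, _, ann = sim_bundle
        from plastidseq.alignment import aligned_blocks

        cov = per_nucleotide_coverage(reads, ann.genome_length)
        aligned_total = sum(
            e - s for read in reads for s, e in aligned_blocks(read)
        )
        assert int(cov.plus_depth.sum() + cov.minus_depth.sum()) == aligned_total

    def test_strand_swap_involution(self, sim_bundle):
        # reverse-complementing every read's placement swaps the tracks exactly
        _, _, _, _, reads, _, ann = sim_bundle
        cov = per_nucleotide_coverage(reads, ann.genome_length)
        import pysam

        flipped = []
        for read in reads:
            rec = pysam.AlignedSegment.from_dict(read.to_dict(), read.header)
            rec.flag ^= 16
            flipped.append(rec)
        swapped = per_nucleotide_coverage(flipped, ann.genome_length)
        assert np.array_equal(swapped.plus_depth, cov.minus_depth)
        assert np.array_equal(swapped.minus_depth, cov.plus_depth)


class TestWindowedCoverage:
    def test_window_starts_enumeration(self):
        assert window_starts(150, 100, 50) == [0, 50, 100]

    def test_uniform_depth_gives_truncated_final_window(self):
        # genome 150, uniform + depth 2: windows (0,100), (50,150), (100,150)
        track = StrandedCoverage(
            "chr", np.full(150, 2, dtype=int), np.zeros(150, dtype=int)
        )
        wc = windowed_coverage(track, total_reads=10**6)
        plus = [w for w in wc.windows if w.strand == "+"]
        assert [(w.start, w.end, w.raw_sum) for w in plus] == [
            (0, 100, 200),
            (50, 150, 200),
            (100, 150, 100),
        ]
        assert plus[0].normalized_value == pytest.approx(200 * 1e6 / 10**6)

    def test_all_zero_track_gives_zero_windows(self):
        track = StrandedCoverage("chr", np.zeros(120, dtype=int), np.zeros(120, dtype=int))
        wc = windowed_coverage(track, total_reads=100)
        assert all(w.raw_sum == 0 and w.normalized_value == 0 for w in wc.windows)

    def test_zero_total_reads_rejected(self):
        track = StrandedCoverage("chr", np.zeros(10, dtype=int), np.zeros(10, dtype=int))
        with pytest.raises(CoverageError):
            windowed_coverage(track, total_reads=0)

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=25, derandomize=True, deadline=None)
    def test_window_sums_match_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(30, 400))
        plus = rng.integers(0, 50, size=n)
        minus = rng.integers(0, 50, size=n)
        track = StrandedCoverage("chr", plus, minus)
        window, step = int(rng.integers(2, 120)), int(rng.integers(1, 80))
        if step > window:
            window, step = step, window
        wc = windowed_coverage(track, total_reads=1000, window=window, step=step)
        for w in wc.windows:
            depth = plus if w.strand == "+" else minus
            assert w.raw_sum == int(depth[w.start : w.end].sum())


class TestFeatureRpkm:
    def test_printed_formula_example(self):
        assert rpkm(100, 10**6, 1000) == pytest.approx(100.0, rel=1e-12)

    def test_zero_reads_zero_rpkm(self):
        assert rpkm(0, 10**6, 500) == 0.0

    def test_doubling_reads_and_total_leaves_rpkm_unchanged(self):
        assert rpkm(84, 12345, 700) == pytest.approx(rpkm(168, 24690, 700), rel=1e-12)

    def test_read_overlapping_two_adjacent_exons_counts_in_both(self):
        header = make_header(length=400)
        exons = [
            FeatureAnnotation(GenomicInterval("chr", 0, 100, "+"), "e1", "exon"),
            FeatureAnnotation(GenomicInterval("chr", 100, 200, "+"), "e2", "exon"),
        ]
        read = make_read(header, 80, "40M")  # spans 80..120
        records = feature_rpkm([read], exons, total_reads=1)
        assert [r.read_count for r in records] == [1, 1]

    def test_spliced_read_does_not_count_in_skipped_intron(self):
        header = make_header(length=400)
        feats = [
            FeatureAnnotation(GenomicInterval("chr", 100, 200, "+"), "i1", "intron"),
        ]
        spliced = make_read(header, 70, "30M100N30M")  # gap exactly over intron
        unspliced = make_read(header, 120, "40M")
        records = feature_rpkm([spliced, unspliced], feats, total_reads=2)
        assert records[0].read_count == 1

    def test_strand_mismatched_read_not_counted(self):
        header = make_header(length=400)
        feats = [FeatureAnnotation(GenomicInterval("chr", 0, 100, "+"), "e1", "exon")]
        read = make_read(header, 10, "50M", reverse=True)
        assert feature_rpkm([read], feats, total_reads=1)[0].read_count == 0

    def test_counts_match_emission_truth(self, sim_bundle):
        _, _, truth, _, reads, stats, ann = sim_bundle
        records = feature_rpkm(reads, ann.features, stats.mapped_reads)
        assert {r.feature_id: r.read_count for r in records} == truth.per_feature
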