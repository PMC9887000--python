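"""Interval arithmetic, format readers and FDR plumbing."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from sineanchor.core import (
    GenomeIndex,
    GenomicInterval,
    PeakRegion,
    RepeatInstance,
    bh_adjust,
    overlaps,
    read_bed,
    read_regions,
    read_repeats,
    shuffle_intervals,
    window_count,
    write_bed,
)


def iv(start, end, chrom="chr1", strand="."):
    return GenomicInterval(chrom, start, end, strand)


class TestIntervalTypes:
    def test_zero_length_rejected(self):
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 100, 100)

    def test_bad_strand_rejected(self):
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 0, 10, "*")

    def test_summit_must_lie_inside_peak(self):
        with pytest.raises(ValueError):
            PeakRegion(iv(100, 300), 300)

    def test_repeat_head_follows_strand(self):
        plus = RepeatInstance(iv(500, 640, strand="+"), "SINE", "B1")
        minus = RepeatInstance(iv(500, 640, strand="-"), "SINE", "B1")
        assert plus.head_pos == 500 and plus.tail_pos == 639
        assert minus.head_pos == 639 and minus.tail_pos == 500

    def test_repeat_requires_strand(self):
        with pytest.raises(ValueError):
            RepeatInstance(iv(500, 640, strand="."), "SINE", "B1")


class TestRegionReader:
    def test_plain_bed_summit_is_midpoint(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t100\t300\n")
        (peak,) = read_regions(p, "bed")
        assert (peak.interval.start, peak.interval.end) == (100, 300)
        assert peak.summit == 200

    def test_narrowpeak_summit_is_start_plus_offset(self, tmp_path):
        p = tmp_path / "a.narrowPeak"
        p.write_text("chr1\t1000\t1800\tpk\t0\t.\t5.0\t-1\t-1\t50\n")
        (peak,) = read_regions(p, "narrowpeak")
        assert peak.summit == 1050

    def test_empty_file_gives_empty_list(self, tmp_path):
        p = tmp_path / "empty.bed"
        p.write_text("")
        assert read_regions(p, "bed") == []

    def test_malformed_line_error_names_line_number(self, tmp_path):
        p = tmp_path / "bad.bed"
        p.write_text("chr1\t100\t300\nchr1\tnotanumber\t5\n")
        with pytest.raises(ValueError, match=":2"):
            read_regions(p, "bed")

    def test_summit_offset_beyond_peak_errors(self, tmp_path):
        p = tmp_path / "a.narrowPeak"
        p.write_text("chr1\t1000\t1100\tpk\t0\t.\t5.0\t-1\t-1\t250\n")
        with pytest.raises(ValueError, match="summit offset"):
            read_regions(p, "narrowpeak")

    def test_file_order_preserved(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr2\t10\t30\nchr1\t0\t20\n")
        got = read_regions(p, "bed")
        assert [pk.chrom for pk in got] == ["chr2", "chr1"]


class TestRepeatReader:
    def test_bed6_family_parsing(self, tmp_path):
        p = tmp_path / "r.bed"
        p.write_text("chr1\t500\t640\tSINE/B1\t0\t+\nchr1\t800\t940\tSINE/B1\t0\t-\n")
        plus, minus = read_repeats(p, "bed6_family")
        assert (plus.family, plus.subfamily, plus.head_pos) == ("SINE", "B1", 500)
        assert minus.head_pos == 939

    def test_missing_family_kept_as_unknown(self, tmp_path):
        p = tmp_path / "r.bed"
        p.write_text("chr1\t500\t640\tB1\t0\t+\n")
        (r,) = read_repeats(p, "bed6_family")
        assert (r.family, r.subfamily) == ("unknown", "B1")

    def test_repeatmasker_coordinates_normalized(self, tmp_path):
        # header + one plus and one C-strand row; coordinates 1-based inclusive
        p = tmp_path / "rm.out"
        p.write_text(
            "   SW  perc perc perc  query      position in query\n"
            "score  div. del. ins.  sequence   begin  end\n"
            "\n"
            "  463  1.3  0.6  1.7  chr1   501   640 (0) +  B1_Mm  SINE/B1  1 140 (0) 1\n"
            "  463  1.3  0.6  1.7  chr1  1501  1640 (0) C  B1_Mm  SINE/B1  1 140 (0) 2\n"
        )
        plus, minus = read_repeats(p, "repeatmasker_out")
        assert (plus.interval.start, plus.interval.end) == (500, 640)
        assert plus.interval.length == 140  # inclusive->half-open keeps length
        assert minus.interval.strand == "-"
        assert (minus.family, minus.subfamily) == ("SINE", "B1")

    def test_unknown_strand_symbol_errors(self, tmp_path):
        p = tmp_path / "rm.out"
        p.write_text(
            "  463  1.3  0.6  1.7  chr1  501  640 (0) ?  B1_Mm  SINE/B1  1 140 (0) 1\n"
        )
        with pytest.raises(ValueError, match="strand"):
            read_repeats(p, "repeatmasker_out")


class TestOverlaps:
    def test_half_open_abutting_do_not_overlap(self):
        assert not overlaps(iv(0, 100), iv(100, 200))
        assert overlaps(iv(0, 100), iv(99, 200))

    def test_agrees_with_per_base_membership(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            a0, b0 = sorted(rng.integers(0, 1000, size=2))
            a1, b1 = sorted(rng.integers(0, 1000, size=2))
            a = iv(a0, b0 + 1)
            b = iv(a1, b1 + 1)
            brute = bool(set(range(a.start, a.end)) & set(range(b.start, b.end)))
            assert overlaps(a, b) == brute
            assert overlaps(a, b) == overlaps(b, a)  # symmetry

    def test_different_chromosomes_never_overlap(self):
        assert not overlaps(iv(0, 100, "chr1"), iv(0, 100, "chr2"))


class TestWindowCount:
    @staticmethod
    def element(start, end, chrom="chr1"):
        return RepeatInstance(iv(start, end, chrom, "+"), "SINE", "B1")

    def test_element_near_summit_counted(self):
        peak = PeakRegion(iv(0, 4000), 2000)
        # midpoint 70 bp downstream of the summit, 140 bp long
        e = self.element(2000, 2140)
        assert window_count([peak], [e], w=500)[0] == 1

    def test_element_outside_window_not_counted(self):
        peak = PeakRegion(iv(0, 4000), 2000)
        assert window_count([peak], [self.element(2700, 2840)], w=500)[0] == 0

    def test_nonpositive_window_rejected(self):
        with pytest.raises(ValueError):
            window_count([], [], w=0)

    def test_matches_brute_force_double_loop(self):
        rng = np.random.default_rng(7)
        peaks, elements = [], []
        for _ in range(200):
            s = int(rng.integers(600, 9400))
            peaks.append(PeakRegion(iv(s - 250, s + 250), s))
            a = int(rng.integers(0, 9800))
            elements.append(self.element(a, a + int(rng.integers(50, 200))))
        got = window_count(peaks, elements, w=500)
        for i, p in enumerate(peaks):
            expected = sum(
                1
                for e in elements
                if e.interval.start < p.summit + 501 and e.interval.end > p.summit - 500
            )
            assert got[i] == expected


class TestShuffle:
    genome = GenomeIndex({"chrT": 10_000})

    def test_deterministic_given_seed(self):
        ivs = [iv(0, 100, "chrT"), iv(500, 900, "chrT")]
        assert shuffle_intervals(ivs, self.genome, 3) == shuffle_intervals(
            ivs, self.genome, 3
        )

    def test_length_multiset_preserved(self):
        ivs = [iv(0, 100, "chrT"), iv(0, 250, "chrT"), iv(0, 100, "chrT")]
        out = shuffle_intervals(ivs, self.genome, 1)
        assert sorted(o.length for o in out) == [100, 100, 250]

    def test_interval_longer_than_chromosome_errors(self):
        with pytest.raises(ValueError, match="longer"):
            shuffle_intervals([iv(0, 20_000, "chrT")], self.genome, 0)

    def test_start_distribution_uniform(self):
        # 10,000 shuffles of one 100 bp interval on a 10 kb chromosome
        starts = [
            shuffle_intervals([iv(0, 100, "chrT")], self.genome, seed)[0].start
            for seed in range(10_000)
        ]
        counts, _ = np.histogram(starts, bins=20, range=(0, 9901))
        assert stats.chisquare(counts).pvalue > 0.001


class TestBHAdjust:
    def test_hand_computed_example(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03]
        )

    def test_single_p_unchanged(self):
        assert bh_adjust([0.2])[0] == pytest.approx(0.2)

    def test_all_ones_stay_ones(self):
        assert np.all(bh_adjust([1.0, 1.0, 1.0]) == 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(min_value=0, max_value=1, allow_nan=False), min_size=1, max_size=30)
    )
    def test_monotone_and_bounded(self, pvals):
        q = bh_adjust(pvals)
        assert np.all((q >= 0) & (q <= 1))
        order = np.argsort(pvals, kind="stable")
        assert np.all(np.diff(q[order]) >= -1e-12)
        assert np.all(q >= np.asarray(pvals) - 1e-12)


def test_bed_round_trip_bit_exact(tmp_path):
    ivs = [
        GenomicInterval("chr1", 0, 100, "+", "a", 3.0),
        GenomicInterval("chr2", 50, 75, "-", "b", 0.0),
    ]
    path = tmp_path / "rt.bed"
    write_bed(ivs, path)
    got = read_bed(path)
    assert [(g.chrom, g.start, g.end, g.strand, g.name) for g in got] == [
        (i.chrom, i.start, i.end, i.strand, i.name) for i in ivs
    ]
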