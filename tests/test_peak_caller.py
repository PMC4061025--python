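"""Window partitioning, pipeline orchestration and BED output."""

import io

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from occupeak import (
    ChromTable,
    Peak,
    call_peaks,
    overlaps,
    partition_windows,
    read_bed,
    subsample_tags,
    write_bed,
)

from .conftest import RECONSTRUCTED_FRAGLEN


class TestPartitionWindows:
    def test_documented_placement(self):
        """len=250, ws=100 gives (0,100), (75,175), (150,250)."""
        windows = partition_windows(ChromTable({"c": 250}), 100)
        assert [(w.start, w.end) for w in windows] == [
            (0, 100), (75, 175), (150, 250),
        ]

    def test_default_is_one_window_per_chromosome(self):
        chroms = ChromTable({"c1": 1000, "c2": 500})
        windows = partition_windows(chroms, None)
        assert [(w.chrom, w.start, w.end) for w in windows] == [
            ("c1", 0, 1000), ("c2", 0, 500),
        ]

    def test_oversized_window_collapses_to_chromosome(self):
        (window,) = partition_windows(ChromTable({"c": 300}), 1000)
        assert (window.start, window.end) == (0, 300)

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(
        length=st.integers(2, 10_000),
        window_size=st.integers(1, 10_000),
    )
    def test_windows_cover_chromosome_with_bounded_overlap(
        self, length, window_size
    ):
        window_size = min(window_size, length)
        windows = partition_windows(ChromTable({"c": length}), window_size)
        starts = [w.start for w in windows]
        assert starts == sorted(starts)
        assert windows[0].start == 0 and windows[-1].end == length
        # contiguous cover: no gap between consecutive windows
        assert all(b.start <= a.end for a, b in zip(windows, windows[1:]))
        # minimal overlap: pairwise overlap never reaches a full window
        for a, b in zip(windows, windows[1:]):
            assert a.end - b.start <= window_size
        if window_size < length:
            assert all(w.length == window_size for w in windows)


class TestCallPeaks:
    def test_infinite_threshold_calls_nothing(self, spiked):
        spec, tags, _ = spiked
        peaks, _ = call_peaks(
            tags, spec.chroms, threshold=np.inf,
            fraglen_override=RECONSTRUCTED_FRAGLEN,
        )
        assert peaks == []

    def test_higher_threshold_calls_subset(self, spiked, spiked_called):
        spec, tags, _ = spiked
        base, _ = spiked_called
        stricter, _ = call_peaks(
            tags, spec.chroms, threshold=3.0,
            fraglen_override=RECONSTRUCTED_FRAGLEN,
        )
        base_set = {(p.chrom, p.start, p.end) for p in base}
        assert {(p.chrom, p.start, p.end) for p in stricter} <= base_set

    def test_summary_reports_fit_and_coverage(self, spiked_called):
        peaks, summary = spiked_called
        frame = summary.to_frame()
        assert summary.fragment_length == RECONSTRUCTED_FRAGLEN
        row = frame.iloc[0]
        assert row["status"] == "ok"
        assert 0 < row["p"] < 1 and row["A"] > 0 and row["B"] >= 0
        assert row["N1"] >= row["N2"] >= row["N3"] >= row["N4"] > 0
        assert row["n_peaks"] == len(peaks)
        assert 0 < row["coverage_total"] < 1
        assert row["coverage_mappable"] >= row["coverage_total"]

    def test_small_windows_gain_almost_no_peaks(self, spiked, spiked_called):
        """0.1 Mb windows lose weak peaks but gain few absent chromosome-wide."""
        spec, tags, _ = spiked
        chromwide, _ = spiked_called
        windowed, summary = call_peaks(
            tags, spec.chroms, window_size=100_000,
            fraglen_override=RECONSTRUCTED_FRAGLEN,
        )
        hit, _ = overlaps(
            [(p.chrom, p.start, p.end) for p in windowed],
            [(p.chrom, p.start, p.end) for p in chromwide],
        )
        gained = int((~hit).sum())
        assert gained / len(chromwide) <= 0.05

    def test_empty_input_rejected(self, chroms_10mb):
        with pytest.raises(ValueError, match="no tags"):
            call_peaks([], chroms_10mb, fraglen_override=100)


class TestSubsampleTags:
    def test_full_fraction_is_identity(self, null_tags):
        assert subsample_tags(null_tags, 1.0, seed=0) == list(null_tags)

    def test_kept_count_within_binomial_bounds(self, null_tags):
        kept = subsample_tags(null_tags, 0.5, seed=1)
        n = len(null_tags)
        sigma = np.sqrt(n * 0.25)
        assert abs(len(kept) - 0.5 * n) < 3 * sigma

    def test_deterministic_for_fixed_seed(self, null_tags):
        a = subsample_tags(null_tags, 0.125, seed=9)
        b = subsample_tags(null_tags, 0.125, seed=9)
        assert a == b

    def test_subsampled_peaks_stay_on_truth_loci(self, spiked):
        """At 12.5% of tags, every surviving peak still marks a true locus."""
        spec, tags, truth = spiked
        sub = subsample_tags(tags, 0.125, seed=13)
        peaks, _ = call_peaks(
            sub, spec.chroms, fraglen_override=RECONSTRUCTED_FRAGLEN
        )
        assert peaks  # the strongest loci survive subsampling
        on_truth, count = overlaps(
            [(p.chrom, p.start, p.end) for p in peaks], truth
        )
        assert count == len(peaks)

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            subsample_tags([], 0.0, seed=0)


class TestBedRoundTrip:
    PEAKS = [
        Peak("chr1", 1000, 1600, 7200, 3.41),
        Peak("chr1", 5000, 5400, 2100, 7.0),
        Peak("chr2", 10, 90, 400, 12.5),
    ]

    def test_row_formatting_and_category_colour(self):
        sink = io.StringIO()
        write_bed(self.PEAKS[:1], fragment_length=164, threshold=2.0, sink=sink)
        body = [l for l in sink.getvalue().splitlines()
                if not l.startswith(("#", "track"))]
        assert body == ["chr1\t1000\t1600\t7200\t3.41\t.\t0\t0\t255,0,0"]

    def test_header_carries_fraglen_and_threshold(self):
        sink = io.StringIO()
        write_bed([], fragment_length=217, threshold=2.5, sink=sink)
        text = sink.getvalue()
        assert "fragment_length=217" in text
        assert "log10_er_threshold=2.50" in text
        assert [l for l in text.splitlines()
                if not l.startswith(("#", "track"))] == []

    def test_colour_bands_follow_significance(self):
        sink = io.StringIO()
        write_bed(self.PEAKS, fragment_length=164, threshold=2.0, sink=sink)
        colours = [l.split("\t")[8] for l in sink.getvalue().splitlines()
                   if "\t" in l]
        assert colours == ["255,0,0", "0,128,0", "0,0,255"]

    def test_write_read_write_is_byte_identical(self):
        first = io.StringIO()
        write_bed(self.PEAKS, fragment_length=164, threshold=2.0, sink=first)
        peaks, meta = read_bed(io.StringIO(first.getvalue()))
        assert meta["fragment_length"] == 164
        second = io.StringIO()
        write_bed(peaks, meta["fragment_length"], meta["log10_er_threshold"],
                  sink=second)
        assert first.getvalue() == second.getvalue()

    def test_unsorted_or_duplicated_peaks_rejected(self):
        with pytest.raises(ValueError, match="sorted"):
            write_bed(self.PEAKS[::-1], 164, 2.0, io.StringIO())
        with pytest.raises(ValueError, match="duplicate"):
            write_bed([self.PEAKS[0]] * 2, 164, 2.0, io.StringIO())
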