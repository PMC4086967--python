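"""Quality filter, dynamic trim window and pair synchronization."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from snpmine.preprocess import (
    PreprocessCounters,
    PreprocessParams,
    QualityProfile,
    TrimWindow,
    build_quality_profile,
    compute_trim_window,
    filter_read,
    preprocess_file,
    preprocess_report,
    synchronize_pairs,
    trim_reads,
)
from snpmine.seqio import Read

PARAMS = PreprocessParams()


def read_with_quals(quals, read_id="r"):
    return Read(read_id=read_id, sequence="A" * len(quals), quals=list(quals))


class TestFilterRead:
    def test_boundary_31_percent_discarded(self):
        quals = [10] * 31 + [30] * 69
        assert filter_read(read_with_quals(quals), PARAMS) is False

    def test_boundary_30_percent_kept(self):
        quals = [10] * 30 + [30] * 70
        assert filter_read(read_with_quals(quals), PARAMS) is True

    def test_all_high_quality_kept(self):
        assert filter_read(read_with_quals([25] * 50), PARAMS) is True

    @given(st.lists(st.integers(0, 41), min_size=1, max_size=150))
    def test_matches_brute_force_counter(self, quals):
        read = read_with_quals(quals)
        n_low = len([q for q in quals if q < 20])
        expected = not (n_low / len(quals) > 0.30)
        assert filter_read(read, PARAMS) is expected


class TestQualityProfile:
    def test_hand_arithmetic_two_reads(self):
        profile = build_quality_profile(
            [read_with_quals([20, 30]), read_with_quals([40, 30])]
        )
        assert profile.per_position_mean == [30.0, 30.0]
        assert profile.dataset_mean == 30.0
        assert profile.n_reads == 2

    def test_single_read_profile_equals_quals(self):
        profile = build_quality_profile([read_with_quals([17, 23, 31])])
        assert profile.per_position_mean == [17.0, 23.0, 31.0]

    def test_unequal_lengths_average_over_covering_reads(self):
        # positions beyond a shorter read use only the reads reaching them
        reads = [
            read_with_quals([10, 20, 30]),
            read_with_quals([20, 40]),
            read_with_quals([30]),
        ]
        profile = build_quality_profile(reads)
        assert profile.per_position_mean == [20.0, 30.0, 30.0]
        assert profile.dataset_mean == pytest.approx(150 / 6)

    def test_empty_stream_is_error(self):
        with pytest.raises(ValueError, match="no reads"):
            build_quality_profile([])


class TestTrimWindow:
    def test_documented_scan_both_ends(self):
        profile = QualityProfile(
            per_position_mean=[25, 26, 38, 38, 38, 38, 27, 25],
            dataset_mean=31.625,
            n_reads=10,
        )
        window = compute_trim_window(profile, PARAMS)
        assert (window.start, window.end) == (3, 6)

    def test_uniformly_high_profile_identity(self):
        profile = QualityProfile([38.0] * 20, 38.0, 5)
        window = compute_trim_window(profile, PARAMS)
        assert (window.start, window.end) == (1, 20)

    def test_three_prime_decay_only(self):
        means = [38.0] * 16 + [30.0, 28.0, 25.0, 22.0]
        profile = QualityProfile(means, float(np.mean(means)), 5)
        window = compute_trim_window(profile, PARAMS)
        assert window.start == 1
        assert window.end < 20

    def test_all_low_profile_errors(self):
        profile = QualityProfile([10.0, 10.0], 40.0, 5)
        with pytest.raises(ValueError, match="below trim threshold"):
            compute_trim_window(profile, PARAMS)


class TestTrimReads:
    def test_window_cuts_to_coordinates(self):
        read = read_with_quals(list(range(100)))
        (out,) = trim_reads([read], TrimWindow(1, 86))
        assert len(out) == 86
        assert out.quals == list(range(86))

    def test_full_window_is_identity(self):
        read = read_with_quals([30] * 50)
        (out,) = trim_reads([read], TrimWindow(1, 50))
        assert out.sequence == read.sequence and out.quals == read.quals

    def test_read_shorter_than_start_discarded(self):
        counters = PreprocessCounters()
        out = list(trim_reads([read_with_quals([30] * 50)], TrimWindow(60, 90), counters))
        assert out == [] and counters.trim_discarded == 1

    @given(st.lists(st.integers(0, 41), min_size=1, max_size=120),
           st.integers(1, 60), st.integers(0, 60))
    def test_never_lengthens(self, quals, start, extra):
        read = read_with_quals(quals)
        out = list(trim_reads([read], TrimWindow(start, start + extra)))
        assert all(len(o) <= len(read) for o in out)


class TestSynchronizePairs:
    def mk(self, ids, mate):
        return [Read(f"{i}/{mate}", "AC", [30, 30]) for i in ids]

    def test_set_intersection(self):
        p1, p2, orphans = synchronize_pairs(self.mk("abc", 1), self.mk("bcd", 2))
        assert [r.read_id for r in p1] == ["b/1", "c/1"]
        assert [r.read_id for r in p2] == ["b/2", "c/2"]
        assert orphans == 2

    def test_identical_sets_no_orphans(self):
        p1, p2, orphans = synchronize_pairs(self.mk("abc", 1), self.mk("abc", 2))
        assert len(p1) == len(p2) == 3 and orphans == 0
        assert [r.read_id[:-2] for r in p1] == [r.read_id[:-2] for r in p2]

    def test_empty_second_file(self):
        p1, p2, orphans = synchronize_pairs(self.mk("abc", 1), [])
        assert p1 == [] and p2 == [] and orphans == 3

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            synchronize_pairs(self.mk("aa", 1), self.mk("ab", 2))


class TestReportAndConservation:
    def test_retained_percentage(self):
        counters = PreprocessCounters(raw=1000, kept=950)
        report = preprocess_report(counters, None, {"f": TrimWindow(1, 86)})
        assert report["retained_pct"] == 95.0
        assert report["trim_windows"]["f"] == "keep 1-86"

    def test_every_read_counted_once(self, rng):
        reads = [
            read_with_quals([int(q) for q in rng.integers(15, 42, size=rng.integers(20, 101))],
                            read_id=f"r{i}")
            for i in range(500)
        ]
        _, _, _, counters = preprocess_file(reads, PARAMS)
        assert counters.kept + counters.filter_discarded + counters.trim_discarded == counters.raw
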