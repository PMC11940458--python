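"""Careless/incomplete rater exclusion and 3-SD response trimming."""

import numpy as np
import pandas as pd
import pytest

from dimnorms.qc_trimming import (drop_raters, expected_counts_from_lists,
                                  flag_careless, flag_incomplete,
                                  trim_responses)
from dimnorms.ratings_io import RatingRecord
from dimnorms.synthetic_ratings import (GeneratorConfig, inject_careless,
                                        make_profiles, simulate_ratings)


def _records(rater, values, variable="SOC", word_prefix="w"):
    return [RatingRecord(rater, "L0", f"{word_prefix}{i}", variable, float(v))
            for i, v in enumerate(values)]


class TestFlagCareless:
    def test_all_identical_flagged(self):
        recs = _records("r1", [4] * 80)
        assert flag_careless(recs) == {"r1"}

    def test_modal_share_exactly_at_threshold_not_flagged(self):
        # 17 of 20 = 0.85 exactly: strict inequality spares the rater
        recs = _records("r1", [4] * 17 + [1, 2, 3])
        assert flag_careless(recs) == frozenset()
        # one more modal response crosses the line
        recs = _records("r1", [4] * 18 + [1, 2])
        assert flag_careless(recs) == {"r1"}

    def test_aoa_excluded_from_pool(self):
        # constant AoA answers alone cannot make a rater careless
        recs = (_records("r1", [5] * 10, variable="AoA")
                + _records("r1", [1, 2, 3, 4, 5, 6, 7], word_prefix="x"))
        assert flag_careless(recs) == frozenset()

    def test_planted_careless_recovered_exactly(self):
        cfg = GeneratorConfig(n_items=120, n_concrete=20, n_lists=4,
                              raters_per_list=25, noise_sd=0.8,
                              careless_rate=0.12, seed=13)
        frame = simulate_ratings(make_profiles(cfg), cfg)
        frame, planted = inject_careless(frame, cfg)
        assert flag_careless(frame) == planted
        assert len(planted) == round(0.12 * 50)


class TestFlagIncomplete:
    def test_missing_responses_flagged(self):
        recs = _records("r1", [4, 5, 6])
        assert flag_incomplete(recs, {"r1": 4}) == {"r1"}
        assert flag_incomplete(recs, {"r1": 3}) == frozenset()

    def test_completeness_fraction(self):
        recs = _records("r1", [4] * 19)
        assert flag_incomplete(recs, {"r1": 20}, 0.9) == frozenset()
        assert flag_incomplete(recs, {"r1": 20}, 1.0) == {"r1"}

    def test_rater_with_zero_responses_flagged(self):
        recs = _records("r1", [4, 5])
        assert "ghost" in flag_incomplete(recs, {"r1": 2, "ghost": 2})

    def test_expected_counts_from_list_design(self, small_dataset):
        frame, _, _ = small_dataset
        expected = expected_counts_from_lists(frame)
        observed = frame.groupby("rater_id").size()
        for rater, exp in expected.items():
            assert observed[rater] == exp  # complete synthetic data


class TestTrimResponses:
    def test_constant_cell_untouched(self):
        recs = [RatingRecord(f"r{i}", "L0", "w0", "SOC", 4.0) for i in range(5)]
        kept, report = trim_responses(recs)
        assert len(kept) == 5
        assert report.removed_responses == []

    def test_single_extreme_removed_hand_oracle(self):
        # cell of 24 sixes and one 1: mean 5.8, sample SD 1.0,
        # |1 - 5.8| = 4.8 > 3; the 1 goes, nothing else does
        values = [6.0] * 24 + [1.0]
        recs = [RatingRecord(f"r{i}", "L0", "w0", "SOC", v)
                for i, v in enumerate(values)]
        arr = np.array(values)
        assert arr.mean() == pytest.approx(5.8)
        assert arr.std(ddof=1) == pytest.approx(1.0)
        kept, report = trim_responses(recs)
        assert report.removed_responses == [("r24", "w0", "SOC")]
        assert len(kept) == 24

    def test_leave_one_out_variant_more_aggressive(self):
        values = [6.0] * 10 + [3.0]
        recs = [RatingRecord(f"r{i}", "L0", "w0", "SOC", v)
                for i, v in enumerate(values)]
        _, inclusive = trim_responses(recs)
        _, loo = trim_responses(recs, leave_one_out=True)
        assert len(loo.removed_responses) >= len(inclusive.removed_responses)
        assert loo.removed_responses == [("r10", "w0", "SOC")]

    def test_report_percentages_bounded(self, small_dataset):
        frame, _, _ = small_dataset
        _, report = trim_responses(frame)
        for pct in report.pct_removed_by_variable.values():
            assert 0.0 <= pct <= 100.0

    def test_planted_outliers_removed_and_rate_low(self):
        """On contaminated synthetic data the 3-SD sweep removes the
        planted extremes at >=90% sensitivity and stays below the 2%
        per-variable removal level typical of norming studies."""
        from dimnorms.synthetic_ratings import inject_outliers
        cfg = GeneratorConfig(n_items=160, n_concrete=20, n_lists=4,
                              raters_per_list=25, noise_sd=0.5,
                              outlier_rate=0.005, seed=42)
        frame = simulate_ratings(make_profiles(cfg), cfg)
        frame, planted = inject_outliers(frame, cfg)
        kept, report = trim_responses(frame)
        removed = set(report.removed_responses)
        sensitivity = len(set(planted) & removed) / len(planted)
        assert sensitivity >= 0.90
        assert max(report.pct_removed_by_variable.values()) < 2.0

    def test_trimming_decrements_counts_only(self, small_dataset):
        frame, _, _ = small_dataset
        kept, report = trim_responses(frame)
        assert len(kept) + len(report.removed_responses) == len(frame)
        # no cell was emptied
        before = frame.groupby(["word", "variable"]).size()
        after = kept.groupby(["word", "variable"]).size()
        assert set(after.index) == set(before.index)


def test_drop_raters(small_dataset):
    frame, _, _ = small_dataset
    some = set(list(frame["rater_id"].unique())[:3])
    out = drop_raters(frame, some)
    assert not out["rater_id"].isin(some).any()
    assert len(out) == len(frame) - frame["rater_id"].isin(some).sum()
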