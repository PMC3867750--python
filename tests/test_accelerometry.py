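import datetime

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from dietval import (
    CountStream,
    ValidationError,
    detect_nonwear,
    parse_counts,
    summarize_activity,
    summarize_days,
)
from dietval.accelerometry import WearDay


def make_stream(counts, start="2011-01-10 08:00", period="baseline"):
    counts = np.asarray(counts, dtype=np.int64)
    ts = pd.date_range(start, periods=len(counts), freq="min")
    return CountStream("S1", period, ts, counts)


def brute_force_nonwear(counts, min_run=20):
    """Independent covering-window scan: an epoch is non-wear iff some
    window of min_run consecutive zeros contains it."""
    n = len(counts)
    wear = [True] * n
    for start in range(n - min_run + 1):
        if all(counts[start + j] == 0 for j in range(min_run)):
            for j in range(min_run):
                wear[start + j] = False
    return wear


class TestStreamValidation:
    def test_negative_counts_rejected(self):
        with pytest.raises(ValidationError):
            make_stream([1, -5, 2])

    def test_gap_in_timestamps_rejected(self):
        ts = pd.DatetimeIndex(
            ["2011-01-10 08:00", "2011-01-10 08:01", "2011-01-10 08:03"]
        )
        with pytest.raises(ValidationError):
            CountStream("S1", "baseline", ts, np.array([1, 2, 3]))

    def test_unknown_period_rejected(self):
        with pytest.raises(ValidationError):
            make_stream([1, 2], period="washout")


class TestParseCounts:
    def test_empty_file(self, tmp_path):
        p = tmp_path / "c.csv"
        p.write_text("subject_id,period,timestamp,counts\n")
        assert parse_counts(p) == []

    def test_week_of_epochs_is_one_stream(self, tmp_path):
        ts = pd.date_range("2011-01-10", periods=7 * 1440, freq="min")
        df = pd.DataFrame(
            {"subject_id": "S1", "period": "baseline",
             "timestamp": ts.strftime("%Y-%m-%dT%H:%M"), "counts": 1}
        )
        p = tmp_path / "c.csv"
        df.to_csv(p, index=False)
        streams = parse_counts(p)
        assert len(streams) == 1 and len(streams[0]) == 10080

    def test_negative_row_reports_line(self, tmp_path):
        p = tmp_path / "c.csv"
        p.write_text(
            "subject_id,period,timestamp,counts\n"
            "S1,baseline,2011-01-10T08:00,10\n"
            "S1,baseline,2011-01-10T08:01,-5\n"
        )
        with pytest.raises(ValidationError, match="line 3"):
            parse_counts(p)

    def test_duplicate_timestamp_rejected(self, tmp_path):
        p = tmp_path / "c.csv"
        p.write_text(
            "subject_id,period,timestamp,counts\n"
            "S1,baseline,2011-01-10T08:00,10\n"
            "S1,baseline,2011-01-10T08:00,11\n"
        )
        with pytest.raises(ValidationError, match="duplicate"):
            parse_counts(p)


class TestDetectNonwear:
    def test_exact_twenty_zero_run_flagged(self):
        counts = [5] + [0] * 20 + [5]
        wear = detect_nonwear(make_stream(counts))
        assert wear[0] and wear[-1]
        assert not wear[1:21].any()

    def test_nineteen_zero_run_kept_as_wear(self):
        counts = [5] + [0] * 19 + [5]
        assert detect_nonwear(make_stream(counts)).all()

    def test_all_nonzero_all_wear(self):
        assert detect_nonwear(make_stream([3] * 100)).all()

    def test_boundary_run_counts_as_nonwear(self):
        counts = [0] * 25 + [5] * 10
        wear = detect_nonwear(make_stream(counts))
        assert not wear[:25].any() and wear[25:].all()

    def test_min_run_below_one_rejected(self):
        with pytest.raises(ValueError):
            detect_nonwear(make_stream([1, 0, 1]), min_run_minutes=0)

    @given(
        st.lists(
            st.integers(0, 3).map(lambda x: 0 if x < 2 else x * 50),
            min_size=30, max_size=300,
        )
    )
    @settings(derandomize=True, max_examples=60, deadline=None)
    def test_matches_covering_window_oracle(self, counts):
        wear = detect_nonwear(make_stream(counts))
        assert wear.tolist() == brute_force_nonwear(counts)

    @given(st.lists(st.integers(0, 100), min_size=25, max_size=200))
    @settings(derandomize=True, max_examples=40, deadline=None)
    def test_prepending_nonzero_epoch_preserves_flags(self, counts):
        base = detect_nonwear(make_stream(counts))
        shifted = detect_nonwear(make_stream([7] + counts))
        assert shifted[0]
        assert shifted[1:].tolist() == base.tolist()

    def test_lengthening_run_never_increases_wear(self):
        for fill in range(25):
            counts = [5] * 10 + [0] * fill + [5] * 10
            short = int(detect_nonwear(make_stream(counts)).sum())
            longer = int(
                detect_nonwear(make_stream([5] * 10 + [0] * (fill + 1) + [5] * 10)).sum()
            )
            assert longer <= short + 1  # the extra epoch can add at most itself
            if fill >= 20:
                assert longer == short


class TestSummarizeDays:
    def _day(self, wear_minutes, counts_per_min=500):
        # one calendar day with the requested amount of wear
        active = [counts_per_min] * wear_minutes
        off = [0] * (1440 - wear_minutes)
        return make_stream(active + off, start="2011-01-10 00:00")

    @pytest.mark.parametrize("minutes,valid", [(780, True), (779, False)])
    def test_thirteen_hour_rule_is_strict(self, minutes, valid):
        stream = self._day(minutes)
        days = summarize_days(stream, detect_nonwear(stream))
        assert len(days) == 1
        assert days[0].valid is valid
        assert days[0].wear_minutes == minutes

    def test_constant_counts_give_that_cpm(self):
        stream = self._day(800, counts_per_min=500)
        days = summarize_days(stream, detect_nonwear(stream))
        assert days[0].cpm == pytest.approx(500.0)

    def test_weekend_flag(self):
        sat = make_stream([5] * 1440, start="2011-01-15 00:00")  # Saturday
        days = summarize_days(sat, detect_nonwear(sat))
        assert days[0].is_weekend

    def test_wear_nonwear_partition(self):
        stream = make_stream([5] * 100 + [0] * 40 + [5] * 100)
        mask = detect_nonwear(stream)
        days = summarize_days(stream, mask)
        assert sum(d.wear_minutes for d in days) + int((~mask).sum()) == len(stream)


def wd(date_str, weekend, wear, cpm=500.0, valid=None):
    valid = wear >= 780 if valid is None else valid
    return WearDay(
        date=datetime.date.fromisoformat(date_str), is_weekend=weekend,
        wear_minutes=wear, total_counts=int(cpm * wear), cpm=cpm, valid=valid,
    )


class TestSummarizeActivity:
    def test_three_weekdays_one_weekend_meets_criteria(self):
        days = [
            wd("2011-01-10", False, 800), wd("2011-01-11", False, 800),
            wd("2011-01-12", False, 800), wd("2011-01-15", True, 800),
        ]
        assert summarize_activity(days).meets_criteria

    def test_five_weekdays_without_weekend_fails(self):
        days = [wd(f"2011-01-1{i}", False, 800) for i in range(5)]
        s = summarize_activity(days)
        assert s.n_valid_days == 5 and not s.meets_criteria

    def test_mean_cpm_averages_daily_values(self):
        days = [
            wd("2011-01-10", False, 800, cpm=400.0),
            wd("2011-01-11", False, 800, cpm=600.0),
        ]
        assert summarize_activity(days).mean_cpm == pytest.approx(500.0)

    def test_pooled_method_weights_by_minutes(self):
        days = [
            wd("2011-01-10", False, 800, cpm=400.0),
            wd("2011-01-11", False, 1000, cpm=600.0),
        ]
        pooled = summarize_activity(days, cpm_method="pooled").mean_cpm
        assert pooled == pytest.approx((400 * 800 + 600 * 1000) / 1800)

    def test_empty_day_list(self):
        s = summarize_activity([])
        assert not s.meets_criteria and np.isnan(s.mean_cpm)
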