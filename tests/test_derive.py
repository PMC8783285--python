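"""Derivation of per-day routine variables from epoch records."""

import numpy as np
import pandas as pd
import pytest

from watchroutine.derive import (
    DerivationError,
    compute_non_watch,
    derive_person_days,
    flag_window_validity,
    non_watch_minutes,
    sleep_intervals,
)

from conftest import brute_force_person_days, random_records


def _records(rows):
    return pd.DataFrame(rows, columns=["participant_id", "timestamp", "heart_rate", "steps"])


class TestDerivePersonDays:
    def test_direct_construction(self):
        rec = _records(
            [
                ("A", "2020-01-01T07:00", 70, 10),
                ("A", "2020-01-01T07:01", 72, 5),
                ("A", "2020-01-01T22:30", 68, 3),
            ]
        )
        out = derive_person_days(rec)
        assert len(out) == 1
        row = out.iloc[0]
        assert row.first_watch_time == 420
        assert row.last_watch_time == 1350
        assert row.wear_minutes == 3
        assert row.step_total == 18

    def test_duplicate_minutes_dedup_wear_sum_steps(self):
        rec = _records(
            [
                ("A", "2020-01-01T08:00", 70, 10),
                ("A", "2020-01-01T08:00", 71, 7),
            ]
        )
        out = derive_person_days(rec)
        assert out.iloc[0].wear_minutes == 1
        assert out.iloc[0].step_total == 17

    def test_record_without_signal_is_not_watch_time(self):
        rec = _records(
            [
                ("A", "2020-01-01T05:00", np.nan, np.nan),
                ("A", "2020-01-01T08:00", 70, 1),
            ]
        )
        out = derive_person_days(rec)
        assert out.iloc[0].first_watch_time == 480

    def test_unparseable_timestamp_strict_and_lenient(self):
        rec = _records(
            [("A", "2020-01-01T08:00", 70, 1), ("A", "not-a-time", 70, 1)]
        )
        with pytest.raises(DerivationError):
            derive_person_days(rec)
        out = derive_person_days(rec, lenient=True)
        assert len(out) == 1

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_scan(self, seed):
        rng = np.random.default_rng(seed)
        rec = random_records(rng, n_records=80)
        got = derive_person_days(rec).reset_index(drop=True)
        want = brute_force_person_days(rec)
        got["date"] = pd.to_datetime(got["date"])
        pd.testing.assert_frame_equal(got, want, check_dtype=False)

    def test_insensitive_to_record_order(self):
        rng = np.random.default_rng(42)
        rec = random_records(rng, n_records=120)
        shuffled = rec.sample(frac=1, random_state=1).reset_index(drop=True)
        a = derive_person_days(rec).reset_index(drop=True)
        b = derive_person_days(shuffled).reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b)

    def test_interior_record_changes_only_wear_and_steps(self):
        base = _records(
            [("A", "2020-01-01T07:00", 70, 10), ("A", "2020-01-01T22:00", 70, 5)]
        )
        added = pd.concat(
            [base, _records([("A", "2020-01-01T12:00", 70, 4)])], ignore_index=True
        )
        a = derive_person_days(base).iloc[0]
        b = derive_person_days(added).iloc[0]
        assert a.first_watch_time == b.first_watch_time
        assert a.last_watch_time == b.last_watch_time
        assert b.wear_minutes == a.wear_minutes + 1
        assert b.step_total == a.step_total + 4


class TestWindowFlags:
    def _day(self, pid, date, first, last):
        return {
            "participant_id": pid,
            "date": pd.Timestamp(date),
            "first_watch_time": first,
            "last_watch_time": last,
            "wear_minutes": last - first + 1,
            "step_total": 0,
        }

    def test_midday_single_record_fails_both_windows(self):
        rec = _records([("A", "2020-01-01T13:00", 70, 1)])
        flagged = flag_window_validity(derive_person_days(rec))
        row = flagged.iloc[0]
        assert row.first_watch_time == 780 and not row.first_valid
        assert row.last_watch_time == 780 and not row.last_valid

    @pytest.mark.parametrize(
        "first,valid", [(239, False), (240, True), (720, True), (721, False)]
    )
    def test_first_window_boundaries(self, first, valid):
        days = pd.DataFrame([self._day("A", "2020-01-01", first, 1300)])
        assert flag_window_validity(days).iloc[0].first_valid == valid

    @pytest.mark.parametrize(
        "last,next_first,valid",
        [
            (1150, 430, True),
            (1139, 430, False),
            (1150, 239, False),  # next day starts before 4 AM
            (1140, 240, True),
        ],
    )
    def test_last_window_with_next_day(self, last, next_first, valid):
        days = pd.DataFrame(
            [
                self._day("A", "2020-01-01", 400, last),
                self._day("A", "2020-01-02", next_first, 1300),
            ]
        )
        assert flag_window_validity(days).iloc[0].last_valid == valid

    def test_last_invalid_when_next_day_absent(self):
        days = pd.DataFrame(
            [
                self._day("A", "2020-01-01", 400, 1150),
                self._day("A", "2020-01-03", 430, 1300),  # gap day
            ]
        )
        assert not flag_window_validity(days).iloc[0].last_valid


class TestNonWatch:
    def _flagged(self, rows):
        days = pd.DataFrame(rows)
        return flag_window_validity(days)

    def _day(self, pid, date, first, last):
        return {
            "participant_id": pid,
            "date": pd.Timestamp(date),
            "first_watch_time": first,
            "last_watch_time": last,
            "wear_minutes": 1,
            "step_total": 0,
        }

    @pytest.mark.parametrize(
        "last,next_first,expected",
        [(1320, 420, 540), (1439, 240, 241), (1140, 720, 1020)],
    )
    def test_interval_arithmetic(self, last, next_first, expected):
        assert non_watch_minutes(last, next_first) == expected
        flagged = self._flagged(
            [
                self._day("A", "2020-01-01", 400, last),
                self._day("A", "2020-01-02", next_first, 1300),
            ]
        )
        iv = sleep_intervals(flagged)
        assert len(iv) == 1
        assert iv.iloc[0].non_watch_minutes == expected

    def test_gap_day_voids_interval(self):
        flagged = self._flagged(
            [
                self._day("A", "2020-01-01", 400, 1320),
                self._day("A", "2020-01-03", 420, 1320),
            ]
        )
        assert sleep_intervals(flagged).empty

    def test_adjacent_watch_day_mode_bridges_gap(self):
        flagged = self._flagged(
            [
                self._day("A", "2020-01-01", 400, 1320),
                self._day("A", "2020-01-03", 420, 1320),
            ]
        )
        iv = sleep_intervals(flagged, adjacent_watch_days=True)
        assert len(iv) == 1  # the bridged night; the final day has no successor
        assert iv.iloc[0].non_watch_minutes == 2 * 1440 - 1320 + 420

    def test_scalar_non_watch_precondition(self):
        a = dict(
            participant_id="A", date=pd.Timestamp("2020-01-01"),
            last_watch_time=1320, first_watch_time=400,
            first_valid=True, last_valid=True,
        )
        b = dict(
            participant_id="A", date=pd.Timestamp("2020-01-03"),
            last_watch_time=1320, first_watch_time=420,
            first_valid=True, last_valid=True,
        )
        with pytest.raises(ValueError, match="calendar days apart"):
            compute_non_watch(a, b)
        b["date"] = pd.Timestamp("2020-01-02")
        assert compute_non_watch(a, b) == 540
        b["participant_id"] = "B"
        with pytest.raises(ValueError, match="different participants"):
            compute_non_watch(a, b)
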