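"""Per-day routine variables from epoch-level smartwatch records.

A minute counts as *watch time* when the device reported any heart-rate or
step observation in it.  On each calendar day the earliest such minute proxies
wake-up time and the latest proxies bedtime, provided they fall in the
plausibility windows ([4 AM, noon] and [7 PM, midnight)); the overnight gap
between a day's last watch time and the next consecutive day's first watch
time proxies sleep duration.

Times are integer minutes since local midnight on naive local timestamps; the
windows never wrap midnight, so no circular arithmetic is needed.  A record
stamped exactly 00:00 belongs to that calendar date.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: first watch time window: closed [4:00, 12:00], minutes since midnight
FIRST_WINDOW = (240, 720)
#: last watch time window: [19:00, 24:00) — midnight belongs to the next day
LAST_WINDOW = (1140, 1440)

PERSON_DAY_COLUMNS = [
    "participant_id",
    "date",
    "first_watch_time",
    "last_watch_time",
    "wear_minutes",
    "step_total",
]


class DerivationError(ValueError):
    """Raised for unparseable records in strict mode."""


def derive_person_days(records: pd.DataFrame, lenient: bool = False) -> pd.DataFrame:
    """Aggregate epoch records into one row per participant per calendar day.

    Parameters
    ----------
    records
        Columns ``participant_id, timestamp, heart_rate, steps``; duplicate
        minutes are allowed (wear minutes are de-duplicated, steps on
        duplicates summed).  Rows with neither heart rate nor steps are not
        watch time and are dropped.
    lenient
        When true, unparseable timestamps are skipped with a warning instead
        of raising :class:`DerivationError`.

    Returns
    -------
    DataFrame with :data:`PERSON_DAY_COLUMNS`; days with no records are
    simply absent (never zero-filled).  ``first_watch_time``/
    ``last_watch_time`` are minutes since midnight.
    """
    df = records.copy()
    ts = pd.to_datetime(df["timestamp"], errors="coerce", format="ISO8601")
    bad = ts.isna() & df["timestamp"].notna()
    if bad.any():
        rows = df.index[bad].tolist()
        if not lenient:
            raise DerivationError(
                f"unparseable timestamp in rows {rows[:10]}"
                + ("..." if len(rows) > 10 else "")
            )
        logger.warning("skipping %d records with unparseable timestamps", bad.sum())
    df = df.loc[~bad & ts.notna()].copy()
    df["timestamp"] = ts.loc[df.index]

    hr = pd.to_numeric(df.get("heart_rate"), errors="coerce")
    st = pd.to_numeric(df.get("steps"), errors="coerce")
    watch = hr.notna() | st.notna()
    df = df.loc[watch].copy()
    df["steps"] = st.loc[df.index].fillna(0)

    if df.empty:
        return pd.DataFrame(columns=PERSON_DAY_COLUMNS)

    df["date"] = df["timestamp"].dt.normalize()
    df["minute"] = df["timestamp"].dt.hour * 60 + df["timestamp"].dt.minute

    grouped = df.groupby(["participant_id", "date"], sort=True)
    out = grouped.agg(
        first_watch_time=("minute", "min"),
        last_watch_time=("minute", "max"),
        wear_minutes=("minute", "nunique"),
        step_total=("steps", "sum"),
    ).reset_index()
    out["first_watch_time"] = out["first_watch_time"].astype(int)
    out["last_watch_time"] = out["last_watch_time"].astype(int)
    out["wear_minutes"] = out["wear_minutes"].astype(int)
    out["step_total"] = out["step_total"].round().astype(int)
    return out[PERSON_DAY_COLUMNS]


def flag_window_validity(
    person_days: pd.DataFrame,
    first_window: tuple = FIRST_WINDOW,
    last_window: tuple = LAST_WINDOW,
) -> pd.DataFrame:
    """Attach ``first_valid``/``last_valid`` flags to a person-day table.

    ``first_valid`` ⇔ the first watch time lies in the closed first window.
    ``last_valid`` ⇔ the last watch time lies in ``[last_window[0],
    last_window[1])`` *and* the immediately following calendar date has
    records whose first watch time is at or after the first window's lower
    bound (so the last watch time cannot be a post-midnight carryover).
    Days failing a window keep their steps and wear minutes; only that
    variable is excluded downstream.
    """
    df = person_days.copy()
    if df.empty:
        df["first_valid"] = pd.Series(dtype=bool)
        df["last_valid"] = pd.Series(dtype=bool)
        return df
    df["date"] = pd.to_datetime(df["date"])
    df = df.sort_values(["participant_id", "date"], kind="mergesort").reset_index(drop=True)

    lo_f, hi_f = first_window
    lo_l, hi_l = last_window
    df["first_valid"] = df["first_watch_time"].between(lo_f, hi_f)

    same_pid = df["participant_id"].shift(-1) == df["participant_id"]
    next_is_tomorrow = df["date"].shift(-1) == df["date"] + pd.Timedelta(days=1)
    next_first = df["first_watch_time"].shift(-1)
    df["last_valid"] = (
        (df["last_watch_time"] >= lo_l)
        & (df["last_watch_time"] < hi_l)
        & same_pid
        & next_is_tomorrow
        & (next_first >= lo_f)
    )
    return df


def non_watch_minutes(last_watch_time: int, next_first_watch_time: int) -> int:
    """Overnight non-watch minutes between two consecutive calendar days."""
    return (1440 - last_watch_time) + next_first_watch_time


def compute_non_watch(day, next_day):
    """Non-watch interval for one night, or ``None`` when a window fails.

    ``day`` and ``next_day`` are person-day rows (mappings with ``date``,
    ``last_watch_time``/``first_watch_time`` and validity flags) on
    consecutive calendar dates for the same participant; non-consecutive
    dates violate the precondition and raise ``ValueError``.
    """
    if day["participant_id"] != next_day["participant_id"]:
        raise ValueError("person-days belong to different participants")
    gap = (pd.Timestamp(next_day["date"]) - pd.Timestamp(day["date"])).days
    if gap != 1:
        raise ValueError(f"person-days are {gap} calendar days apart, expected 1")
    if not (day["last_valid"] and next_day["first_valid"]):
        return None
    return non_watch_minutes(int(day["last_watch_time"]), int(next_day["first_watch_time"]))


def sleep_intervals(
    flagged_days: pd.DataFrame, adjacent_watch_days: bool = False
) -> pd.DataFrame:
    """Non-watch (sleep-proxy) intervals across consecutive valid days.

    One row per night: ``participant_id, date`` (the earlier day) and
    ``non_watch_minutes = (1440 - last_watch_time) + next day's
    first_watch_time``, emitted only when the earlier day's last watch time
    and the following day's first watch time are both valid.

    By default the two days must be adjacent *calendar* dates (a skipped day
    voids that night's interval).  With ``adjacent_watch_days=True`` the next
    *watch* day is used even if calendar days were skipped, and the
    intervening full days are counted; the [240, 1020]-minute closure bound
    then no longer applies.
    """
    df = flagged_days.sort_values(["participant_id", "date"], kind="mergesort").reset_index(
        drop=True
    )
    if df.empty:
        return pd.DataFrame(columns=["participant_id", "date", "non_watch_minutes"])
    df["date"] = pd.to_datetime(df["date"])

    same_pid = df["participant_id"].shift(-1) == df["participant_id"]
    gap_days = (df["date"].shift(-1) - df["date"]).dt.days
    next_first = df["first_watch_time"].shift(-1)
    next_first_valid = df["first_valid"].shift(-1, fill_value=False)

    if adjacent_watch_days:
        pairable = same_pid & gap_days.notna()
        # last_valid conditions on the adjacent *calendar* day; re-derive the
        # window part against the next watch day instead.
        lo_l, hi_l = LAST_WINDOW
        last_ok = (
            (df["last_watch_time"] >= lo_l)
            & (df["last_watch_time"] < hi_l)
            & (next_first >= FIRST_WINDOW[0])
        )
        mask = pairable & last_ok & next_first_valid
        nw = (gap_days * 1440 - df["last_watch_time"] + next_first)[mask]
    else:
        mask = same_pid & (gap_days == 1) & df["last_valid"] & next_first_valid
        nw = (1440 - df["last_watch_time"] + next_first)[mask]

    out = pd.DataFrame(
        {
            "participant_id": df.loc[mask, "participant_id"],
            "date": df.loc[mask, "date"],
            "non_watch_minutes": nw.astype(int),
        }
    ).reset_index(drop=True)
    return out
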