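import numpy as np
import pandas as pd
import pytest

from watchroutine.pipeline import run_pipeline
from watchroutine.simulate import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def tiny_config():
    """Six participants, two per glycemic group, short follow-up."""
    return SimulationConfig(
        n_participants=6,
        group_proportions=(1 / 3, 1 / 3, 1 / 3),
        followup_median_days=15,
        followup_min_days=5,
        followup_cap_days=25,
        seed=7,
    )


@pytest.fixture(scope="session")
def tiny_minute_cohort(tiny_config):
    return simulate_cohort(tiny_config, resolution="minute")


@pytest.fixture(scope="session")
def small_cohort():
    """150 participants at day resolution; enough for stable group stats."""
    cfg = SimulationConfig(n_participants=150, seed=11, followup_cap_days=100)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def small_pipeline(small_cohort):
    return run_pipeline(small_cohort.person_days, small_cohort.baselines)


def random_records(rng, n_records=60, n_participants=3, n_days=4):
    """A random epoch-record fixture with duplicate minutes allowed."""
    pids = rng.choice([f"S{i}" for i in range(n_participants)], size=n_records)
    day = rng.integers(0, n_days, size=n_records)
    minute = rng.integers(0, 1440, size=n_records)
    base = pd.Timestamp("2020-03-01")
    ts = [
        (base + pd.Timedelta(days=int(d), minutes=int(m))).strftime("%Y-%m-%dT%H:%M")
        for d, m in zip(day, minute)
    ]
    hr = np.where(rng.random(n_records) < 0.8, rng.integers(45, 160, n_records), np.nan)
    steps = np.where(rng.random(n_records) < 0.8, rng.integers(0, 120, n_records), np.nan)
    return pd.DataFrame(
        {"participant_id": pids, "timestamp": ts, "heart_rate": hr, "steps": steps}
    )


def brute_force_person_days(records):
    """Independent per-day scan: min/max minute, distinct minutes, step sum."""
    acc = {}
    for row in records.itertuples(index=False):
        hr_missing = pd.isna(row.heart_rate)
        steps_missing = pd.isna(row.steps)
        if hr_missing and steps_missing:
            continue
        ts = pd.Timestamp(row.timestamp)
        key = (row.participant_id, ts.normalize())
        minute = ts.hour * 60 + ts.minute
        d = acc.setdefault(key, {"minutes": set(), "steps": 0})
        d["minutes"].add(minute)
        d["steps"] += 0 if steps_missing else int(row.steps)
    rows = [
        {
            "participant_id": pid,
            "date": date,
            "first_watch_time": min(d["minutes"]),
            "last_watch_time": max(d["minutes"]),
            "wear_minutes": len(d["minutes"]),
            "step_total": d["steps"],
        }
        for (pid, date), d in sorted(acc.items())
    ]
    return pd.DataFrame(rows)


def brute_force_flags_and_nonwatch(day_rows):
    """Window flags and overnight intervals by direct enumeration.

    ``day_rows`` is a list of dicts with participant_id, date (Timestamp),
    first_watch_time, last_watch_time.  Returns ({(pid, date): (first_valid,
    last_valid)}, {(pid, date): non_watch_minutes}).
    """
    index = {(r["participant_id"], r["date"]): r for r in day_rows}
    flags, nonwatch = {}, {}
    for (pid, date), r in index.items():
        first_valid = 240 <= r["first_watch_time"] <= 720
        nxt = index.get((pid, date + pd.Timedelta(days=1)))
        last_valid = (
            1140 <= r["last_watch_time"] < 1440
            and nxt is not None
            and nxt["first_watch_time"] >= 240
        )
        flags[(pid, date)] = (first_valid, last_valid)
        if last_valid and nxt is not None and 240 <= nxt["first_watch_time"] <= 720:
            nonwatch[(pid, date)] = 1440 - r["last_watch_time"] + nxt["first_watch_time"]
    return flags, nonwatch
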