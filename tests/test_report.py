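"""Descriptive tables, trajectories, retention, window diagnostics."""

import numpy as np
import pandas as pd
import pytest

from watchroutine.derive import flag_window_validity
from watchroutine.qc import classify_baselines
from watchroutine.report import (
    attach_mean_abs_devs,
    descriptive_table,
    median_trajectories,
    retention_summary,
    watch_time_distribution,
)
from watchroutine.simulate import SimulationConfig, simulate_cohort


def _flagged_days(rows):
    return flag_window_validity(pd.DataFrame(rows))


def _day(pid, date, steps=8000, first=420, last=1320, wear=800):
    return {
        "participant_id": pid,
        "date": pd.Timestamp(date),
        "first_watch_time": first,
        "last_watch_time": last,
        "wear_minutes": wear,
        "step_total": steps,
    }


def _baselines(pids, statuses):
    return pd.DataFrame(
        {
            "participant_id": pids,
            "glycemic_status": statuses,
            "age": 50.0,
            "sex": "female",
            "race_ethnicity": "white",
            "bmi": 27.0,
            "current_smoker": False,
            "current_drinker": True,
        }
    )


class TestRetention:
    def test_hand_built_spans(self):
        rows = []
        for pid, span in (("a", 25), ("b", 45), ("c", 95), ("d", 200)):
            rows.append(_day(pid, "2020-01-01"))
            rows.append(_day(pid, pd.Timestamp("2020-01-01") + pd.Timedelta(days=span - 1)))
        days = pd.DataFrame(rows)
        base = _baselines(list("abcd"), ["referent"] * 4)
        ret = retention_summary(days, base)
        ref = ret.loc[ret.group == "referent"].set_index("window_days")
        got = {w: int(ref.loc[w, "n_remaining"]) for w in (30, 60, 90, 180)}
        assert got == {30: 3, 60: 2, 90: 2, 180: 1}

    def test_all_long_followup_is_full_retention(self, small_pipeline):
        cfgless = retention_summary(
            small_pipeline.flagged_days, small_pipeline.baselines
        )
        at30 = cfgless.loc[cfgless.window_days == 30]
        assert (at30["pct_remaining"] == 100.0).all()

    def test_monotone_non_increasing(self, small_pipeline):
        ret = retention_summary(small_pipeline.flagged_days, small_pipeline.baselines)
        for _, grp in ret.groupby("group"):
            vals = grp.sort_values("window_days")["n_remaining"].to_numpy()
            assert (np.diff(vals) <= 0).all()


class TestTrajectories:
    def test_median_of_two_constant_participants(self):
        rows = [
            _day(pid, f"2020-01-{d:02d}", steps=steps)
            for pid, steps in (("a", 400), ("b", 500))
            for d in range(1, 11)
        ]
        days = _flagged_days(rows)
        base = _baselines(["a", "b"], ["referent", "referent"])
        panel = median_trajectories(days, base, "steps", window_days=10, balance=False)
        assert (panel.medians["referent"] == 450).all()

    def test_balanced_sampling_sizes_and_reproducibility(self, small_pipeline):
        kwargs = dict(
            flagged_days=small_pipeline.flagged_days,
            baselines=small_pipeline.baselines,
            variable="steps",
            window_days=60,
            balance=True,
            seed=5,
        )
        a = median_trajectories(**kwargs)
        b = median_trajectories(**kwargs)
        assert a.sampled_ids == b.sampled_ids
        sizes = {g: len(v) for g, v in a.sampled_ids.items()}
        assert len(set(sizes.values())) == 1  # balanced to smallest group
        c = median_trajectories(**{**kwargs, "seed": 6})
        assert c.sampled_ids != a.sampled_ids

    def test_window_truncated_to_max_followup(self, small_pipeline):
        panel = median_trajectories(
            small_pipeline.flagged_days, small_pipeline.baselines, "steps",
            window_days=10_000,
        )
        assert panel.window_days <= 100

    def test_diabetes_median_steps_below_referent(self, small_pipeline):
        panel = median_trajectories(
            small_pipeline.flagged_days, small_pipeline.baselines, "steps",
            window_days=60, balance=True, seed=1,
        )
        diff = panel.medians["referent"] - panel.medians["diabetes"]
        assert (diff.dropna() > 0).mean() > 0.5


class TestWatchTimeDistribution:
    def test_clean_simulation_is_all_in_window(self):
        cfg = SimulationConfig(
            n_participants=30, seed=3, out_of_window_prob_wake=0.0,
            out_of_window_prob_bed=0.0, followup_median_days=40,
            followup_min_days=30, followup_cap_days=60,
        )
        dist = watch_time_distribution(simulate_cohort(cfg).person_days)
        assert dist["prop_first_after_4am"] == 1.0
        assert dist["prop_last_after_7pm"] == 1.0

    def test_displacement_rate_shows_up_in_proportion(self):
        cfg = SimulationConfig(
            n_participants=300, seed=4, out_of_window_prob_wake=0.14,
            out_of_window_prob_bed=0.0, followup_median_days=60,
            followup_min_days=40, followup_cap_days=80,
        )
        days = simulate_cohort(cfg).person_days
        dist = watch_time_distribution(days)
        n = dist["n_days"]
        se = np.sqrt(0.14 * 0.86 / n)
        assert dist["prop_first_after_4am"] == pytest.approx(0.86, abs=4 * se + 0.005)
        assert dist["prop_last_after_7pm"] == 1.0

    def test_empty_input_reports_absent(self):
        dist = watch_time_distribution(pd.DataFrame(columns=["first_watch_time"]))
        assert np.isnan(dist["prop_first_after_4am"])
        assert dist["n_days"] == 0


class TestDescriptiveTable:
    def test_counts_match_group_sizes_and_step_ordering(self, small_pipeline):
        summaries = attach_mean_abs_devs(
            small_pipeline.summaries, small_pipeline.deviations
        )
        table = descriptive_table(small_pipeline.baselines, summaries)
        n = table.loc["n"]
        counts = small_pipeline.baselines["glycemic_status"].value_counts()
        assert n["referent"] == counts["referent"]
        assert n["diabetes"] == counts["diabetes"]
        steps = {
            g: float(table.loc["Daily steps, mean (SD)", g].split(" ")[0])
            for g in ("referent", "diabetes")
        }
        assert steps["diabetes"] < steps["referent"]
        assert 0 <= table.attrs["kruskal_wear_p"] <= 1

    def test_hand_computed_means(self):
        base = classify_baselines(
            pd.DataFrame(
                {
                    "participant_id": ["a", "b"],
                    "age": [40.0, 50.0],
                    "sex": ["female", "male"],
                    "race_ethnicity": ["white", "white"],
                    "bmi": [25.0, 35.0],
                    "current_smoker": [False, True],
                    "current_drinker": [True, True],
                    "education": ["bachelors", "bachelors"],
                    "fasting_glucose_mgdl": [90.0, 95.0],
                    "glucose_med": [False, False],
                    "cvd_prevalent": [False, False],
                }
            )
        )
        summaries = pd.DataFrame(
            {
                "participant_id": ["a", "b"],
                "mean_daily_steps": [6000.0, 10000.0],
                "mean_wear_hours": [13.0, 15.0],
            }
        )
        table = descriptive_table(base, summaries)
        assert table.loc["Age (years), mean (SD)", "referent"] == "45.0 (7.1)"
        assert table.loc["Daily steps, mean (SD)", "referent"] == "8000.0 (2828.4)"
        assert table.loc["Women, n (%)", "referent"] == "1 (50.0%)"
        assert table.loc["n", "prediabetes"] == 0

    def test_single_group_cohort(self):
        base = _baselines(["a", "b"], ["referent", "referent"])
        summaries = pd.DataFrame(
            {
                "participant_id": ["a", "b"],
                "mean_daily_steps": [6000.0, 10000.0],
                "mean_wear_hours": [13.0, 15.0],
            }
        )
        table = descriptive_table(base, summaries)
        assert table.loc["n", "referent"] == 2
        assert table.loc["n", "diabetes"] == 0
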