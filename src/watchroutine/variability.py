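"""Intraindividual variability outcomes.

Each participant's long-run mean of a watch-time variable is taken over all
their valid follow-up days; the repeated daily outcome is the absolute
deviation of that day's value from the participant's own mean.  These
absolute deviations quantify routine irregularity and are the outcomes of
the association models (units: minutes).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

VARIABLES = ("first", "last", "nonwatch")


def participant_summaries(
    flagged_days: pd.DataFrame, intervals: pd.DataFrame
) -> pd.DataFrame:
    """Per-participant full-follow-up means of the routine variables.

    Means are computed only over valid-flag days (first/last watch time) or
    available nights (non-watch); a variable with zero valid days yields a
    missing mean, and that participant contributes no deviations for it.
    Also reports mean daily steps and mean daily wear hours over all days
    with records.
    """
    days = flagged_days.copy()
    by = days.groupby("participant_id")

    first = days.loc[days["first_valid"]].groupby("participant_id")["first_watch_time"]
    last = days.loc[days["last_valid"]].groupby("participant_id")["last_watch_time"]
    nw = intervals.groupby("participant_id")["non_watch_minutes"]

    out = pd.DataFrame(index=by.size().index)
    out["mean_first"] = first.mean()
    out["n_first_days"] = first.size().reindex(out.index, fill_value=0).astype(int)
    out["mean_last"] = last.mean()
    out["n_last_days"] = last.size().reindex(out.index, fill_value=0).astype(int)
    out["mean_nonwatch"] = nw.mean()
    out["n_nonwatch_days"] = nw.size().reindex(out.index, fill_value=0).astype(int)
    out["mean_daily_steps"] = by["step_total"].mean()
    out["mean_wear_hours"] = by["wear_minutes"].mean() / 60.0
    return out.reset_index().rename(columns={"index": "participant_id"})


def deviation_observations(
    flagged_days: pd.DataFrame,
    intervals: pd.DataFrame,
    summaries: pd.DataFrame,
) -> pd.DataFrame:
    """Daily absolute deviations from each participant's own mean.

    Long format: ``participant_id, date, variable, value, abs_deviation``
    with one row per valid day per variable in {first, last, nonwatch}.
    Signed deviations are not retained.  Raises ``ValueError`` when the
    summaries do not cover a participant present in the data.
    """
    summ = summaries.set_index("participant_id")

    def _check(ids):
        missing = set(ids.unique()) - set(summ.index)
        if missing:
            raise ValueError(f"summaries missing participants: {sorted(missing)[:10]}")

    parts = []
    days = flagged_days
    for variable, frame, col, mean_col in (
        ("first", days.loc[days["first_valid"]], "first_watch_time", "mean_first"),
        ("last", days.loc[days["last_valid"]], "last_watch_time", "mean_last"),
        ("nonwatch", intervals, "non_watch_minutes", "mean_nonwatch"),
    ):
        if frame.empty:
            continue
        _check(frame["participant_id"])
        mu = frame["participant_id"].map(summ[mean_col])
        parts.append(
            pd.DataFrame(
                {
                    "participant_id": frame["participant_id"],
                    "date": pd.to_datetime(frame["date"]),
                    "variable": variable,
                    "value": frame[col].astype(float),
                    "abs_deviation": (frame[col] - mu).abs(),
                }
            )
        )
    if not parts:
        return pd.DataFrame(
            columns=["participant_id", "date", "variable", "value", "abs_deviation"]
        )
    out = pd.concat(parts, ignore_index=True)
    return out.sort_values(["participant_id", "variable", "date"], kind="mergesort").reset_index(
        drop=True
    )
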