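"""Descriptive tables, retention summaries, and median-trajectory panels.

Trajectory panels follow the group-balancing convention: because the
diabetes group is much smaller than the others, the referent and prediabetes
groups are first down-sampled (seeded) to the diabetes group's size before
per-day medians are taken, so the comparison is not distorted by unequal
sampling noise.  The x-axis is days since each participant's first data day
(enrollment is staggered, so calendar alignment is not meaningful).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .qc import GLYCEMIC_LEVELS

logger = logging.getLogger(__name__)


def _fmt_mean_sd(x):
    x = pd.Series(x).dropna()
    if x.empty:
        return ""
    return f"{x.mean():.1f} ({x.std(ddof=1):.1f})" if len(x) > 1 else f"{x.mean():.1f}"


def _fmt_n_pct(flags):
    flags = pd.Series(flags).dropna().astype(bool)
    if flags.empty:
        return ""
    return f"{int(flags.sum())} ({100 * flags.mean():.1f}%)"


def descriptive_table(baselines: pd.DataFrame, summaries: pd.DataFrame) -> pd.DataFrame:
    """Baseline-characteristics table by glycemic group.

    Continuous fields as mean (SD), categorical as n (%), plus mean daily
    steps and the mean variation (mean absolute deviation, minutes) of the
    three watch-time variables and median daily wear hours.  A
    Kruskal-Wallis comparison of daily wear hours across groups is attached
    as ``table.attrs['kruskal_wear_p']``.  Empty groups get a column with
    n=0 and blank statistics.
    """
    base = baselines.merge(summaries, on="participant_id", how="left")
    if "glycemic_status" not in base.columns:
        raise ValueError("baselines must carry glycemic_status (run qc.classify_baselines)")

    dev_means = _per_participant_mads(base)

    cols = {}
    wear_by_group = []
    for g in GLYCEMIC_LEVELS:
        sub = base.loc[base["glycemic_status"] == g]
        col = {"n": len(sub)}
        if len(sub):
            col["Age (years), mean (SD)"] = _fmt_mean_sd(sub["age"])
            col["Women, n (%)"] = _fmt_n_pct(sub["sex"] == "female")
            col["Alcohol drinking (yes), n (%)"] = _fmt_n_pct(sub["current_drinker"])
            col["Smoking (yes), n (%)"] = _fmt_n_pct(sub["current_smoker"])
            col["BMI (kg/m2), mean (SD)"] = _fmt_mean_sd(sub["bmi"])
            col["Daily steps, mean (SD)"] = _fmt_mean_sd(sub["mean_daily_steps"])
            for var, label in (
                ("first", "Variation of first watch time (min), mean (SD)"),
                ("last", "Variation of last watch time (min), mean (SD)"),
                ("nonwatch", "Variation of non-watch time (min), mean (SD)"),
            ):
                col[label] = _fmt_mean_sd(dev_means.get((g, var), pd.Series(dtype=float)))
            wear = sub["mean_wear_hours"].dropna()
            col["Daily wear (hours), median"] = f"{wear.median():.1f}" if len(wear) else ""
            wear_by_group.append(wear.to_numpy())
        cols[g] = col

    table = pd.DataFrame(cols)
    groups_with_data = [w for w in wear_by_group if len(w)]
    if len(groups_with_data) >= 2:
        table.attrs["kruskal_wear_p"] = float(stats.kruskal(*groups_with_data).pvalue)
    else:
        table.attrs["kruskal_wear_p"] = np.nan
    return table


def _per_participant_mads(base):
    """{(group, variable): per-participant mean abs deviation series}."""
    out = {}
    if "mean_abs_dev_first" in base.columns:
        for g in GLYCEMIC_LEVELS:
            sub = base.loc[base["glycemic_status"] == g]
            for var in ("first", "last", "nonwatch"):
                out[(g, var)] = sub[f"mean_abs_dev_{var}"]
    return out


def attach_mean_abs_devs(summaries: pd.DataFrame, deviations: pd.DataFrame) -> pd.DataFrame:
    """Add per-participant mean absolute deviation columns to the summaries."""
    out = summaries.copy()
    if deviations.empty:
        for var in ("first", "last", "nonwatch"):
            out[f"mean_abs_dev_{var}"] = np.nan
        return out
    mad = (
        deviations.groupby(["participant_id", "variable"])["abs_deviation"]
        .mean()
        .unstack("variable")
    )
    for var in ("first", "last", "nonwatch"):
        col = mad[var] if var in mad.columns else pd.Series(dtype=float)
        out[f"mean_abs_dev_{var}"] = out["participant_id"].map(col)
    return out


@dataclass
class TrajectoryPanel:
    """Per-day group medians of one routine variable over a follow-up window."""

    variable: str
    window_days: int
    medians: pd.DataFrame  # index: follow-up day 1..window; columns: groups
    sampled_ids: dict = field(default_factory=dict)


def median_trajectories(
    flagged_days: pd.DataFrame,
    baselines: pd.DataFrame,
    variable: str = "steps",
    window_days: int = 90,
    balance: bool = True,
    seed: int = 0,
) -> TrajectoryPanel:
    """Across-participant daily medians per glycemic group.

    ``variable`` is one of ``steps`` (all days), ``first`` or ``last``
    (valid-flag days only).  Follow-up day 1 is each participant's first data
    day.  With ``balance`` on, the larger groups are down-sampled (seeded) to
    the smallest group's size.  Medians are taken over the participants
    contributing data on that day; no imputation.
    """
    value_col, mask_col = {
        "steps": ("step_total", None),
        "first": ("first_watch_time", "first_valid"),
        "last": ("last_watch_time", "last_valid"),
    }[variable]

    days = flagged_days.copy()
    days["date"] = pd.to_datetime(days["date"])
    origin = days.groupby("participant_id")["date"].transform("min")
    days["followup_day"] = (days["date"] - origin).dt.days + 1

    max_day = int(days["followup_day"].max()) if len(days) else 0
    if window_days > max_day:
        logger.warning(
            "window of %d days exceeds max follow-up %d; truncating", window_days, max_day
        )
        window_days = max_day

    status = baselines.set_index("participant_id")["glycemic_status"]
    days["group"] = days["participant_id"].map(status)
    days = days.loc[days["group"].isin(GLYCEMIC_LEVELS)]
    if mask_col is not None:
        days = days.loc[days[mask_col]]
    days = days.loc[days["followup_day"] <= window_days]

    ids_by_group = {
        g: np.sort(days.loc[days["group"] == g, "participant_id"].unique())
        for g in GLYCEMIC_LEVELS
    }
    sampled = dict(ids_by_group)
    if balance:
        sizes = {g: len(v) for g, v in ids_by_group.items() if len(v)}
        if sizes:
            target = min(sizes.values())
            rng = np.random.default_rng(seed)
            sampled = {
                g: (
                    np.sort(rng.choice(ids, size=target, replace=False))
                    if len(ids) > target
                    else ids
                )
                for g, ids in ids_by_group.items()
            }
    keep = set().union(*(set(v) for v in sampled.values())) if sampled else set()
    days = days.loc[days["participant_id"].isin(keep)]

    med = (
        days.groupby(["followup_day", "group"])[value_col]
        .median()
        .unstack("group")
        .reindex(range(1, window_days + 1))
        .reindex(columns=list(GLYCEMIC_LEVELS))
    )
    return TrajectoryPanel(
        variable=variable,
        window_days=window_days,
        medians=med,
        sampled_ids={g: list(v) for g, v in sampled.items()},
    )


def retention_summary(
    person_days: pd.DataFrame,
    baselines: pd.DataFrame,
    windows=(30, 60, 90, 180),
) -> pd.DataFrame:
    """Fraction of each group whose follow-up span reaches each window.

    Follow-up span is first-to-last data day, inclusive.  Retention is
    non-increasing across widening windows by construction.
    """
    days = person_days.copy()
    days["date"] = pd.to_datetime(days["date"])
    span = days.groupby("participant_id")["date"].agg(["min", "max"])
    span_days = ((span["max"] - span["min"]).dt.days + 1).rename("span")

    status = baselines.set_index("participant_id")["glycemic_status"]
    tab = pd.DataFrame({"span": span_days})
    tab["group"] = tab.index.map(status)
    tab = tab.loc[tab["group"].isin(GLYCEMIC_LEVELS)]

    rows = []
    for g in GLYCEMIC_LEVELS:
        sub = tab.loc[tab["group"] == g, "span"]
        n = len(sub)
        for w in windows:
            remaining = int((sub >= w).sum())
            rows.append(
                {
                    "group": g,
                    "window_days": w,
                    "n_group": n,
                    "n_remaining": remaining,
                    "pct_remaining": 100.0 * remaining / n if n else np.nan,
                }
            )
    return pd.DataFrame(rows)


def watch_time_distribution(person_days: pd.DataFrame) -> dict:
    """Proportions of first watch times after 4 AM and last after 7 PM.

    Computed on all person-days before window exclusion; supports the choice
    of the 4 AM / 7 PM analysis windows.  Empty input yields missing
    proportions.
    """
    if person_days.empty:
        return {"prop_first_after_4am": np.nan, "prop_last_after_7pm": np.nan, "n_days": 0}
    return {
        "prop_first_after_4am": float((person_days["first_watch_time"] >= 240).mean()),
        "prop_last_after_7pm": float((person_days["last_watch_time"] >= 1140).mean()),
        "n_days": int(len(person_days)),
    }


def plot_trajectories(panel: TrajectoryPanel, path) -> None:
    """Render a trajectory panel to a figure file (thin layer over the data)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    for g in panel.medians.columns:
        ax.plot(panel.medians.index, panel.medians[g], label=g)
    ylabel = {
        "steps": "median daily steps",
        "first": "median first watch time (min since midnight)",
        "last": "median last watch time (min since midnight)",
    }[panel.variable]
    ax.set_xlabel("follow-up day")
    ax.set_ylabel(ylabel)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
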