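"""Participant-level quality control and glycemic classification.

Reproduces the study-sample construction: participants with prevalent
cardiovascular disease, insufficient daily wear, or too little follow-up are
excluded, and the remainder are classified as referent / prediabetes /
diabetes from fasting glucose and medication use.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

GLYCEMIC_LEVELS = ("referent", "prediabetes", "diabetes")

#: exclusion reason codes, in the fixed order they are applied
REASON_CVD = "cvd"
REASON_STATUS = "status_missing"
REASON_WEAR = "wear"
REASON_DURATION = "duration"


class ValidationError(ValueError):
    pass


class QCError(ValueError):
    pass


def classify_diabetes(fasting_glucose_mgdl, glucose_med):
    """Three-level glycemic status from fasting glucose and medication use.

    Diabetes: fasting glucose >= 126 mg/dL or any glucose-lowering
    medication; prediabetes: 100-125 mg/dL without medication; referent:
    < 100 mg/dL without medication.  Missing glucose without medication
    yields missing status (the participant is dropped downstream).

    Accepts scalars or array-likes; negative glucose raises
    :class:`ValidationError`.
    """
    glucose = np.asarray(fasting_glucose_mgdl, dtype=float)
    med = np.asarray(glucose_med, dtype=bool)
    scalar = glucose.ndim == 0
    glucose = np.atleast_1d(glucose)
    med = np.atleast_1d(med)
    if (glucose < 0).any():
        raise ValidationError("fasting glucose must be nonnegative")

    status = np.full(glucose.shape, None, dtype=object)
    status[med | (glucose >= 126)] = "diabetes"
    pre = ~med & (glucose >= 100) & (glucose < 126)
    status[pre] = "prediabetes"
    ref = ~med & (glucose < 100)
    status[ref] = "referent"
    # missing glucose without medication stays None
    status[np.isnan(glucose) & ~med] = None
    return status[0] if scalar else status


def classify_baselines(baselines: pd.DataFrame) -> pd.DataFrame:
    """Return the baseline table with a ``glycemic_status`` column attached."""
    out = baselines.copy()
    out["glycemic_status"] = classify_diabetes(
        out["fasting_glucose_mgdl"].to_numpy(), out["glucose_med"].to_numpy()
    )
    return out


@dataclass
class QCReport:
    """Accounting of the participant-level exclusions.

    The identity ``n_input == n_retained + sum(exclusions)`` holds on every
    run; each participant is counted once, under the first triggered rule in
    the fixed order CVD → missing status → wear → duration.
    """

    n_input: int = 0
    n_excluded_cvd: int = 0
    n_excluded_status: int = 0
    n_excluded_wear: int = 0
    n_excluded_duration: int = 0
    n_retained: int = 0
    reasons: dict = field(default_factory=dict)

    @property
    def n_excluded(self) -> int:
        return (
            self.n_excluded_cvd
            + self.n_excluded_status
            + self.n_excluded_wear
            + self.n_excluded_duration
        )

    def check_identity(self) -> bool:
        return self.n_input == self.n_retained + self.n_excluded

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_excluded_cvd": self.n_excluded_cvd,
            "n_excluded_status": self.n_excluded_status,
            "n_excluded_wear": self.n_excluded_wear,
            "n_excluded_duration": self.n_excluded_duration,
            "n_retained": self.n_retained,
        }


def apply_exclusions(
    person_days: pd.DataFrame,
    baselines: pd.DataFrame,
    min_wear_hours: float = 10.0,
    min_days: int = 30,
    span_as_data_days: bool = False,
) -> tuple[list, QCReport]:
    """Participant-level exclusions; returns (retained ids, QCReport).

    Exclusion rules, applied in fixed order so reason codes are
    deterministic:

    1. prevalent cardiovascular disease at baseline;
    2. glycemic status not classifiable (missing glucose, no medication);
    3. mean daily wear (total wear minutes / number of dates with records)
       below ``min_wear_hours``;
    4. follow-up below ``min_days`` — by default the first-to-last data-day
       span (``span_as_data_days=True`` counts data days instead).

    Participants present in ``person_days`` but absent from ``baselines``
    are a hard error.
    """
    if min_wear_hours <= 0 or min_days <= 0:
        raise ValidationError("QC thresholds must be positive")

    pd_ids = set(person_days["participant_id"].unique())
    base_ids = set(baselines["participant_id"])
    orphans = sorted(pd_ids - base_ids)
    if orphans:
        raise QCError(f"participants with records but no baseline row: {orphans[:20]}")

    base = baselines
    if "glycemic_status" not in base.columns:
        base = classify_baselines(base)
    base = base.set_index("participant_id")

    days = person_days.copy()
    days["date"] = pd.to_datetime(days["date"])
    per = days.groupby("participant_id").agg(
        n_dates=("date", "nunique"),
        total_wear=("wear_minutes", "sum"),
        first_date=("date", "min"),
        last_date=("date", "max"),
    )
    per["mean_wear_hours"] = per["total_wear"] / per["n_dates"] / 60.0
    per["span_days"] = (per["last_date"] - per["first_date"]).dt.days + 1

    report = QCReport(n_input=len(base))
    retained = []
    for pid, row in base.iterrows():
        if bool(row["cvd_prevalent"]):
            report.n_excluded_cvd += 1
            report.reasons[pid] = REASON_CVD
            continue
        if row["glycemic_status"] is None or (
            isinstance(row["glycemic_status"], float) and np.isnan(row["glycemic_status"])
        ):
            report.n_excluded_status += 1
            report.reasons[pid] = REASON_STATUS
            continue
        if pid in per.index:
            mean_wear = per.at[pid, "mean_wear_hours"]
            followup = (
                per.at[pid, "n_dates"] if span_as_data_days else per.at[pid, "span_days"]
            )
        else:
            mean_wear, followup = 0.0, 0
        if mean_wear < min_wear_hours:
            report.n_excluded_wear += 1
            report.reasons[pid] = REASON_WEAR
            continue
        if followup < min_days:
            report.n_excluded_duration += 1
            report.reasons[pid] = REASON_DURATION
            continue
        retained.append(pid)

    report.n_retained = len(retained)
    assert report.check_identity()
    logger.info(
        "QC: %d in, %d retained (excluded: cvd=%d status=%d wear=%d duration=%d)",
        report.n_input,
        report.n_retained,
        report.n_excluded_cvd,
        report.n_excluded_status,
        report.n_excluded_wear,
        report.n_excluded_duration,
    )
    return retained, report
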