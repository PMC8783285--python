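"""End-to-end orchestration of the analysis stages.

``run_pipeline`` chains window flagging, QC, summarisation and deviation
computation on a person-day table; ``model1_contrasts`` additionally fits the
primary covariate set and returns the two group contrasts per outcome, which
is the unit of work for parameter-recovery studies.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .derive import flag_window_validity, sleep_intervals
from .models import OUTCOMES, ModelSpec, build_model_frame, fit_mixed_model
from .qc import QCReport, apply_exclusions, classify_baselines
from .variability import deviation_observations, participant_summaries


@dataclass
class PipelineResult:
    flagged_days: pd.DataFrame
    intervals: pd.DataFrame
    baselines: pd.DataFrame  # with glycemic_status
    retained_ids: list
    qc_report: QCReport
    summaries: pd.DataFrame
    deviations: pd.DataFrame


def run_pipeline(
    person_days: pd.DataFrame,
    baselines: pd.DataFrame,
    min_wear_hours: float = 10.0,
    min_days: int = 30,
) -> PipelineResult:
    """Flag windows, apply QC, and compute the repeated deviation outcomes."""
    base = classify_baselines(baselines)
    flagged = flag_window_validity(person_days)
    retained, qc_report = apply_exclusions(
        person_days, base, min_wear_hours=min_wear_hours, min_days=min_days
    )
    kept = flagged.loc[flagged["participant_id"].isin(set(retained))].reset_index(drop=True)
    intervals = sleep_intervals(kept)
    summaries = participant_summaries(kept, intervals)
    deviations = deviation_observations(kept, intervals, summaries)
    return PipelineResult(
        flagged_days=kept,
        intervals=intervals,
        baselines=base,
        retained_ids=retained,
        qc_report=qc_report,
        summaries=summaries,
        deviations=deviations,
    )


def model1_contrasts(result: PipelineResult, outcomes=OUTCOMES) -> dict:
    """Primary-model contrasts per outcome.

    Returns ``{outcome: {"prediabetes": Contrast, "diabetes": Contrast}}``
    for the requested outcomes under the model-1 covariate set.
    """
    out = {}
    for outcome in outcomes:
        frame = build_model_frame(
            outcome,
            result.flagged_days,
            result.deviations,
            result.baselines,
            result.retained_ids,
        )
        fit = fit_mixed_model(frame, ModelSpec(outcome=outcome, covariate_set="model1"))
        out[outcome] = {
            "prediabetes": fit.contrast_prediabetes,
            "diabetes": fit.contrast_diabetes,
        }
    return out
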