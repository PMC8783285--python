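"""Linear mixed models relating daily routine outcomes to glycemic status.

Outcomes are repeated daily measurements (step totals or absolute deviations
of a watch-time variable from the participant's own mean); the exposure is
3-level glycemic status with the referent group as reference.  Models use a
random intercept per participant, REML estimation, and Wald 95% intervals on
the identity scale — estimates are untransformed mean differences (steps/day
or minutes).

Covariate sets:

* ``model1`` — sex, age, race/ethnicity;
* ``model2`` — model 1 + BMI;
* ``model3`` — model 2 + current smoking + current alcohol use;
* ``model1_plus_followup`` — model 1 + follow-up days (sensitivity);
* ``model1_plus_followup_wear`` — model 1 + follow-up days + daily wear.

Daily wear minutes are always included as a time-varying covariate when the
outcome is steps, since wear time mechanically drives the daily step total.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.regression.mixed_linear_model import MixedLMParams

logger = logging.getLogger(__name__)

OUTCOMES = ("steps", "dev_first", "dev_last", "dev_nonwatch")

COVARIATE_SETS = {
    "model1": ("age", "sex", "race_ethnicity"),
    "model2": ("age", "sex", "race_ethnicity", "bmi"),
    "model3": ("age", "sex", "race_ethnicity", "bmi", "current_smoker", "current_drinker"),
    "model1_plus_followup": ("age", "sex", "race_ethnicity", "followup_days"),
    "model1_plus_followup_wear": (
        "age",
        "sex",
        "race_ethnicity",
        "followup_days",
        "wear_minutes",
    ),
}

_CATEGORICAL = {"sex", "race_ethnicity"}
_BINARY = {"current_smoker", "current_drinker"}


class DegenerateDataError(ValueError):
    """Too little data to identify the group contrasts."""


class ConvergenceError(RuntimeError):
    pass


@dataclass(frozen=True)
class ModelSpec:
    outcome: str
    covariate_set: str = "model1"

    def __post_init__(self):
        if self.outcome not in OUTCOMES:
            raise ValueError(f"unknown outcome {self.outcome!r}")
        if self.covariate_set not in COVARIATE_SETS:
            raise ValueError(f"unknown covariate set {self.covariate_set!r}")

    @property
    def include_wear_covariate(self) -> bool:
        # wear time mechanically bounds the daily step total
        return self.outcome == "steps" or "wear_minutes" in COVARIATE_SETS[self.covariate_set]


@dataclass
class Contrast:
    estimate: float
    ci_low: float
    ci_high: float
    p_value: float


@dataclass
class ModelFit:
    spec: ModelSpec
    contrast_prediabetes: Contrast
    contrast_diabetes: Contrast
    n_participants: int
    n_observations: int
    converged: bool


def build_model_frame(
    outcome: str,
    flagged_days: pd.DataFrame,
    deviations: pd.DataFrame,
    baselines: pd.DataFrame,
    retained_ids=None,
) -> pd.DataFrame:
    """Long-format modeling table: one row per analysable day.

    Joins the repeated outcome with baseline covariates, attaches daily wear
    minutes and the participant's follow-up span, and restricts to retained
    participants when ``retained_ids`` is given.
    """
    if outcome == "steps":
        obs = flagged_days.loc[:, ["participant_id", "date", "step_total", "wear_minutes"]]
        obs = obs.rename(columns={"step_total": "value"})
    else:
        variable = outcome.removeprefix("dev_")
        dev = deviations.loc[deviations["variable"] == variable]
        obs = dev.loc[:, ["participant_id", "date", "abs_deviation"]].rename(
            columns={"abs_deviation": "value"}
        )
        obs = obs.assign(date=pd.to_datetime(obs["date"]))
        wear = flagged_days.loc[:, ["participant_id", "date", "wear_minutes"]]
        wear = wear.assign(date=pd.to_datetime(wear["date"]))
        obs = obs.merge(wear, on=["participant_id", "date"], how="left")

    if retained_ids is not None:
        obs = obs.loc[obs["participant_id"].isin(set(retained_ids))]

    days = flagged_days.copy()
    days["date"] = pd.to_datetime(days["date"])
    span = days.groupby("participant_id")["date"].agg(["min", "max"])
    followup = ((span["max"] - span["min"]).dt.days + 1).rename("followup_days")

    base_cols = [
        "participant_id",
        "age",
        "sex",
        "race_ethnicity",
        "bmi",
        "current_smoker",
        "current_drinker",
        "glycemic_status",
    ]
    frame = obs.merge(baselines.loc[:, base_cols], on="participant_id", how="left")
    frame = frame.merge(followup, left_on="participant_id", right_index=True, how="left")
    return frame


def _formula(spec: ModelSpec, frame: pd.DataFrame) -> str:
    terms = ["C(glycemic_status, Treatment('referent'))"]
    for cov in COVARIATE_SETS[spec.covariate_set]:
        if cov == "wear_minutes":
            continue  # handled below so steps models do not double it
        if cov in _CATEGORICAL:
            if cov == "race_ethnicity":
                ref = frame[cov].value_counts().idxmax()
                terms.append(f"C({cov}, Treatment({ref!r}))")
            else:
                terms.append(f"C({cov})")
        elif cov in _BINARY:
            terms.append(f"C({cov})")
        else:
            terms.append(cov)
    if spec.include_wear_covariate:
        terms.append("wear_minutes")
    return "value ~ " + " + ".join(terms)


def _moment_start(model, group_ids) -> MixedLMParams | None:
    """Method-of-moments starting values for the random-intercept fit.

    OLS fixed effects, then a one-way ANOVA decomposition of the residuals
    into within- and between-participant variance; starting the optimizer at
    the implied variance ratio avoids the zero-variance boundary region where
    quasi-Newton steps stall.  Returns None when the decomposition is not
    informative (e.g. one observation per participant).
    """
    try:
        ols = sm.OLS(model.endog, model.exog).fit()
        resid = pd.Series(ols.resid)
        stats = resid.groupby(group_ids.reset_index(drop=True)).agg(["mean", "var", "count"])
        multi = stats["count"] > 1
        if not multi.any():
            return None
        vw = float(
            np.average(stats.loc[multi, "var"], weights=stats.loc[multi, "count"] - 1)
        )
        harmonic_n = 1.0 / np.mean(1.0 / stats["count"])
        vb = max(float(stats["mean"].var(ddof=1)) - vw / harmonic_n, 1e-6 * vw)
        if not (np.isfinite(vw) and vw > 0 and np.isfinite(vb)):
            return None
        return MixedLMParams.from_components(
            fe_params=np.asarray(ols.params), cov_re=np.array([[vb / vw]])
        )
    except Exception:  # starting values are an optimisation, never fatal
        return None


def fit_mixed_model(
    frame: pd.DataFrame, spec: ModelSpec, strict: bool = False
) -> ModelFit:
    """Random-intercept linear mixed model; returns the two group contrasts.

    Complete-case on the covariates in the spec (missing rows logged);
    requires at least 2 participants per glycemic group.  Non-convergence is
    flagged (and raised in ``strict`` mode).
    """
    needed = ["value", "glycemic_status", "participant_id"] + [
        c for c in COVARIATE_SETS[spec.covariate_set]
        if c != "followup_days" or "followup_days" in frame.columns
    ]
    if spec.include_wear_covariate and "wear_minutes" not in needed:
        needed.append("wear_minutes")
    if "followup_days" in COVARIATE_SETS[spec.covariate_set]:
        needed.append("followup_days")
    needed = list(dict.fromkeys(needed))
    df = frame.loc[:, needed].dropna()
    dropped = len(frame) - len(df)
    if dropped:
        logger.info("complete-case deletion dropped %d observations", dropped)

    counts = df.groupby("glycemic_status")["participant_id"].nunique()
    lacking = [g for g in ("referent", "prediabetes", "diabetes") if counts.get(g, 0) < 2]
    if lacking:
        raise DegenerateDataError(
            f"fewer than 2 participants in group(s): {lacking} "
            f"(counts: {counts.to_dict()})"
        )

    model = smf.mixedlm(_formula(spec, df), df, groups=df["participant_id"])
    start = _moment_start(model, df["participant_id"])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if start is not None:
            result = model.fit(reml=True, start_params=start)
        else:
            result = model.fit(reml=True)
    converged = bool(getattr(result, "converged", True))
    if not converged and strict:
        raise ConvergenceError(f"mixed model failed to converge for {spec}")

    ci = result.conf_int(alpha=0.05)
    contrasts = {}
    for group in ("prediabetes", "diabetes"):
        name = f"C(glycemic_status, Treatment('referent'))[T.{group}]"
        contrasts[group] = Contrast(
            estimate=float(result.params[name]),
            ci_low=float(ci.loc[name, 0]),
            ci_high=float(ci.loc[name, 1]),
            p_value=float(result.pvalues[name]),
        )

    return ModelFit(
        spec=spec,
        contrast_prediabetes=contrasts["prediabetes"],
        contrast_diabetes=contrasts["diabetes"],
        n_participants=int(df["participant_id"].nunique()),
        n_observations=len(df),
        converged=converged,
    )


def run_analysis_suite(
    flagged_days: pd.DataFrame,
    deviations: pd.DataFrame,
    baselines: pd.DataFrame,
    retained_ids=None,
    outcomes=OUTCOMES,
    covariate_sets=("model1", "model2", "model3"),
    strict: bool = False,
) -> pd.DataFrame:
    """Fit every outcome x covariate-set combination.

    Returns a tidy results table (one row per contrast) with columns
    ``outcome, model, group, estimate, ci_low, ci_high, p_value,
    n_participants, n_obs, converged``; degenerate combinations are emitted
    with missing estimates and ``converged=False`` rather than aborting the
    suite.  Ordering is deterministic.
    """
    rows = []
    for outcome in outcomes:
        frame = build_model_frame(outcome, flagged_days, deviations, baselines, retained_ids)
        for cov_set in covariate_sets:
            spec = ModelSpec(outcome=outcome, covariate_set=cov_set)
            try:
                fit = fit_mixed_model(frame, spec, strict=strict)
                for group, contrast in (
                    ("prediabetes", fit.contrast_prediabetes),
                    ("diabetes", fit.contrast_diabetes),
                ):
                    rows.append(
                        {
                            "outcome": outcome,
                            "model": cov_set,
                            "group": group,
                            "estimate": contrast.estimate,
                            "ci_low": contrast.ci_low,
                            "ci_high": contrast.ci_high,
                            "p_value": contrast.p_value,
                            "n_participants": fit.n_participants,
                            "n_obs": fit.n_observations,
                            "converged": fit.converged,
                        }
                    )
            except DegenerateDataError as exc:
                logger.warning("degenerate fit for %s/%s: %s", outcome, cov_set, exc)
                for group in ("prediabetes", "diabetes"):
                    rows.append(
                        {
                            "outcome": outcome,
                            "model": cov_set,
                            "group": group,
                            "estimate": np.nan,
                            "ci_low": np.nan,
                            "ci_high": np.nan,
                            "p_value": np.nan,
                            "n_participants": 0,
                            "n_obs": 0,
                            "converged": False,
                        }
                    )
    return pd.DataFrame(rows)
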