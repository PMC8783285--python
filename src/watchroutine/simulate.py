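"""Synthetic smartwatch cohort generator.

Emulates the behavioural model underlying wrist-worn wake/bed proxies: a
participant puts the watch on shortly after waking and removes it at bedtime
to charge, so the first and last minutes with any heart-rate or step data on
a calendar day proxy wake-up time and bedtime.  Each participant carries
latent wake/bed means (between-person spread) and a glycemic-group-specific
within-person day-to-day spread; daily step totals have a right-skewed
between-person distribution with group effects partially mediated through
BMI.

Two resolutions are supported.  ``minute`` emits one record per worn minute
(the external epoch-record schema); ``day`` emits the per-day sufficient
statistics (first/last worn minute, worn-minute count, daily step total)
directly from the same day-level draws.  The two are exactly equivalent:
minute records are an expansion of the day table and the derivation stage
recovers it bit for bit.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

logger = logging.getLogger(__name__)

GROUPS = ("referent", "prediabetes", "diabetes")

#: truncation of latent daily wake/bed draws (minutes since midnight): the
#: analysis windows themselves, so a day falls outside a window only through
#: the explicit displacement mechanism and effect injection stays
#: interpretable on the analysed days.
WAKE_TRUNCATION = (240.0, 720.0)
BED_TRUNCATION = (1140.0, 1439.0)

# Within-person SDs frozen from the calibration oracle
# (calibration.calibrate_within_sds with het_sigma=0.15): they reproduce
# population mean absolute deviations of 57/60/69 min (first watch time) and
# 46/47/52 min (last watch time) for referent/prediabetes/diabetes under the
# default latent-mean distributions and person-level variability
# heterogeneity, i.e. model-1 contrasts of +3/+12 and +1/+6 minutes.
CALIBRATED_WAKE_SD_WITHIN = (75.3729, 80.0695, 95.2955)
CALIBRATED_BED_SD_WITHIN = (66.0414, 68.0778, 79.4337)


class ConfigurationError(ValueError):
    """A simulation configuration field is invalid."""


def _default_covariate_spec():
    # Group-conditional covariate distributions (referent, prediabetes,
    # diabetes): age/BMI normal (mean, sd); binary fields as probabilities;
    # education as 4-level probabilities (high school or less, some college,
    # bachelor's, graduate); race/ethnicity shared across groups.
    return {
        "age": {"referent": (51.5, 8.7), "prediabetes": (55.3, 8.2), "diabetes": (57.4, 7.8)},
        "female": {"referent": 0.72, "prediabetes": 0.402, "diabetes": 0.415},
        "bmi": {"referent": (26.9, 5.1), "prediabetes": (30.2, 5.0), "diabetes": (33.4, 6.4)},
        "current_smoker": {"referent": 0.035, "prediabetes": 0.067, "diabetes": 0.049},
        "current_drinker": {"referent": 0.83, "prediabetes": 0.837, "diabetes": 0.659},
        "education": {
            "referent": (0.061, 0.212, 0.392, 0.335),
            "prediabetes": (0.10, 0.244, 0.411, 0.245),
            "diabetes": (0.171, 0.317, 0.268, 0.244),
        },
        "race_ethnicity": {
            "levels": ("white", "black", "hispanic", "other"),
            "probs": (0.90, 0.03, 0.04, 0.03),
        },
        # glucose drawn consistently with the group label so classification
        # round-trips: referent <100, prediabetes 100-125, diabetes >=126 or
        # on glucose-lowering medication.
        "glucose_med_prob_diabetes": 0.7,
    }


@dataclass
class SimulationConfig:
    """Generative parameters for a synthetic smartwatch cohort.

    Times are minutes since local midnight, steps are counts/day, follow-up
    in days.  Defaults describe the analysed (post-exclusion) cohort: 796
    participants split 546/209/41 across referent/prediabetes/diabetes,
    median follow-up 219 days with a 30-day floor, 14 h/day typical wear,
    group step effects of -392/-1611 steps/day (totals, partially mediated
    through BMI) and within-person watch-time spreads frozen from the
    calibration oracle.
    """

    n_participants: int = 796
    group_proportions: tuple = (546 / 796, 209 / 796, 41 / 796)
    followup_median_days: float = 219.0
    followup_min_days: int = 30
    followup_cap_days: int | None = 1095
    wake_mean_population: float = 420.0
    wake_sd_between: float = 60.0
    wake_sd_within_by_group: tuple = CALIBRATED_WAKE_SD_WITHIN
    bed_mean_population: float = 1320.0
    bed_sd_between: float = 50.0
    bed_sd_within_by_group: tuple = CALIBRATED_BED_SD_WITHIN
    #: lognormal sigma of the mean-one person-level multiplier on the
    #: within-person SDs — trait heterogeneity in routine variability
    sd_within_heterogeneity: float = 0.15
    steps_mean_referent: float = 8120.0
    steps_effect_prediabetes: float = -392.0
    steps_effect_diabetes: float = -1611.0
    steps_sd_between: float = 3850.0
    steps_sd_within: float = 2000.0
    bmi_steps_slope: float = -129.0
    wear_steps_slope: float = 3.0
    wear_hours_mean: float = 14.0
    wear_sd_minutes: float = 60.0
    missing_day_prob: float = 0.10
    out_of_window_prob_wake: float = 0.14
    out_of_window_prob_bed: float = 0.10
    cvd_prob: float = 0.0
    covariate_spec: dict = field(default_factory=_default_covariate_spec)
    seed: int = 20220107

    def validate(self):
        if self.n_participants <= 0:
            raise ConfigurationError("n_participants must be positive")
        p = np.asarray(self.group_proportions, dtype=float)
        if p.shape != (3,) or (p < 0).any() or (p > 1).any() or abs(p.sum() - 1) > 1e-9:
            raise ConfigurationError("group_proportions must be 3 probabilities summing to 1")
        if not 240 <= self.wake_mean_population <= 720:
            raise ConfigurationError("wake_mean_population must lie in [240, 720]")
        if not 1140 <= self.bed_mean_population < 1440:
            raise ConfigurationError("bed_mean_population must lie in [1140, 1440)")
        for name in (
            "wake_sd_between",
            "bed_sd_between",
            "steps_sd_between",
            "steps_sd_within",
            "wear_sd_minutes",
        ):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        for name in ("wake_sd_within_by_group", "bed_sd_within_by_group"):
            v = getattr(self, name)
            if len(v) != 3 or any(s < 0 for s in v):
                raise ConfigurationError(f"{name} must be 3 nonnegative SDs")
        if self.sd_within_heterogeneity < 0:
            raise ConfigurationError("sd_within_heterogeneity must be >= 0")
        for name in ("missing_day_prob", "out_of_window_prob_wake", "out_of_window_prob_bed", "cvd_prob"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigurationError(f"{name} must be a probability in [0, 1]")
        if self.followup_median_days < self.followup_min_days:
            raise ConfigurationError("followup_median_days must be >= followup_min_days")
        if self.wear_hours_mean <= 0 or self.wear_hours_mean > 24:
            raise ConfigurationError("wear_hours_mean must lie in (0, 24]")
        return self

    def replace(self, **kwargs) -> "SimulationConfig":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown config fields: {sorted(unknown)}")
        cfg = cls(**{k: tuple(v) if isinstance(v, list) else v for k, v in d.items()})
        return cfg.validate()


def null_config(**overrides) -> SimulationConfig:
    """A configuration with all group effects removed.

    Step effects are zero and every group shares the referent within-person
    watch-time SDs, so any fitted contrast estimates a true null; everything
    else (covariate distributions, wear, follow-up) keeps its default.
    """
    base = SimulationConfig()
    cfg = base.replace(
        steps_effect_prediabetes=0.0,
        steps_effect_diabetes=0.0,
        wake_sd_within_by_group=(base.wake_sd_within_by_group[0],) * 3,
        bed_sd_within_by_group=(base.bed_sd_within_by_group[0],) * 3,
        **overrides,
    )
    return cfg.validate()


@dataclass
class SyntheticCohort:
    """A realized cohort: baselines, day-level data, optional minute records.

    ``truth`` records the configuration and the realized latent quantities
    (per-participant wake/bed means and step means, injected group effects)
    so recovery can be checked against what was actually generated.
    """

    baselines: pd.DataFrame
    person_days: pd.DataFrame
    records: pd.DataFrame | None
    truth: dict


def _group_counts(n, proportions):
    """Largest-remainder rounding so counts are deterministic and sum to n."""
    raw = np.asarray(proportions, dtype=float) * n
    counts = np.floor(raw).astype(int)
    rem = raw - counts
    for i in np.argsort(-rem)[: n - counts.sum()]:
        counts[i] += 1
    return counts


def _truncnorm_rvs(rng, mean, sd, lo, hi, size=None):
    mean = np.asarray(mean, dtype=float)
    if sd == 0:
        out = np.clip(mean, lo, hi)
        return np.broadcast_to(out, size).copy() if size is not None else out
    a = (lo - mean) / sd
    b = (hi - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def _lognormal_params(mean, sd):
    """(mu, sigma) of a lognormal with the given arithmetic mean and SD."""
    if mean <= 0:
        raise ConfigurationError("lognormal mean must be positive")
    sigma2 = np.log1p((sd / mean) ** 2)
    return np.log(mean) - sigma2 / 2.0, np.sqrt(sigma2)


def _simulate_baselines(config, rng):
    spec = config.covariate_spec
    counts = _group_counts(config.n_participants, config.group_proportions)
    group = np.repeat(GROUPS, counts)
    n = config.n_participants
    pid = np.array([f"P{i:05d}" for i in range(n)])

    age = np.empty(n)
    bmi = np.empty(n)
    sex = np.empty(n, dtype=object)
    smoker = np.zeros(n, dtype=bool)
    drinker = np.zeros(n, dtype=bool)
    education = np.empty(n, dtype=object)
    glucose = np.empty(n)
    med = np.zeros(n, dtype=bool)
    edu_levels = ("high_school_or_less", "some_college", "bachelors", "graduate")

    for g in GROUPS:
        m = group == g
        k = int(m.sum())
        if k == 0:
            continue
        a_mu, a_sd = spec["age"][g]
        age[m] = np.clip(rng.normal(a_mu, a_sd, k), 25, 90).round(1)
        b_mu, b_sd = spec["bmi"][g]
        bmi[m] = np.clip(rng.normal(b_mu, b_sd, k), 15, 60).round(1)
        sex[m] = np.where(rng.random(k) < spec["female"][g], "female", "male")
        smoker[m] = rng.random(k) < spec["current_smoker"][g]
        drinker[m] = rng.random(k) < spec["current_drinker"][g]
        education[m] = rng.choice(edu_levels, size=k, p=spec["education"][g])
        if g == "referent":
            glucose[m] = np.clip(rng.normal(90, 6, k), 70, 99).round(0)
        elif g == "prediabetes":
            glucose[m] = np.clip(rng.normal(108, 8, k), 100, 125).round(0)
        else:
            on_med = rng.random(k) < spec["glucose_med_prob_diabetes"]
            med[m] = on_med
            g_hi = np.clip(rng.normal(150, 25, k), 126, 350).round(0)
            g_med = np.clip(rng.normal(130, 25, k), 80, 350).round(0)
            glucose[m] = np.where(on_med, g_med, g_hi)

    race_spec = spec["race_ethnicity"]
    race = rng.choice(race_spec["levels"], size=n, p=race_spec["probs"])
    cvd = rng.random(n) < config.cvd_prob

    return pd.DataFrame(
        {
            "participant_id": pid,
            "age": age,
            "sex": sex,
            "race_ethnicity": race,
            "bmi": bmi,
            "current_smoker": smoker,
            "current_drinker": drinker,
            "education": education,
            "fasting_glucose_mgdl": glucose,
            "glucose_med": med,
            "cvd_prevalent": cvd,
            "group": group,  # generative label; downstream re-derives it
        }
    )


def _simulate_followup(config, rng, n):
    """Follow-up spans: shifted geometric with the configured conditional median."""
    m = config.followup_median_days - config.followup_min_days + 1
    p = 1.0 - 0.5 ** (1.0 / m)
    span = config.followup_min_days - 1 + rng.geometric(p, size=n)
    if config.followup_cap_days is not None:
        span = np.minimum(span, config.followup_cap_days)
    return span.astype(int)


def simulate_cohort(config: SimulationConfig, resolution: str = "day") -> SyntheticCohort:
    """Generate a seeded synthetic cohort.

    Parameters
    ----------
    config
        Validated generative parameters; identical config (including seed)
        yields identical output.
    resolution
        ``"day"`` emits only the person-day table; ``"minute"`` additionally
        expands every day into one record per worn minute (suitable for small
        cohorts and for exercising the derivation stage).
    """
    config.validate()
    if resolution not in ("day", "minute"):
        raise ValueError("resolution must be 'day' or 'minute'")
    rng = np.random.default_rng(config.seed)

    baselines = _simulate_baselines(config, rng)
    n = len(baselines)
    gidx = baselines["group"].map({g: i for i, g in enumerate(GROUPS)}).to_numpy()

    # latent per-participant means and variability traits
    wake_mu = rng.normal(config.wake_mean_population, config.wake_sd_between, n)
    bed_mu = rng.normal(config.bed_mean_population, config.bed_sd_between, n)
    het = config.sd_within_heterogeneity
    if het > 0:
        # mean-one lognormal multipliers on the within-person SDs
        wake_sd_mult = rng.lognormal(-0.5 * het**2, het, n)
        bed_sd_mult = rng.lognormal(-0.5 * het**2, het, n)
    else:
        wake_sd_mult = np.ones(n)
        bed_sd_mult = np.ones(n)

    # person-mean daily steps: lognormal between-person spread around the
    # group's direct effect, plus a BMI-mediated component so that the total
    # (unadjusted-for-BMI) group contrast equals the configured effect.
    spec = config.covariate_spec
    bmi_ref_mean = spec["bmi"]["referent"][0]
    total_effects = np.array([0.0, config.steps_effect_prediabetes, config.steps_effect_diabetes])
    bmi_gaps = np.array([0.0] + [spec["bmi"][g][0] - bmi_ref_mean for g in GROUPS[1:]])
    direct_effects = total_effects - config.bmi_steps_slope * bmi_gaps
    steps_mu = np.empty(n)
    for i, g in enumerate(GROUPS):
        m = gidx == i
        if not m.any():
            continue
        mu_g = config.steps_mean_referent + direct_effects[i]
        lmu, lsd = _lognormal_params(mu_g, config.steps_sd_between)
        steps_mu[m] = rng.lognormal(lmu, lsd, int(m.sum()))
    steps_mu = steps_mu + config.bmi_steps_slope * (baselines["bmi"].to_numpy() - bmi_ref_mean)
    steps_mu = np.maximum(steps_mu, 200.0)

    followup = _simulate_followup(config, rng, n)
    enrollment = np.datetime64("2017-01-01") + rng.integers(0, 720, n).astype("timedelta64[D]")

    frames = []
    for i in range(n):
        T = followup[i]
        keep = rng.random(T) < 1.0 - config.missing_day_prob
        keep[0] = True
        keep[T - 1] = True
        days = np.nonzero(keep)[0]
        k = len(days)
        g = gidx[i]

        wake = _truncnorm_rvs(
            rng,
            wake_mu[i],
            config.wake_sd_within_by_group[g] * wake_sd_mult[i],
            *WAKE_TRUNCATION,
            size=k,
        )
        bed = _truncnorm_rvs(
            rng,
            bed_mu[i],
            config.bed_sd_within_by_group[g] * bed_sd_mult[i],
            *BED_TRUNCATION,
            size=k,
        )
        disp_w = rng.random(k) < config.out_of_window_prob_wake
        disp_b = rng.random(k) < config.out_of_window_prob_bed
        wake[disp_w] = rng.uniform(90, 239, disp_w.sum())
        bed[disp_b] = rng.uniform(900, 1139, disp_b.sum())
        wake = np.round(wake).astype(int)
        bed = np.round(bed).astype(int)

        span = bed - wake + 1
        wear = np.round(rng.normal(config.wear_hours_mean * 60.0, config.wear_sd_minutes, k))
        wear = np.clip(wear, 60, span).astype(int)

        steps = np.round(
            steps_mu[i]
            + config.wear_steps_slope * (wear - config.wear_hours_mean * 60.0)
            + rng.normal(0.0, config.steps_sd_within, k)
        )
        steps = np.maximum(steps, 0).astype(int)

        frames.append(
            pd.DataFrame(
                {
                    "participant_id": baselines["participant_id"].iloc[i],
                    "date": enrollment[i] + days.astype("timedelta64[D]"),
                    "first_watch_time": wake,
                    "last_watch_time": bed,
                    "wear_minutes": wear,
                    "step_total": steps,
                }
            )
        )

    person_days = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(
            columns=[
                "participant_id",
                "date",
                "first_watch_time",
                "last_watch_time",
                "wear_minutes",
                "step_total",
            ]
        )
    )
    if len(person_days):
        person_days["date"] = pd.to_datetime(person_days["date"])

    records = None
    if resolution == "minute":
        records = _expand_records(person_days, np.random.default_rng(rng.integers(2**31)))

    truth = {
        "config": config.to_dict(),
        "group_counts": dict(zip(GROUPS, (gidx == np.arange(3)[:, None]).sum(axis=1).tolist())),
        "injected_step_effects": {
            "prediabetes": config.steps_effect_prediabetes,
            "diabetes": config.steps_effect_diabetes,
        },
        "wake_mu": wake_mu,
        "bed_mu": bed_mu,
        "steps_mu": steps_mu,
        "followup_days": followup,
    }
    logger.info(
        "simulated cohort: %d participants, %d person-days%s",
        n,
        len(person_days),
        "" if records is None else f", {len(records)} minute records",
    )
    return SyntheticCohort(
        baselines=baselines.drop(columns=["group"]),
        person_days=person_days,
        records=records,
        truth=truth,
    )


def _expand_records(person_days, rng):
    """One record per worn minute, consistent with the day-level table.

    The first and last worn minutes are always kept (they define the day's
    first/last watch time); interior non-wear gaps are sampled uniformly and
    the daily step total is spread multinomially over the worn minutes.
    Every worn minute carries a heart-rate value.
    """
    pids, stamps, hrs, steps_col = [], [], [], []
    for row in person_days.itertuples(index=False):
        first, last = row.first_watch_time, row.last_watch_time
        span = last - first + 1
        wear = row.wear_minutes
        if wear >= span:
            minutes = np.arange(first, last + 1)
        elif wear <= 1:
            minutes = np.array([first]) if first == last else np.array([first, last])
        else:
            interior = rng.choice(np.arange(first + 1, last), size=wear - 2, replace=False)
            minutes = np.concatenate(([first], np.sort(interior), [last]))
        k = len(minutes)
        step_alloc = rng.multinomial(row.step_total, np.full(k, 1.0 / k))
        hr = np.clip(np.round(rng.normal(75, 8, k)), 40, 180).astype(int)
        base = pd.Timestamp(row.date)
        pids.append(np.full(k, row.participant_id, dtype=object))
        stamps.append(base + pd.to_timedelta(minutes, unit="m"))
        hrs.append(hr)
        steps_col.append(step_alloc)
    if not pids:
        return pd.DataFrame(columns=["participant_id", "timestamp", "heart_rate", "steps"])
    return pd.DataFrame(
        {
            "participant_id": np.concatenate(pids),
            "timestamp": pd.DatetimeIndex(np.concatenate(stamps)),
            "heart_rate": np.concatenate(hrs),
            "steps": np.concatenate(steps_col),
        }
    )


# ---------------------------------------------------------------------------
# I/O: external-interface schemas

RECORD_COLUMNS = ["participant_id", "timestamp", "heart_rate", "steps"]
BASELINE_COLUMNS = [
    "participant_id",
    "age",
    "sex",
    "race_ethnicity",
    "bmi",
    "current_smoker",
    "current_drinker",
    "education",
    "fasting_glucose_mgdl",
    "glucose_med",
    "cvd_prevalent",
]


def write_cohort(cohort: SyntheticCohort, directory) -> dict:
    """Write the cohort to CSV files; returns {name: path}.

    Always writes ``baselines.csv`` and ``person_days.csv``; writes
    ``records.csv`` when minute records were generated.  Round-trips
    losslessly through :func:`read_records` / :func:`read_baselines`.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {}

    baselines = cohort.baselines.loc[:, BASELINE_COLUMNS]
    paths["baselines"] = directory / "baselines.csv"
    baselines.to_csv(paths["baselines"], index=False)

    pd_out = cohort.person_days.copy()
    if len(pd_out):
        pd_out["date"] = pd.to_datetime(pd_out["date"]).dt.strftime("%Y-%m-%d")
    paths["person_days"] = directory / "person_days.csv"
    pd_out.to_csv(paths["person_days"], index=False)

    if cohort.records is not None:
        rec = cohort.records.copy()
        if len(rec):
            rec["timestamp"] = pd.to_datetime(rec["timestamp"]).dt.strftime("%Y-%m-%dT%H:%M")
        paths["records"] = directory / "records.csv"
        rec.to_csv(paths["records"], index=False)

    truth = {
        k: (v.tolist() if isinstance(v, np.ndarray) else v) for k, v in cohort.truth.items()
    }
    paths["truth"] = directory / "truth.json"
    paths["truth"].write_text(json.dumps(truth, indent=1))
    return paths


def read_records(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"participant_id": str})
    missing = set(RECORD_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"records file missing columns: {sorted(missing)}")
    return df


def read_baselines(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"participant_id": str})
    missing = set(BASELINE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"baseline file missing columns: {sorted(missing)}")
    for col in ("current_smoker", "current_drinker", "glucose_med", "cvd_prevalent"):
        df[col] = df[col].astype(bool)
    return df


def read_person_days(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"participant_id": str}, parse_dates=["date"])
    return df


def load_config(path) -> SimulationConfig:
    """Read a YAML or JSON configuration file."""
    import yaml

    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ConfigurationError("config file must contain a mapping")
    return SimulationConfig.from_dict(data)
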