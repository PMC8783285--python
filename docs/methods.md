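# Methods

## Setting and measurement model

`watchroutine` analyses daily-routine regularity in a smartwatch cohort of
middle-aged and older adults with and without impaired glycemic health.
Participants are instructed to put the watch on when they wake and take it
off at bedtime to charge, so wear itself carries behavioural signal: any
minute with a heart-rate or step observation is *watch time*, and on each
calendar day

* the **first watch time** proxies wake-up time,
* the **last watch time** proxies bedtime,
* the overnight **non-watch time** (from one day's last watch time to the
  next consecutive day's first watch time) proxies sleep duration,
* the **daily step total** summarises physical activity.

Times are integer minutes since local midnight on naive local timestamps
(no DST or timezone handling — a documented limitation). A wake proxy is
accepted only in the closed window [4:00, 12:00] (minute 240–720); a bedtime
proxy only in [19:00, 24:00) (minute 1140–1439) and only when the following
calendar day has records starting at or after 4:00, which rules out
post-midnight carryover. Window boundaries are measure-zero decisions and
configurable; midnight itself belongs to the next day. Days failing a window
keep their steps and wear minutes — only the failing variable is excluded.
Non-watch time is computed only across adjacent calendar dates (a skipped
day voids that night); an alternative "next watch day" pairing is available
behind a flag, off by default, and the [240, 1020]-minute closure bound does
not apply to it.

## Outcomes

For each participant the long-run mean of each watch-time variable is taken
over all their valid follow-up days (a single full-window mean, not a
rolling one; days are weighted equally). The repeated daily outcome is the
**absolute deviation** of the day's value from that mean, in minutes; signed
deviations are discarded. These deviations quantify intraindividual routine
irregularity. Daily step totals are used untransformed.

## Glycemic classification and quality control

Three-level status from baseline measurements: **diabetes** when fasting
glucose ≥ 126 mg/dL or any glucose-lowering medication is used;
**prediabetes** when glucose is in [100, 126) without medication;
**referent** otherwise. The half-open prediabetes band keeps the
classification total on continuous glucose values. Missing glucose without
medication leaves status missing and the participant is dropped with its own
reason code.

Participant-level exclusions run in a fixed order so reason codes are
deterministic: prevalent cardiovascular disease → unclassifiable status →
mean daily wear below 10 h (total wear minutes over days with records) →
follow-up span below 30 days (first-to-last data day inclusive; a data-day
count is available behind a flag). The accounting identity `n_input =
n_retained + Σ exclusions` is asserted on every run.

## Association models

Linear mixed regressions of each repeated daily outcome on glycemic status
(referent as reference), with a random intercept per participant, REML
estimation, and Wald 95% intervals on the identity scale. Covariate sets:
model 1 — sex, age, race/ethnicity; model 2 — + BMI; model 3 — + current
smoking and current alcohol use (both binary indicators); sensitivity
variants add follow-up days and daily wear minutes. Daily wear minutes are
always a time-varying covariate when the outcome is steps, because wear time
mechanically bounds the daily total. Race/ethnicity enters as unordered
categorical with the largest observed category as reference. Missing
covariates are handled by complete-case deletion (logged). Profile or robust
intervals and Kenward–Roger-type degree-of-freedom corrections are not
implemented; with hundreds of participants the Wald intervals are adequate.

Numerically, the variance optimisation starts from method-of-moments values
(OLS fixed effects plus a one-way ANOVA decomposition of the residuals into
within- and between-participant variance). This matters: for the deviation
outcomes the random-intercept variance is small relative to the residual,
and quasi-Newton optimisers started at the default can stall against the
zero-variance boundary — in testing, `lbfgs` then returned grossly wrong
fixed effects while reporting convergence. Moment-started fits reproduce the
slow reference optimisation exactly at a fraction of the cost. Fits with
fewer than two participants in any glycemic group raise a degenerate-data
error; the batch runner records such combinations as unconverged rows rather
than aborting.

## Synthetic cohort generator

The study's cohort data are not redistributable, so the generator emulates
the analysed (post-exclusion) sample and is the substrate for every
end-to-end test. Defaults describe a 796-participant cohort split 546
referent / 209 prediabetes / 41 diabetes.

Per participant: latent wake and bed means are normal (7:00 ± 60 min and
22:00 ± 50 min between persons). Daily wake/bed times are normal around the
latent means, truncated to the analysis windows; with probability 0.14 a
day's wake time is displaced before 4:00 and with probability 0.10 its bed
time is displaced before 19:00, reproducing the observed ~86% / ~90%
in-window proportions. Truncating the latent draws to the windows themselves
makes displacement the *only* out-of-window mechanism, so injected effects
act entirely on analysable days.

Within-person day-to-day SDs are group-specific and carry a mean-one
lognormal person-level multiplier (σ = 0.15): routine regularity is a
personal trait, and the contrast interval widths reported for such cohorts
imply between-person variance in the deviation outcome well above pure
sampling noise. The multiplier also keeps the random-intercept variance
usefully away from zero.

**Calibration.** The generator is parameterised by within-person SDs but the
scientific targets are fitted mean-absolute-deviation (MAD) contrasts. The
calibration oracle closes the gap semi-analytically: the MAD of a doubly
truncated normal about its own mean has a closed form via partial
expectations; averaging over the latent-mean and multiplier distributions by
Gauss–Hermite quadrature gives the population MAD as a function of the
within-person SD, which `brentq` inverts. Frozen defaults reproduce group
MADs of 57/60/69 min (first watch time) and 46/47/52 min (last watch time),
i.e. model-1 contrasts of +3/+12 and +1/+6 minutes. Since covariates do not
enter the watch-time outcomes in the generator, the fitted contrast equals
the MAD difference. The non-watch variable is a sum of the other two, so its
contrast is emergent: a large-n Monte-Carlo evaluation of the day-level law
gives +12.6 min (diabetes) and +2.9 min (prediabetes).

**Steps.** Person-mean daily steps are lognormal between persons (referent
mean 8120, SD 3850 — read as the between-participant spread of person
means), with group effects of −392 (prediabetes) and −1611 (diabetes)
steps/day defined as *total* effects. BMI acts as a mediator-like correlate:
it enters the person mean with slope −129 steps per kg/m², derived from the
ratio of BMI-adjusted to unadjusted contrasts over the ~6.5 kg/m² group BMI
gap, and the direct group effect is reduced accordingly so the total is
preserved. Adjusting for BMI therefore attenuates the fitted step contrast,
qualitatively and quantitatively mirroring the adjusted analyses. Daily
totals add a wear effect (3 steps per wear minute above the 14 h mean) and
normal day-to-day noise (SD 2000 — the within/between decomposition is not
identifiable from published summaries; this is a realistic day-to-day
spread), floored at zero and rounded. The flooring induces a differential
bias below ~20 steps/day, negligible against the effects.

**Covariates, wear, follow-up.** Group-conditional covariate distributions
(age, sex, BMI, smoking, alcohol, education) match the cohort's published
composition; fasting glucose and medication flags are drawn consistently
with the group label so classification round-trips. Wear is ~14 h/day (SD
60 min), placed as a contiguous wake-to-bed span with interior non-wear
gaps. Follow-up spans are a shifted geometric with conditional median 219
days above the 30-day floor (the generator emulates the post-QC sample;
dropout law beyond the published median is not claimed), capped at 3 years;
~10% of interior days are missing entirely, and the first and last day are
always present so the span is exact. The implied 90-day retention is ≈ 80%.

Two output resolutions are generated from the same day-level draws:
``minute`` expands each day into epoch records (non-wear gaps sampled
uniformly in the interior, steps spread multinomially, per-minute heart
rates); ``day`` emits the person-day sufficient statistics directly. A test
proves the minute records derive back to the identical day table, so
large-cohort studies run at day resolution without loss.

**What the generator does not emulate** — and hence what passing tests do
not establish about real data: physiological intra-day heart-rate structure;
circadian phenomena beyond wake/bed times (weekday/weekend cycles, seasonal
drift); informative missingness or dropout correlated with health status;
transmission gaps distinct from non-wear; device-level step-count error.
Parameter-recovery results certify the pipeline's statistical machinery, not
the behavioural realism of any particular cohort.

## Problem sizes for simulation studies

Parameter recovery uses the 796-participant cohort with follow-up capped at
120 days (the contrasts are follow-up-invariant in expectation; the cap
keeps replicate batches cheap): 20 replicates in the test suite, and in the
acceptance script 24 replicates for the deviation contrasts plus 120 for the
noisier step contrasts. Null calibration uses 400 participants, 180 days,
200 replicates, steps outcome. Derivation oracles run 1000 random record
fixtures against an independent brute-force scan with exact integer
equality.

## Known limitations

Cross-sectional by design — status is measured once at baseline; no causal
or mediation claims. Wake/bed proxies inherit the behavioural assumption
that wear tracks the sleep–wake boundary. Naive local time. Random
intercepts only (no random slopes), Wald inference, and no GEE alternative.
The exclusion order and the prediabetes boundary convention are fixed
choices where the underlying definitions are ambiguous.
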