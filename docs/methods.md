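# Methods

This note documents the models, the numerical choices, and what the
synthetic-data validation does and does not establish.

## Signal model and quality screening

Input is a uniform grid of nonnegative activity counts (15-s epochs,
7–14 days).  Two artifact rules mark epochs as *gaps* (missing, never
zero-filled): counts above the subject's global mean + 10 SD
(one-sided, since counts are bounded below), and maximal daytime runs
of zeros strictly longer than 60 minutes.  "Daytime" defaults to
08:00–20:00 local clock and is configurable; a zero-run qualifies only
when it lies entirely inside the window — runs straddling the window
boundary are presumed to contain genuine rest.  "Isolated" spikes are
interpreted as any epoch over threshold regardless of neighbours.  QC
only ever extends the gap mask; it is idempotent and never alters
count values.

## UP-EMD extraction of the ~24-h component

The series is averaged into 5-min bins (gaps linearly interpolated for
the decomposition only) and demeaned.  For each of 16 mask phases
uniformly spaced over [0, 2π), a sinusoid at the 24-h target period
with amplitude 2 × SD(series) is added, modes are sifted off until the
target-scale mode emerges, the mask is subtracted, and the 16 results
are averaged, cancelling mask leakage.

Sifting uses cubic-spline envelopes through local extrema,
mirror-extended by two extrema at each end, with a Cauchy-type stop
(energy of the mean envelope < 0.2² of the mode energy) or 50
iterations.  Within each masked pass, faster-than-target modes are
removed level by level: a plain pilot sift sets the scale of the
fastest remaining mode, which is then re-extracted with a mask at that
scale whose amplitude (2 × SD of the residual) dominates the slower
carrier.  This mask-assisted inner sifting is what prevents the classic
mode-mixing failure where a small fast mode riding a steep ~24-h
carrier steals carrier content; without it, extraction error grows
several-fold at realistic noise levels.  A candidate mode is accepted
as the ~24-h component once its extrema-based mean period exceeds 0.7 ×
24 h, which also keeps the 12-h harmonic of non-sinusoidal daily
waveforms out of the component.

Hilbert demodulation uses the analytic signal of the mirror-padded
component (padding one target period at each end limits edge ringing).
Peaks are the times where the unwrapped phase crosses multiples of 2π,
refined by linear interpolation between samples; a quarter-cycle Hann
smoother applied to the detrended phase suppresses crossing jitter.
Summaries use the first six complete peak-to-peak cycles (sample SD
with n−1 for cycle lengths; circular mean for acrophase, since an
arithmetic mean is wrong across midnight); amplitude is the mean
instantaneous amplitude — the mean rather than the median, a
documented choice — over those cycles, excluding samples within half a
cycle of either end, divided by the SD of the screened recording on
the same 5-min grid.  Subjects with fewer than six cycles are
ineligible, as are recordings under 7 days or with ≥20% gaps.

## Nonparametric metrics

IS and IV use 1-h bins (field convention; configurable).  IS is the
between-clock-hour sum of squares over the total, clipped at 1 (with
unequal hour coverage the raw ratio can nominally exceed 1).  IV is the
mean squared successive difference over consecutive valid hourly pairs
divided by the variance; missing hours break difference chains and are
never interpolated.  M10/L5 slide 10-h/5-h windows over the
epoch-resolution average day with midnight wraparound; fully missing
profile slots are filled by circular interpolation.  RA ties at the
cohort median are assigned "low" (deterministic).

## Sleep covariates

No published scoring algorithm is reimplemented here; the scorer is the
package's own, deliberately simple and subject-adaptive: an epoch is
"rest" iff it is valid, lies in the night window (default: the 12-h
window centred on the L5 midpoint), and its count is at or below the
threshold (default: 10th percentile of the subject's nonzero counts).
Sleep duration averages nightly rest hours over nights with ≥80% valid
coverage; fragmentation is the rest→active transition probability —
the geometric-bout hazard, for which the estimator is unbiased under a
memoryless bout model (verified at p = 0.01/0.03/0.1).

## Frailty

Quintile cut-offs use linear-interpolation percentiles on the baseline
cohort; grip, gait and physical activity are sex-stratified.  Gait is
recorded as a walk *time*, so its deficit group is the slowest quintile
(≥ 80th percentile of time) — low gait *speed* means high time.  BMI
uses the unstratified lowest quintile.  Quintile membership is ≤ the
cut-off (ties flagged).  Frail = ≥3 of 5 deficits; with missing
components the status is reported only when decidable either way.  The
composite score averages baseline-referenced z-scores of grip (×−1),
gait time, BMI (×−1) and the 0–2 fatigue score; by construction its
baseline cohort mean is 0 when the z-references come from the analysed
baseline sample (the reference population is configurable, since a
published composite may be referenced to an earlier or larger cohort
and then have a nonzero baseline mean).

## Association models

Follow-up is rounded to the nearest whole year (ties at .5 round up,
floor 1 year) to make event ties deliberate; Cox models then use the
Efron approximation (lifelines).  Continuous predictors are
standardized to the analysis sample; "decrease"-coded metrics are
negated after z-scoring so HR > 1 reads "per 1-SD decrease".
Complete-case handling throughout.

The Fine–Gray fit is written in-package: risk sets for the frailty
event keep subjects who died, weighted by G(t−)/G(T_death−) with G the
Kaplan–Meier censoring survival; the weighted partial likelihood
(Breslow ties) is maximized by damped Newton iteration.  On fixtures
with administrative-only censoring it agrees with an
infinite-risk-window Cox fit to 3 decimals (and with R's `cmprsk::crr`
on the same data); reported SEs are model-based and ignore the
estimation of G, so they are mildly approximate.  Because it uses
Breslow rather than Efron ties it can differ from the cause-specific
Cox fit by ~2–3% under heavy year-grouped ties even without deaths.

Trajectory models are REML random-intercept + random-slope linear
mixed models (statsmodels MixedLM, unstructured 2×2 covariance) with
metric × time as the effect of interest and covariate × time terms for
the adjustment set; a singular random-effects covariance triggers a
logged fallback to a random intercept only.  The ordinal fatigue model
is a cumulative-logit (proportional-odds) model with a subject random
intercept, fitted by maximum likelihood with 25-node Gauss–Hermite
quadrature; at σ_u = 0 it reproduces statsmodels' `OrderedModel`
estimates exactly, and thresholds/slopes are recovered within
Monte-Carlo error in simulation.

## Synthetic cohort generator

The generator defines the study conditions.  Rhythms are raised,
optionally tanh-squared cosines (`counts = max(0, mesor + A·w(φ) + ε)`,
rounded to integers) whose per-cycle lengths are 24 h + N(0, σ_jitter),
giving a well-defined true cycle-length SD; artifact spikes and
daytime device-off gaps are injected at configurable rates and logged
in a per-subject truth ledger together with every event time and
random effect, so recovery tests never re-derive truth from outputs.
Covariates follow the target population: age 81 ± 7.2, 74.6% female,
education 15.2 ± 3.0 years, vascular burden/risk as binomial sums.
Incident frailty times are exponential with log-hazard linear in the
subject's true standardized metrics; death is an independent competing
exponential; censoring is administrative at 16 years plus exponential
dropout; the baseline hazard can be calibrated by bisection to a
target event fraction (0.349, the studied cohort's).  Annual visits
carry a latent random-slope composite trajectory (defaults: intercept
−0.11, slope 0.095/yr, age × time 0.002, random intercept/slope SDs
0.4/0.05, residual SD 0.2); measured components are the latent score
plus independent noise mapped into natural units, and fatigue is the
thresholded latent score.

What the generator does *not* emulate: counts at night do not rest
near zero (noise is additive and homoscedastic), so absolute sleep
duration/fragmentation levels differ from a real cohort's; there is no
ultradian or behavioural autocorrelation, so generator IS runs high
and IV low relative to real wrist data; frailty event times are drawn
from the hazard model rather than derived from component-threshold
crossings, so the phenotype classifier and the survival models are
validated on separate ground truths.  Passing recovery tests therefore
demonstrates correctness of the estimators under the stated model, not
calibration to any real counts distribution.

## Validation design and problem sizes

Cox recovery simulates n = 1022 with injected per-1-SD hazard ratios
(1.37, 1.41, 1.28, 1.27) and ≈35% events, averaging fitted HRs over 50
seeds; mixed-model recovery injects slope 0.095, amplitude × time
0.005 (per 1-SD decrease) and age × time 0.002 into 16-visit panels of
n = 1022, also over 50 seeds.  Null-calibration checks (95% CI coverage
under zero effects, 200 replicates) run at n = 300 subjects (Cox) and
n = 150 × 6 visits (LMM): coverage is a calibration property and does
not require the full cohort size.  The demo pipeline uses 50 subjects
of 7-day recordings.

Known estimator limitations, measured against the generator ledger:
the Hilbert-phase cycle-length-SD estimator is essentially unbiased
for moderate jitter (|bias| < 0.1 h at σ = 0.25–0.5 h under clean
conditions) but shrinks large jitter (≈20% attenuation at σ = 1 h), as
any narrowband demodulation must, and acquires a ≈0.5 h noise floor at
the cohort noise level; the normalized-amplitude metric depends on the
resolution at which the recording SD is taken (fixed here to the 5-min
analysis grid).
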