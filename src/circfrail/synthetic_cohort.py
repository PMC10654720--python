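"""Synthetic actigraphy cohort with a known ground-truth ledger.

The real cohort this pipeline is designed for (community-dwelling older
adults with annual wrist actigraphy, frailty assessments and up to 16
years of follow-up) is restricted-access, so every downstream stage is
exercised on simulated data instead.  The generator produces three
linked artefacts:

* per-subject 15-s epoch actigraphy with a nonstationary ~24-h rhythm —
  a raised, optionally squared cosine whose cycle lengths jitter around
  24 h — plus Gaussian noise, isolated artifact spikes and daytime
  device-off gaps;
* a cohort table of covariates drawn from distributions matching the
  study population (age 81 ± 7.2, 74.6% female, education 15.2 ± 3.0,
  ...), proportional-hazards incident-frailty times driven by the
  subject's true standardized rhythm metrics, an independent competing
  death hazard and administrative censoring at 16 years, and annual
  frailty-component visits following a random-slope trajectory model;
* a truth ledger recording every realized parameter, injected artifact,
  event time and random effect, so recovery tests never re-derive truth
  from the generated outputs.

All randomness flows from one integer seed, expanded into per-subject
substreams so any subject is reproducible in isolation.  Dedicated
stripped-down recovery simulators (`simulate_survival_recovery`,
`simulate_trajectory_recovery`) implement the parameter-recovery designs
used by the validation suite: a standardized metric drawn N(0, 1),
exponential event times under a specified hazard ratio with censoring
calibrated to a target event fraction, and linear mixed trajectories
with specified fixed and random effects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq

from .actigraphy_qc import EpochSeries
from .errors import ConfigurationError

logger = logging.getLogger(__name__)

#: event fraction observed in the study cohort (357 of 1022 subjects)
TARGET_EVENT_FRACTION = 0.349

#: metrics for which a true value (hence a hazard effect) is defined
SIMULATED_METRICS = ("amplitude", "cycle_length_sd", "acrophase", "m10")


# ----------------------------------------------------------------------
# configuration
# ----------------------------------------------------------------------

@dataclass
class RhythmDistribution:
    """Population distributions of the per-subject rhythm parameters."""

    mesor_mean: float = 150.0          # counts per 15-s epoch
    mesor_sd: float = 40.0
    amplitude_mean: float = 100.0      # raw counts
    amplitude_sd: float = 35.0
    acrophase_mean: float = 13.1       # clock hours
    acrophase_sd: float = 1.5
    cycle_jitter_sd: float = 1.0       # hours, SD of per-cycle length
    squareness: float = 1.5            # 0 = pure cosine
    noise_sd: float = 80.0             # counts


@dataclass
class ArtifactConfig:
    spike_rate: float = 0.5            # expected spikes per day
    gap_rate: float = 0.3              # expected daytime device-off gaps/day
    gap_length_minutes: float = 90.0


@dataclass
class CovariateConfig:
    age_mean: float = 81.0
    age_sd: float = 7.2
    female_fraction: float = 0.746
    education_mean: float = 15.2
    education_sd: float = 3.0
    vascular_burden_mean: float = 0.35   # sum of 4 binary conditions
    vascular_risk_mean: float = 1.10     # sum of 3 binary risk factors
    ad_prevalence: float = 0.08
    pd_prevalence: float = 0.02
    grip_mean: float = 46.65
    grip_sd: float = 17.58
    gait_mean: float = 4.43
    gait_sd: float = 1.77
    bmi_mean: float = 27.25
    bmi_sd: float = 5.25
    activity_mean: float = 3.72          # hours/week; ~exponential spread
    fatigue_probs: tuple = (0.73, 0.22, 0.05)


@dataclass
class OutcomeConfig:
    baseline_hazard: float = 0.055       # frailty events / year at z = 0
    log_hr: dict = field(default_factory=dict)   # per 1-SD increase
    death_hazard: float = 0.04           # competing events / year
    censor_years: float = 16.0           # administrative
    dropout_rate: float = 0.1            # exponential dropout / year


@dataclass
class TrajectoryConfig:
    intercept: float = -0.11
    slope: float = 0.095                 # frailty-score units / year
    age_time: float = 0.002              # per year of age above the mean
    metric_time: dict = field(default_factory=dict)  # per 1-SD increase
    metric_main: dict = field(default_factory=dict)
    rand_intercept_sd: float = 0.4
    rand_slope_sd: float = 0.05
    rand_corr: float = 0.0
    residual_sd: float = 0.2
    component_noise_sd: float = 0.3      # extra z-noise per component


@dataclass
class SimConfig:
    """Full generator configuration; defaults match the study conditions."""

    n_subjects: int = 50
    epoch_seconds: float = 15.0
    min_days: int = 7
    max_days: int = 14
    rhythm: RhythmDistribution = field(default_factory=RhythmDistribution)
    artifacts: ArtifactConfig = field(default_factory=ArtifactConfig)
    covariates: CovariateConfig = field(default_factory=CovariateConfig)
    outcome: OutcomeConfig = field(default_factory=OutcomeConfig)
    trajectory: TrajectoryConfig = field(default_factory=TrajectoryConfig)
    start_date: str = "2020-01-06"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ConfigurationError("n_subjects must be >= 1")
        if self.epoch_seconds <= 0:
            raise ConfigurationError("epoch length must be positive")
        if not (7 <= self.min_days <= self.max_days <= 14):
            raise ConfigurationError("days per subject must lie within 7-14")
        r = self.rhythm
        for name in ("mesor_sd", "amplitude_sd", "acrophase_sd",
                     "cycle_jitter_sd", "noise_sd"):
            if getattr(r, name) < 0:
                raise ConfigurationError(f"rhythm.{name} must be >= 0")
        if not 0 <= r.acrophase_mean < 24:
            raise ConfigurationError("acrophase must lie in [0, 24)")
        a = self.artifacts
        if a.spike_rate < 0 or a.gap_rate < 0 or a.gap_length_minutes < 0:
            raise ConfigurationError("artifact rates must be >= 0")
        for metric in self.outcome.log_hr:
            if metric not in SIMULATED_METRICS:
                raise ConfigurationError(
                    f"hazard effect for unsimulated metric '{metric}'"
                )
        for metric in list(self.trajectory.metric_time) + list(
            self.trajectory.metric_main
        ):
            if metric not in SIMULATED_METRICS:
                raise ConfigurationError(
                    f"trajectory effect for unsimulated metric '{metric}'"
                )

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "SimConfig":
        kwargs = dict(raw)
        for key, sub in (("rhythm", RhythmDistribution),
                         ("artifacts", ArtifactConfig),
                         ("covariates", CovariateConfig),
                         ("outcome", OutcomeConfig),
                         ("trajectory", TrajectoryConfig)):
            if key in kwargs and isinstance(kwargs[key], dict):
                kwargs[key] = sub(**kwargs[key])
        cfg = cls(**kwargs)
        if isinstance(cfg.covariates.fatigue_probs, list):
            cfg.covariates.fatigue_probs = tuple(cfg.covariates.fatigue_probs)
        return cfg

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class TrueSubjectParams:
    """Ground-truth ledger for one subject."""

    subject_id: str
    seed: int
    days: int
    mesor: float
    amplitude_raw: float
    acrophase_true: float
    cycle_jitter_sd: float
    squareness: float
    noise_sd: float
    cycle_lengths: np.ndarray = None            # type: ignore[assignment]
    spike_epochs: np.ndarray = None             # type: ignore[assignment]
    gap_spans: list = field(default_factory=list)
    event_time: float = float("nan")            # years
    event_type: str = ""                        # frailty | death | censored
    rand_intercept: float = 0.0
    rand_slope: float = 0.0

    def __post_init__(self) -> None:
        if self.event_type and self.event_type not in (
            "frailty", "death", "censored"
        ):
            raise ConfigurationError(f"bad event type '{self.event_type}'")


# ----------------------------------------------------------------------
# waveform helpers
# ----------------------------------------------------------------------

def waveform(phase: np.ndarray, squareness: float) -> np.ndarray:
    """Shaped cosine in [-1, 1]; squareness 0 gives a pure cosine."""
    c = np.cos(phase)
    if squareness <= 0:
        return c
    return np.tanh(squareness * c) / np.tanh(squareness)


def _waveform_window_mean(squareness: float, window_hours: float,
                          maximum: bool) -> float:
    """Mean of the waveform over its best/worst window of given width."""
    phi = np.linspace(-np.pi, np.pi, 2881, endpoint=False)
    w = waveform(phi, squareness)
    half = window_hours / 48.0 * phi.size  # window fraction of the cycle
    width = max(1, int(round(2 * half)))
    ext = np.concatenate([w, w[: width - 1]])
    csum = np.concatenate([[0.0], np.cumsum(ext)])
    means = (csum[width:] - csum[:-width]) / width
    return float(means.max() if maximum else means.min())


def true_metrics(params: TrueSubjectParams) -> dict:
    """Analytic ground-truth metric values implied by the parameters.

    amplitude is normalized by the series SD implied by the rhythm +
    noise model; m10 is the waveform mean over the best 10-h window.
    """
    w_rms = 1.0 / np.sqrt(2.0) if params.squareness <= 0 else float(
        np.sqrt(np.mean(waveform(
            np.linspace(0, 2 * np.pi, 4096, endpoint=False), params.squareness
        ) ** 2))
    )
    signal_sd = np.sqrt(
        (params.amplitude_raw * w_rms) ** 2 + params.noise_sd**2
    )
    c10 = _waveform_window_mean(params.squareness, 10.0, maximum=True)
    return {
        "amplitude": params.amplitude_raw / signal_sd,
        "cycle_length_sd": params.cycle_jitter_sd,
        "acrophase": params.acrophase_true,
        "m10": params.mesor + params.amplitude_raw * c10,
    }


# ----------------------------------------------------------------------
# actigraphy generation
# ----------------------------------------------------------------------

def simulate_actigraphy(params: TrueSubjectParams, cfg: SimConfig) -> EpochSeries:
    """Generate one epoch series from a subject's true parameters.

    The rhythm phase advances piecewise-linearly through peaks separated
    by 24 h + Normal(0, cycle_jitter_sd) hours, so the realized cycle
    lengths (stored in the ledger) have a well-defined SD.  Counts are
    clipped at zero and rounded to integers; requested spikes and
    daytime gaps are injected afterwards and logged.
    """
    if params.days < 1 or cfg.epoch_seconds <= 0:
        raise ConfigurationError("duration and epoch length must be positive")
    rng = np.random.default_rng(params.seed)
    n = int(round(params.days * 24 * 3600 / cfg.epoch_seconds))
    t = np.arange(n) * cfg.epoch_seconds / 3600.0   # hours since midnight
    n_cycles = params.days + 2
    lengths = 24.0 + rng.normal(0.0, params.cycle_jitter_sd, size=n_cycles)
    lengths = np.maximum(lengths, 12.0)
    peaks = params.acrophase_true + np.concatenate([[0.0], np.cumsum(lengths)])
    # unwrap phase through the peaks: phase(p_k) = 2πk
    knots_t = np.concatenate([[peaks[0] - lengths[0]], peaks])
    knots_ph = 2 * np.pi * np.arange(-1, n_cycles + 1)
    phase = np.interp(t, knots_t, knots_ph)
    clean = params.mesor + params.amplitude_raw * waveform(
        phase, params.squareness
    )
    counts = clean + rng.normal(0.0, params.noise_sd, size=n)
    counts = np.maximum(np.round(counts), 0.0)

    # artifact spikes (isolated, far beyond the global mean)
    nominal_sd = np.sqrt((params.amplitude_raw / np.sqrt(2)) ** 2
                         + params.noise_sd**2)
    n_spikes = rng.poisson(cfg.artifacts.spike_rate * params.days)
    spike_idx = (
        rng.choice(n, size=min(n_spikes, n), replace=False)
        if n_spikes > 0 else np.array([], dtype=int)
    )
    counts[spike_idx] = np.round(
        params.mesor + rng.uniform(12.0, 18.0, size=spike_idx.size) * nominal_sd
    )

    # daytime device-off gaps: zero runs within 08:00-20:00
    gap_spans = []
    n_gaps = rng.poisson(cfg.artifacts.gap_rate * params.days)
    gap_h = cfg.artifacts.gap_length_minutes / 60.0
    per_hour = 3600.0 / cfg.epoch_seconds
    for _ in range(n_gaps):
        day = rng.integers(0, params.days)
        start_clock = rng.uniform(8.0, max(8.0 + 1e-6, 20.0 - gap_h))
        a = int(round((day * 24 + start_clock) * per_hour))
        b = min(n, a + int(round(gap_h * per_hour)))
        if a >= n:
            continue
        counts[a:b] = 0.0
        gap_spans.append((a, b))

    params.cycle_lengths = lengths
    params.spike_epochs = np.sort(spike_idx)
    params.gap_spans = gap_spans
    start = pd.Timestamp(cfg.start_date)
    return EpochSeries(params.subject_id, start, cfg.epoch_seconds, counts)


# ----------------------------------------------------------------------
# outcome calibration
# ----------------------------------------------------------------------

def _event_probability(log_lambda0: float, beta_z: np.ndarray,
                       censor_rate: float, admin_years: float) -> float:
    """Expected event fraction under exponential events and censoring."""
    lam = np.exp(log_lambda0 + beta_z)
    mu = censor_rate
    tot = lam + mu
    return float(np.mean(lam / tot * (1.0 - np.exp(-tot * admin_years))))


def calibrate_baseline_hazard(
    linear_predictor: np.ndarray,
    target_fraction: float = TARGET_EVENT_FRACTION,
    censor_rate: float = 0.1,
    admin_years: float = 16.0,
) -> float:
    """Baseline hazard giving the target expected event fraction.

    Solves E[P(event)] = target over the supplied linear-predictor values
    (log-hazard offsets) by bisection; increasing the baseline hazard
    can only increase the expected number of events.
    """
    if not 0 < target_fraction < 1:
        raise ConfigurationError("target event fraction must be in (0, 1)")
    f = lambda lg: (_event_probability(lg, linear_predictor, censor_rate,
                                       admin_years) - target_fraction)
    return float(np.exp(brentq(f, -12.0, 4.0)))


# ----------------------------------------------------------------------
# cohort generation
# ----------------------------------------------------------------------

def _draw_covariates(rng: np.random.Generator, cov: CovariateConfig) -> dict:
    return {
        "age": rng.normal(cov.age_mean, cov.age_sd),
        "female": int(rng.random() < cov.female_fraction),
        "education": max(0.0, rng.normal(cov.education_mean, cov.education_sd)),
        "vascular_burden": int(rng.binomial(4, cov.vascular_burden_mean / 4.0)),
        "vascular_risk": int(rng.binomial(3, cov.vascular_risk_mean / 3.0)),
        "ad_diagnosis": int(rng.random() < cov.ad_prevalence),
        "pd_diagnosis": int(rng.random() < cov.pd_prevalence),
    }


def simulate_cohort(
    cfg: SimConfig,
) -> tuple[pd.DataFrame, dict[str, EpochSeries], list[TrueSubjectParams]]:
    """Generate the full synthetic cohort.

    Returns (cohort table, per-subject epoch series, truth ledger).  The
    cohort table has one row per subject with covariates, observed
    follow-up (min of frailty, death, dropout and administrative
    censoring), and the event coding used downstream; annual visit rows
    with frailty components and the latent composite trajectory are in
    ``visits_long`` (attached as ``cohort.attrs["visits"]`` and also
    returned by :func:`simulate_visits`).
    """
    root = np.random.SeedSequence(cfg.seed)
    subject_seeds = root.spawn(cfg.n_subjects + 1)
    rng_cohort = np.random.default_rng(subject_seeds[-1])

    truths: list[TrueSubjectParams] = []
    series: dict[str, EpochSeries] = {}
    rows = []
    r = cfg.rhythm
    for i in range(cfg.n_subjects):
        sid = f"S{i:04d}"
        sub_rng = np.random.default_rng(subject_seeds[i])
        sub_seed = int(subject_seeds[i].generate_state(1)[0] % (2**31))
        days = int(sub_rng.integers(cfg.min_days, cfg.max_days + 1))
        params = TrueSubjectParams(
            subject_id=sid,
            seed=sub_seed,
            days=days,
            mesor=max(10.0, sub_rng.normal(r.mesor_mean, r.mesor_sd)),
            amplitude_raw=max(5.0, sub_rng.normal(r.amplitude_mean,
                                                  r.amplitude_sd)),
            acrophase_true=float(
                sub_rng.normal(r.acrophase_mean, r.acrophase_sd) % 24.0
            ),
            cycle_jitter_sd=float(
                max(0.05, sub_rng.gamma(2.0, r.cycle_jitter_sd / 2.0))
            ),
            squareness=r.squareness,
            noise_sd=r.noise_sd,
        )
        series[sid] = simulate_actigraphy(params, cfg)
        truths.append(params)
        row = {"subject_id": sid, **_draw_covariates(sub_rng, cfg.covariates)}
        row.update({f"true_{k}": v for k, v in true_metrics(params).items()})
        rows.append(row)

    cohort = pd.DataFrame(rows)

    # standardized true metrics (cohort sample z-scores, increase scale)
    zcols = {}
    for m in SIMULATED_METRICS:
        col = cohort[f"true_{m}"]
        zcols[m] = (col - col.mean()) / col.std(ddof=1)

    out = cfg.outcome
    lp = np.zeros(cfg.n_subjects)
    for m, b in out.log_hr.items():
        lp += b * zcols[m].to_numpy()
    lam = out.baseline_hazard * np.exp(lp)
    t_frail = rng_cohort.exponential(1.0 / np.maximum(lam, 1e-12))
    t_death = (
        rng_cohort.exponential(1.0 / out.death_hazard, size=cfg.n_subjects)
        if out.death_hazard > 0 else np.full(cfg.n_subjects, np.inf)
    )
    t_drop = (
        rng_cohort.exponential(1.0 / out.dropout_rate, size=cfg.n_subjects)
        if out.dropout_rate > 0 else np.full(cfg.n_subjects, np.inf)
    )
    t_cens = np.minimum(t_drop, out.censor_years)
    observed = np.minimum.reduce([t_frail, t_death, t_cens])
    event_type = np.where(
        t_frail <= np.minimum(t_death, t_cens), 1,
        np.where(t_death <= t_cens, 2, 0),
    )
    cohort["followup_years"] = np.maximum(observed, 1e-3)
    cohort["event_type"] = event_type
    cohort["frailty_event"] = (event_type == 1).astype(int)
    names = {1: "frailty", 2: "death", 0: "censored"}
    tr = cfg.trajectory
    for i, params in enumerate(truths):
        params.event_time = float(observed[i])
        params.event_type = names[int(event_type[i])]
        params.rand_intercept = float(
            rng_cohort.normal(0.0, tr.rand_intercept_sd)
        )
        rs_mean = (
            tr.rand_corr * tr.rand_slope_sd / tr.rand_intercept_sd
            * params.rand_intercept
            if tr.rand_intercept_sd > 0 else 0.0
        )
        rs_sd = tr.rand_slope_sd * np.sqrt(max(0.0, 1 - tr.rand_corr**2))
        params.rand_slope = float(rng_cohort.normal(rs_mean, rs_sd))

    visits = simulate_visits(cfg, cohort, truths, zcols, rng_cohort)
    cohort.attrs["visits"] = visits
    return cohort, series, truths


def simulate_visits(
    cfg: SimConfig,
    cohort: pd.DataFrame,
    truths: list[TrueSubjectParams],
    zcols: dict,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Annual frailty-component visits until each subject's event.

    The latent composite score follows the random-slope linear model;
    each measured component's z-score is the latent score plus
    independent noise, mapped back to its natural units (grip and BMI
    with inverted sign so that low values are frail), and fatigue is the
    latent score thresholded into the 0-2 ordinal range.
    """
    tr = cfg.trajectory
    cov = cfg.covariates
    rows = []
    age_c = cohort["age"] - cohort["age"].mean()
    for i, params in enumerate(truths):
        n_visits = int(np.floor(params.event_time)) + 1
        n_visits = min(n_visits, int(cfg.outcome.censor_years) + 1)
        slope_i = tr.slope + tr.age_time * age_c.iloc[i] + params.rand_slope
        level_i = tr.intercept + params.rand_intercept
        for m, b in tr.metric_time.items():
            slope_i += b * zcols[m].iloc[i]
        for m, b in tr.metric_main.items():
            level_i += b * zcols[m].iloc[i]
        for v in range(n_visits):
            t = float(v)
            latent = level_i + slope_i * t
            score = latent + rng.normal(0.0, tr.residual_sd)
            comp_z = latent + rng.normal(0.0, tr.component_noise_sd, size=4)
            grip = cov.grip_mean - cov.grip_sd * comp_z[0]
            gait = cov.gait_mean + cov.gait_sd * comp_z[1]
            bmi = cov.bmi_mean - cov.bmi_sd * comp_z[2]
            fat_latent = comp_z[3]
            fat = int(np.clip(np.digitize(fat_latent, [0.6, 1.6]), 0, 2))
            activity = rng.exponential(cov.activity_mean)
            rows.append({
                "subject_id": params.subject_id,
                "visit": v,
                "time": t,
                "latent_score": latent,
                "composite_score": score,
                "grip_strength": max(2.0, grip),
                "gait_time": max(1.0, gait),
                "bmi": max(14.0, bmi),
                "fatigue_score": fat,
                "fatigue_effort": int(fat >= 1),
                "fatigue_no_go": int(fat >= 2),
                "physical_activity": activity,
            })
    return pd.DataFrame(rows)


# ----------------------------------------------------------------------
# stripped-down recovery simulators
# ----------------------------------------------------------------------

def simulate_survival_recovery(
    n: int,
    hazard_ratio: float,
    direction: str = "increase",
    seed: int = 0,
    event_fraction: float = TARGET_EVENT_FRACTION,
    admin_years: float = 16.0,
    dropout_rate: float = 0.1,
) -> pd.DataFrame:
    """Single-metric proportional-hazards cohort for Cox recovery tests.

    The standardized metric is drawn N(0, 1); event times are exponential
    with hazard λ0·HR^(±z) (the sign chosen so ``hazard_ratio`` is the
    effect per 1-SD *change in the stated direction*); censoring is the
    minimum of administrative follow-up and exponential dropout, with λ0
    calibrated so the expected event fraction matches ``event_fraction``.
    """
    if hazard_ratio <= 0:
        raise ConfigurationError("hazard ratio must be positive")
    rng = np.random.default_rng(seed)
    z = rng.standard_normal(n)
    sign = -1.0 if direction == "decrease" else 1.0
    beta = sign * np.log(hazard_ratio)
    # calibrate on a fixed quadrature grid, not the sampled z
    lam0 = _calibrated_lambda0(beta, event_fraction, dropout_rate, admin_years)
    lam = lam0 * np.exp(beta * z)
    t_event = rng.exponential(1.0 / lam)
    t_cens = np.minimum(
        rng.exponential(1.0 / dropout_rate, size=n)
        if dropout_rate > 0 else np.inf,
        admin_years,
    )
    obs = np.minimum(t_event, t_cens)
    return pd.DataFrame({
        "metric": z,
        "followup_years": np.maximum(obs, 1e-3),
        "frailty_event": (t_event <= t_cens).astype(int),
        "true_event_time": t_event,
    })


def _calibrated_lambda0(beta: float, target: float, censor_rate: float,
                        admin_years: float) -> float:
    grid = np.linspace(-5, 5, 201)
    w = np.exp(-0.5 * grid**2)
    w /= w.sum()

    def frac(lg):
        lam = np.exp(lg + beta * grid)
        tot = lam + censor_rate
        p = lam / tot * (1.0 - np.exp(-tot * admin_years))
        return float(np.sum(w * p)) - target

    return float(np.exp(brentq(frac, -12.0, 4.0)))


def simulate_trajectory_recovery(
    n: int = 1022,
    seed: int = 0,
    intercept: float = -0.11,
    slope: float = 0.095,
    metric_main: float = -0.05,
    metric_time: float = -0.005,
    age_main: float = 0.0,
    age_time: float = 0.002,
    age_sd: float = 7.2,
    rand_intercept_sd: float = 0.4,
    rand_slope_sd: float = 0.05,
    residual_sd: float = 0.2,
    n_years: int = 16,
) -> pd.DataFrame:
    """Random-slope trajectory panel for mixed-model recovery tests.

    score_ij = intercept + metric_main·z_i + age_main·a_i + u0_i
             + (slope + metric_time·z_i + age_time·a_i + u1_i)·t + ε_ij
    with z ~ N(0,1) the standardized metric (increase scale), a the
    mean-centred baseline age, u0/u1 independent random effects and
    annual visits t = 0..n_years for everyone.
    """
    rng = np.random.default_rng(seed)
    z = rng.standard_normal(n)
    age_c = rng.normal(0.0, age_sd, size=n)
    u0 = rng.normal(0.0, rand_intercept_sd, size=n)
    u1 = rng.normal(0.0, rand_slope_sd, size=n)
    t = np.arange(n_years + 1, dtype=float)
    level = intercept + metric_main * z + age_main * age_c + u0     # (n,)
    slope_i = slope + metric_time * z + age_time * age_c + u1
    y = level[:, None] + slope_i[:, None] * t[None, :]
    y = y + rng.normal(0.0, residual_sd, size=y.shape)
    long = pd.DataFrame({
        "subject_id": np.repeat([f"S{i:04d}" for i in range(n)], t.size),
        "time": np.tile(t, n),
        "metric": np.repeat(z, t.size),
        "age_c": np.repeat(age_c, t.size),
        "composite_score": y.reshape(-1),
    })
    return long


def simulate_ordinal_trajectories(
    n: int = 300,
    n_visits: int = 6,
    thresholds=(0.5, 2.0),
    beta_time: float = 0.15,
    beta_metric: float = -0.2,
    sigma_u: float = 0.8,
    seed: int = 0,
) -> pd.DataFrame:
    """Proportional-odds panel for the ordinal fatigue model tests.

    P(Y ≤ k | u) = logistic(θ_k − (β_t·t + β_m·z) − u), u ~ N(0, σ_u²).
    """
    rng = np.random.default_rng(seed)
    z = rng.standard_normal(n)
    u = rng.normal(0.0, sigma_u, size=n)
    rows = []
    th = np.asarray(thresholds, dtype=float)
    for i in range(n):
        for t in range(n_visits):
            eta = beta_time * t + beta_metric * z[i] + u[i]
            p_le = 1.0 / (1.0 + np.exp(-(th - eta)))
            probs = np.diff(np.concatenate([[0.0], p_le, [1.0]]))
            y = int(rng.choice(len(probs), p=probs))
            rows.append({"subject_id": f"S{i:04d}", "time": float(t),
                         "metric": z[i], "fatigue_score": y})
    return pd.DataFrame(rows)
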