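"""End-to-end orchestration: simulate → QC → rhythms → sleep → frailty → models.

Each stage reads and writes plain CSV files inside a run directory, so a
stage can be re-run in isolation and no stage touches another's
internals.  A manifest (JSON) records the configuration hash, seed and
package version; re-running with the same configuration reproduces every
stochastic output bit-identically because all randomness descends from
the single configured seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .actigraphy_qc import DAY_END, DAY_START, load_epochs, run_qc
from .association_models import (
    fit_cox, fit_frailty_lmm, metric_correlations, predicted_curves,
)
from .errors import CircfrailError, ConfigurationError, ModelFitError
from .frailty_scoring import assess_cohort
from .rhythm_nonparametric import dichotomize_RA, nonparametric_metrics
from .rhythm_parametric import cosinor_fit, parametric_metrics
from .sleep_metrics import sleep_metrics
from .synthetic_cohort import SimConfig, simulate_cohort

logger = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "qc", "rhythms", "sleep", "frailty", "associate")

#: direction convention for the survival models: "decrease" for metrics
#: whose low values are hypothesised harmful, so reported HR > 1 means
#: higher hazard per 1-SD loss
METRIC_DIRECTIONS = {
    "amplitude": "decrease",
    "acrophase": "decrease",
    "cycle_length_sd": "increase",
    "IS": "decrease",
    "IV": "increase",
    "M10": "decrease",
    "L5": "increase",
    "cosinor_amplitude": "decrease",
}


@dataclass
class RunConfig:
    """Validated configuration for one pipeline run."""

    output_dir: str = "run"
    seed: int = 0
    stages: tuple = ALL_STAGES
    sim: SimConfig = None  # type: ignore[assignment]
    day_start: float = DAY_START
    day_end: float = DAY_END
    upemd_bin_minutes: float = 5.0
    is_bin_minutes: float = 60.0
    cox_metrics: tuple = ("amplitude", "cycle_length_sd", "IS", "IV", "M10")
    lmm_metrics: tuple = ("amplitude", "M10")
    covariates: tuple = (
        "age", "female", "education", "sleep_duration",
        "sleep_fragmentation", "vascular_burden", "vascular_risk",
    )

    def __post_init__(self) -> None:
        if self.sim is None:
            self.sim = SimConfig(seed=self.seed)
        elif isinstance(self.sim, dict):
            self.sim = SimConfig.from_dict({**self.sim, "seed": self.seed})
        if not 0 <= self.day_start < self.day_end <= 24:
            raise ConfigurationError("invalid daytime window")
        if self.upemd_bin_minutes <= 0 or self.is_bin_minutes <= 0:
            raise ConfigurationError("bin sizes must be positive")
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ConfigurationError(f"unknown stages {sorted(unknown)}")
        self.stages = tuple(s for s in ALL_STAGES if s in self.stages)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stages"] = list(self.stages)
        return d

    def config_hash(self) -> str:
        """Hash of the scientific configuration (paths excluded)."""
        d = self.to_dict()
        d.pop("output_dir", None)
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()


# ----------------------------------------------------------------------
# stages
# ----------------------------------------------------------------------

def stage_simulate(cfg: RunConfig, outdir: Path) -> None:
    cohort, series, truths = simulate_cohort(cfg.sim)
    epochs_dir = outdir / "epochs"
    epochs_dir.mkdir(parents=True, exist_ok=True)
    for sid, s in series.items():
        s.to_frame()[["timestamp", "counts"]].to_csv(
            epochs_dir / f"{sid}.csv", index=False
        )
    cohort.drop(columns=[c for c in cohort.columns if c.startswith("true_")]
                ).to_csv(outdir / "cohort.csv", index=False)
    cohort.attrs["visits"].to_csv(outdir / "visits.csv", index=False)
    truth_rows = []
    for t, (_, row) in zip(truths, cohort.iterrows()):
        truth_rows.append({
            "subject_id": t.subject_id,
            "days": t.days,
            "mesor": t.mesor,
            "amplitude_raw": t.amplitude_raw,
            "acrophase_true": t.acrophase_true,
            "cycle_jitter_sd": t.cycle_jitter_sd,
            "noise_sd": t.noise_sd,
            "n_spikes": len(t.spike_epochs),
            "n_gaps": len(t.gap_spans),
            "event_time": t.event_time,
            "event_type": t.event_type,
            "rand_intercept": t.rand_intercept,
            "rand_slope": t.rand_slope,
            **{k: row[k] for k in row.index if str(k).startswith("true_")},
        })
    pd.DataFrame(truth_rows).to_csv(outdir / "truth.csv", index=False)


def stage_qc(cfg: RunConfig, outdir: Path) -> None:
    epochs_dir = outdir / "epochs"
    qc_dir = outdir / "epochs_qc"
    qc_dir.mkdir(exist_ok=True)
    reports = []
    for path in sorted(epochs_dir.glob("*.csv")):
        series = load_epochs(path, subject_id=path.stem)
        series, report = run_qc(series, cfg.day_start, cfg.day_end)
        series.write_csv(qc_dir / f"{series.subject_id}.csv")
        reports.append(report.to_frame())
    if not reports:
        raise CircfrailError("qc: no epoch files found")
    pd.concat(reports, ignore_index=True).to_csv(
        outdir / "qc_report.csv", index=False
    )


def stage_rhythms(cfg: RunConfig, outdir: Path) -> None:
    qc_dir = outdir / "epochs_qc"
    rows = []
    for path in sorted(qc_dir.glob("*.csv")):
        series = load_epochs(path, subject_id=path.stem)
        row = {"subject_id": series.subject_id}
        try:
            pm, _ = parametric_metrics(
                series, bin_minutes=cfg.upemd_bin_minutes
            )
            row.update({
                "amplitude": pm.amplitude,
                "acrophase": pm.acrophase,
                "cycle_length_sd": pm.cycle_length_sd,
                "n_cycles_used": pm.n_cycles_used,
                "eligible": pm.eligible,
            })
            if not pm.eligible:
                logger.info("%s: <6 cycles, excluded from parametric metrics",
                            series.subject_id)
        except CircfrailError as exc:
            logger.warning("%s: parametric metrics skipped (%s)",
                           series.subject_id, exc)
            row["eligible"] = False
        try:
            cf = cosinor_fit(series, bin_minutes=cfg.upemd_bin_minutes)
            row.update({
                "cosinor_mesor": cf.mesor,
                "cosinor_amplitude": cf.amplitude_24h,
                "cosinor_acrophase": cf.acrophase_24h,
            })
            npm = nonparametric_metrics(series)
            row.update({
                "IS": npm.IS, "IV": npm.IV, "M10": npm.M10, "L5": npm.L5,
                "M10_midpoint": npm.M10_midpoint,
                "L5_midpoint": npm.L5_midpoint, "RA": npm.RA,
            })
        except CircfrailError as exc:
            logger.warning("%s: rhythm metrics incomplete (%s)",
                           series.subject_id, exc)
        rows.append(row)
    metrics = pd.DataFrame(rows)
    if "RA" in metrics.columns:
        metrics["RA_category"] = dichotomize_RA(metrics["RA"])
    metrics.to_csv(outdir / "metrics.csv", index=False)


def stage_sleep(cfg: RunConfig, outdir: Path) -> None:
    qc_dir = outdir / "epochs_qc"
    rows = []
    for path in sorted(qc_dir.glob("*.csv")):
        series = load_epochs(path, subject_id=path.stem)
        try:
            sm = sleep_metrics(series)
        except CircfrailError as exc:
            logger.warning("%s: sleep metrics skipped (%s)",
                           series.subject_id, exc)
            continue
        rows.append({
            "subject_id": sm.subject_id,
            "sleep_duration": sm.sleep_duration,
            "sleep_fragmentation": sm.sleep_fragmentation,
            "night_start": sm.night_start,
            "night_end": sm.night_end,
            "rest_threshold": sm.rest_threshold,
        })
    pd.DataFrame(rows).to_csv(outdir / "sleep.csv", index=False)


def stage_frailty(cfg: RunConfig, outdir: Path) -> None:
    visits = pd.read_csv(outdir / "visits.csv")
    cohort = pd.read_csv(outdir / "cohort.csv")
    sex = cohort.set_index("subject_id")["female"].map(
        {1: "female", 0: "male"}
    )
    visits["sex"] = visits["subject_id"].map(sex)
    assessment, _ = assess_cohort(visits)
    out = pd.concat(
        [visits[["subject_id", "visit", "time"]], assessment], axis=1
    )
    out.to_csv(outdir / "frailty.csv", index=False)


def stage_associate(cfg: RunConfig, outdir: Path) -> None:
    cohort = pd.read_csv(outdir / "cohort.csv")
    metrics = pd.read_csv(outdir / "metrics.csv")
    sleep = pd.read_csv(outdir / "sleep.csv")
    frailty = pd.read_csv(outdir / "frailty.csv")
    table = cohort.merge(metrics, on="subject_id").merge(
        sleep[["subject_id", "sleep_duration", "sleep_fragmentation"]],
        on="subject_id", how="left",
    )
    if "eligible" in table.columns:
        n0 = len(table)
        table = table[table["eligible"] == True]  # noqa: E712
        logger.info("associate: %d of %d subjects eligible", len(table), n0)

    cox_rows, curve_frames = [], []
    for metric in cfg.cox_metrics:
        if metric not in table.columns:
            continue
        direction = METRIC_DIRECTIONS.get(metric, "increase")
        try:
            res = fit_cox(table, metric, cfg.covariates, direction=direction)
        except ModelFitError:
            try:
                res = fit_cox(table, metric, ("age", "female", "education"),
                              direction=direction)
                res.metadata["reduced_covariates"] = True
            except ModelFitError as exc:
                logger.warning("cox %s skipped: %s", metric, exc)
                continue
        hr = res.hazard_ratios().loc[metric]
        cox_rows.append({
            "metric": metric, "direction": direction, "hr": hr["hr"],
            "ci_low": hr["ci_low"], "ci_high": hr["ci_high"], "p": hr["p"],
            "n": res.n, "events": res.n_events,
        })
        curves = predicted_curves(res, table)
        curves.insert(0, "metric", metric)
        curve_frames.append(curves)
    pd.DataFrame(
        cox_rows, columns=["metric", "direction", "hr", "ci_low", "ci_high",
                           "p", "n", "events"],
    ).to_csv(outdir / "results_cox.csv", index=False)

    long = frailty.merge(
        table[["subject_id"] + [m for m in cfg.lmm_metrics
                                if m in table.columns]
              + [c for c in cfg.covariates if c in table.columns]],
        on="subject_id",
    )
    lmm_rows = []
    for metric in cfg.lmm_metrics:
        if metric not in long.columns:
            continue
        direction = METRIC_DIRECTIONS.get(metric, "increase")
        try:
            res = fit_frailty_lmm(long, metric, cfg.covariates,
                                  direction=direction)
        except (ModelFitError, CircfrailError) as exc:
            logger.warning("lmm %s skipped: %s", metric, exc)
            continue
        for term in ("time", metric, f"{metric}:time"):
            if term in res.terms.index:
                row = res.terms.loc[term]
                lmm_rows.append({
                    "metric": metric, "term": term,
                    "estimate": row["estimate"], "se": row["se"],
                    "p": row["p"],
                })
        curves = predicted_curves(res, table)
        curves.insert(0, "metric", f"{metric}_trajectory")
        curve_frames.append(curves)
    pd.DataFrame(
        lmm_rows, columns=["metric", "term", "estimate", "se", "p"],
    ).to_csv(outdir / "results_lmm.csv", index=False)
    if curve_frames:
        pd.concat(curve_frames, ignore_index=True).to_csv(
            outdir / "curves.csv", index=False
        )
    corr_cols = [m for m in ("amplitude", "acrophase", "cycle_length_sd",
                             "IS", "IV", "M10", "L5", "RA")
                 if m in table.columns]
    metric_correlations(table[corr_cols]).to_csv(outdir / "correlations.csv")


STAGE_FUNCS = {
    "simulate": stage_simulate,
    "qc": stage_qc,
    "rhythms": stage_rhythms,
    "sleep": stage_sleep,
    "frailty": stage_frailty,
    "associate": stage_associate,
}


def run_pipeline(cfg: RunConfig) -> Path:
    """Run the configured stages in order; returns the run directory."""
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    for stage in cfg.stages:
        logger.info("stage %s", stage)
        try:
            STAGE_FUNCS[stage](cfg, outdir)
        except Exception as exc:
            raise CircfrailError(f"stage '{stage}' failed: {exc}") from exc
    manifest = {
        "config": cfg.to_dict(),
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "version": __version__,
        "stages_run": list(cfg.stages),
        "numpy": np.__version__,
        "pandas": pd.__version__,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return outdir
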