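"""Frailty phenotype and continuous composite frailty score.

The physical frailty phenotype counts deficits over five components —
grip strength (lbs, mean of four dynamometer trials), gait time (seconds
to walk eight feet), body-mass index, fatigue (two yes/no questionnaire
items, summed to a 0-2 score), and self-reported physical activity
(hours/week) — with a subject frail when three or more components are
deficient.  Deficit cut-offs are the 20th percentiles of the baseline
cohort; grip, gait and activity use sex-specific percentiles because of
level differences between men and women.  Gait is recorded as a *time*,
so its deficit group is the slowest (highest-time) quintile.  Fatigue is
deficient on a "yes" to either item.

The continuous composite score averages baseline-referenced z-scores of
grip, gait time, BMI and fatigue, with grip and BMI negated so that a
larger score always means frailer.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DegenerateSignalError

logger = logging.getLogger(__name__)

#: components entering the deficit count
PHENOTYPE_COMPONENTS = ("grip_strength", "gait_time", "bmi",
                        "fatigue", "physical_activity")
#: components entering the composite z-score (and their frail direction)
COMPOSITE_SIGNS = {"grip_strength": -1.0, "gait_time": 1.0,
                   "bmi": -1.0, "fatigue_score": 1.0}
#: sex-specific cut-offs are mandated for these
SEX_SPECIFIC = ("grip_strength", "gait_time", "physical_activity")
QUINTILE = 20.0
FRAIL_MIN_DEFICITS = 3


@dataclass
class CohortCutoffs:
    """Baseline 20th-percentile cut-offs and composite z-references.

    ``cutoffs[component]`` maps either sex ("male"/"female") or "all" to
    the cut-off value; ``zref[component]`` holds (mean, sd) pairs.
    """

    cutoffs: dict = field(default_factory=dict)
    zref: dict = field(default_factory=dict)
    n_baseline: int = 0


def fatigue_score(df: pd.DataFrame) -> pd.Series:
    """0-2 fatigue score from the two yes/no items (1 per "yes")."""
    if "fatigue_score" in df.columns:
        return pd.to_numeric(df["fatigue_score"])
    return (
        df["fatigue_effort"].astype(float) + df["fatigue_no_go"].astype(float)
    )


def compute_cutoffs(baseline: pd.DataFrame) -> CohortCutoffs:
    """Derive deficit cut-offs and z-references from the baseline cohort.

    Percentiles use linear interpolation.  Gait uses the 80th percentile
    of walk time (slowest quintile); all other quintile components use
    the 20th.  Requires at least 5 subjects per sex stratum for the
    sex-specific components.
    """
    out = CohortCutoffs(n_baseline=len(baseline))
    sexes = baseline["sex"].unique().tolist()
    for comp in ("grip_strength", "gait_time", "bmi", "physical_activity"):
        pct = 100.0 - QUINTILE if comp == "gait_time" else QUINTILE
        if comp in SEX_SPECIFIC:
            per_sex = {}
            for sex in sexes:
                vals = baseline.loc[baseline["sex"] == sex, comp].dropna()
                if len(vals) < 5:
                    raise ConfigurationError(
                        f"fewer than 5 subjects with {comp} in sex stratum "
                        f"'{sex}'"
                    )
                per_sex[str(sex)] = float(np.percentile(vals, pct))
            out.cutoffs[comp] = per_sex
        else:
            vals = baseline[comp].dropna()
            if len(vals) < 5:
                raise ConfigurationError(f"fewer than 5 subjects with {comp}")
            out.cutoffs[comp] = {"all": float(np.percentile(vals, pct))}
    fs = fatigue_score(baseline)
    for comp, series in (
        ("grip_strength", baseline["grip_strength"]),
        ("gait_time", baseline["gait_time"]),
        ("bmi", baseline["bmi"]),
        ("fatigue_score", fs),
    ):
        vals = pd.to_numeric(series).dropna()
        mu, sd = float(vals.mean()), float(vals.std(ddof=1))
        if sd == 0.0:
            raise DegenerateSignalError(
                f"zero baseline SD for composite component '{comp}'"
            )
        out.zref[comp] = (mu, sd)
    for comp, by_sex in out.cutoffs.items():
        for sex, cut in by_sex.items():
            vals = (
                baseline[comp]
                if sex == "all"
                else baseline.loc[baseline["sex"] == sex, comp]
            ).dropna()
            if vals.nunique() == 1:
                warnings.warn(
                    f"all {comp} values identical in stratum '{sex}': "
                    "everyone will be flagged"
                )
    return out


def _component_flags(df: pd.DataFrame, cutoffs: CohortCutoffs) -> pd.DataFrame:
    """Per-visit deficit flags (nullable booleans; NaN where missing)."""
    flags = pd.DataFrame(index=df.index)
    for comp in ("grip_strength", "gait_time", "bmi", "physical_activity"):
        cut_by = cutoffs.cutoffs[comp]
        if "all" in cut_by:
            cut = pd.Series(cut_by["all"], index=df.index)
        else:
            cut = df["sex"].astype(str).map(cut_by)
        vals = pd.to_numeric(df[comp])
        if comp == "gait_time":
            flag = vals >= cut     # slowest quintile is the deficit
        else:
            flag = vals <= cut
        flags[comp] = flag.where(vals.notna(), other=pd.NA)
    fs = fatigue_score(df)
    flags["fatigue"] = (fs >= 1).where(fs.notna(), other=pd.NA)
    return flags[list(PHENOTYPE_COMPONENTS)]


def classify_frailty(df: pd.DataFrame, cutoffs: CohortCutoffs) -> pd.DataFrame:
    """Deficit flags and frail status for each visit row.

    ``frail`` is True when ≥3 components are deficient, False when enough
    components are observed non-deficient to rule that out, and NA when
    missing components leave the ≥3 rule undecidable.
    """
    flags = _component_flags(df, cutoffs)
    n_true = flags.apply(lambda r: int((r == True).sum()), axis=1)  # noqa: E712
    n_missing = flags.isna().sum(axis=1)
    frail = pd.Series(pd.NA, index=df.index, dtype=object)
    frail[n_true >= FRAIL_MIN_DEFICITS] = True
    frail[(n_true + n_missing) < FRAIL_MIN_DEFICITS] = False
    undecided = frail.isna()
    if undecided.any():
        logger.info("%d visits with undecidable frailty status excluded",
                    int(undecided.sum()))
    out = flags.copy()
    out["n_deficits"] = n_true
    out["frail"] = frail
    return out


def composite_score(df: pd.DataFrame, cutoffs: CohortCutoffs) -> pd.Series:
    """Continuous frailty score: mean of directed baseline z-scores.

    score = mean{ −z(grip), +z(gait time), −z(BMI), +z(fatigue) }, using
    the baseline cohort means/SDs stored in ``cutoffs``; greater = frailer.
    """
    parts = []
    comp_values = {
        "grip_strength": pd.to_numeric(df["grip_strength"]),
        "gait_time": pd.to_numeric(df["gait_time"]),
        "bmi": pd.to_numeric(df["bmi"]),
        "fatigue_score": fatigue_score(df),
    }
    for comp, sign in COMPOSITE_SIGNS.items():
        mu, sd = cutoffs.zref[comp]
        parts.append(sign * (comp_values[comp] - mu) / sd)
    return sum(parts) / len(parts)


def assess_cohort(
    visits: pd.DataFrame, baseline: pd.DataFrame | None = None
) -> tuple[pd.DataFrame, CohortCutoffs]:
    """Full per-visit assessment against baseline-derived cut-offs.

    ``baseline`` defaults to the rows of ``visits`` with ``visit == 0``
    (or all rows when no visit column exists).
    """
    if baseline is None:
        baseline = (
            visits[visits["visit"] == 0] if "visit" in visits.columns else visits
        )
    cutoffs = compute_cutoffs(baseline)
    assessment = classify_frailty(visits, cutoffs)
    assessment["composite_score"] = composite_score(visits, cutoffs)
    assessment["fatigue_score"] = fatigue_score(visits)
    return assessment, cutoffs
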