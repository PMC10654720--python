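"""Nonparametric rest-activity metrics: IS, IV, M10, L5 and RA.

These classical actigraphy statistics make no rhythm-shape assumption:

* IS (interdaily stability, [0, 1]) — fraction of the total hourly
  variance explained by the average 24-h profile; 1 for perfectly
  repeated days, ≈1/d for white noise over d days.
* IV (intradaily variability, ≥ 0) — normalized mean square successive
  difference of the hourly series; ≈2 for white noise, near 0 for a
  smooth sinusoid.
* M10 / L5 — mean activity in the most active 10-h and least active 5-h
  windows of the average day (epoch resolution, midnight wraparound).
* RA = (M10 − L5) / (M10 + L5) — relative amplitude in [0, 1], which the
  cohort analysis dichotomises at the median (ties to "low") to correct
  its left-skewness.

IS and IV are computed on hourly bins; missing hours are excluded from IS
sums and break IV difference chains rather than being interpolated.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .actigraphy_qc import EpochSeries
from .errors import EligibilityError

logger = logging.getLogger(__name__)

M10_HOURS = 10.0
L5_HOURS = 5.0


@dataclass
class NonparametricRhythms:
    subject_id: str
    IS: float
    IV: float
    M10: float
    L5: float
    M10_midpoint: float   # clock hours
    L5_midpoint: float
    RA: float
    RA_category: str = ""   # "low"/"high", filled at cohort level


# ----------------------------------------------------------------------

def hourly_binned(series: EpochSeries) -> np.ndarray:
    """Hourly means over non-gap epochs as a (n_days, 24) matrix.

    Rows are calendar days relative to the first epoch's clock hour grid;
    hours with no valid epoch are NaN.
    """
    if series.duration_hours < 24.0:
        raise EligibilityError("need >= 24 h of data for hourly binning")
    start_clock = (
        series.start.hour + series.start.minute / 60.0 + series.start.second / 3600.0
    )
    abs_hour = np.floor(start_clock + series.hours_from_start).astype(int)
    valid = ~series.gap_mask
    n_hours = abs_hour[-1] + 1
    sums = np.bincount(abs_hour[valid], weights=series.counts[valid],
                       minlength=n_hours)
    cnts = np.bincount(abs_hour[valid], minlength=n_hours)
    with np.errstate(invalid="ignore"):
        hourly = np.where(cnts > 0, sums / np.maximum(cnts, 1), np.nan)
    n_days = int(np.ceil(n_hours / 24))
    out = np.full(n_days * 24, np.nan)
    out[: n_hours] = hourly
    return out.reshape(n_days, 24)


def compute_IS(hourly: np.ndarray) -> float:
    """Interdaily stability of an (n_days, 24) hourly matrix.

    IS = (n·Σ_h(x̄_h − x̄)²) / (p·Σ_i(x_i − x̄)²) with x̄_h the per-clock-hour
    means (p of them with any data) and x_i the n valid hourly values.
    Undefined (NaN, warning) for a zero-variance series.
    """
    x = np.asarray(hourly, dtype=float)
    valid = np.isfinite(x)
    if valid.sum(axis=0).astype(bool).sum() < 1 or valid.sum() < 25:
        raise EligibilityError("need >= 2 days of hourly data for IS")
    flat = x[valid]
    n = flat.size
    grand = flat.mean()
    ss_total = float(np.sum((flat - grand) ** 2))
    if ss_total == 0.0:
        warnings.warn("zero-variance hourly series: IS undefined")
        return float("nan")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        hour_means = np.nanmean(x, axis=0)
    have = np.isfinite(hour_means)
    p = int(have.sum())
    ss_hours = float(np.sum((hour_means[have] - grand) ** 2))
    # with unequal hour coverage the ratio can nominally exceed 1 by a
    # hair; IS is defined on [0, 1]
    return min((n * ss_hours) / (p * ss_total), 1.0)


def compute_IV(hourly: np.ndarray) -> float:
    """Intradaily variability of an (n_days, 24) hourly matrix.

    The mean squared difference over consecutive valid hourly pairs
    divided by the variance of the valid hours; missing hours break the
    difference chain.  Undefined (NaN, warning) at zero variance.
    """
    x = np.asarray(hourly, dtype=float).reshape(-1)
    valid = np.isfinite(x)
    flat = x[valid]
    n = flat.size
    if n < 2:
        raise EligibilityError("need >= 2 valid hours for IV")
    grand = flat.mean()
    var = float(np.sum((flat - grand) ** 2)) / (n - 1)
    if var == 0.0:
        warnings.warn("zero-variance hourly series: IV undefined")
        return float("nan")
    pair = valid[1:] & valid[:-1]
    m = int(pair.sum())
    if m < 1:
        raise EligibilityError("no consecutive valid hourly pairs for IV")
    d = x[1:][pair] - x[:-1][pair]
    msd = float(np.sum(d * d)) / m
    return msd / var


def average_day_profile(series: EpochSeries) -> tuple[np.ndarray, np.ndarray]:
    """Epoch-resolution average day (clock-aligned), gaps filled circularly.

    Returns (clock hours of bin starts, profile).  Bins with no valid
    epoch on any day are filled by circular linear interpolation.
    """
    per_day = int(round(24 * 3600 / series.epoch_seconds))
    start_clock = (
        series.start.hour + series.start.minute / 60.0 + series.start.second / 3600.0
    )
    offset = int(round(start_clock * 3600 / series.epoch_seconds))
    slot = (offset + np.arange(series.n_epochs)) % per_day
    valid = ~series.gap_mask
    sums = np.bincount(slot[valid], weights=series.counts[valid], minlength=per_day)
    cnts = np.bincount(slot[valid], minlength=per_day)
    with np.errstate(invalid="ignore"):
        profile = np.where(cnts > 0, sums / np.maximum(cnts, 1), np.nan)
    missing = ~np.isfinite(profile)
    if missing.any():
        if missing.all():
            raise EligibilityError("no valid epochs in any clock slot")
        # circular interpolation: unwrap by tripling
        idx = np.arange(per_day)
        good = ~missing
        tri_idx = np.concatenate([idx[good] - per_day, idx[good], idx[good] + per_day])
        tri_val = np.tile(profile[good], 3)
        profile[missing] = np.interp(idx[missing], tri_idx, tri_val)
    clock = (np.arange(per_day) * series.epoch_seconds / 3600.0) % 24.0
    return clock, profile


def _window_means(profile: np.ndarray, width: int) -> np.ndarray:
    """Circular sliding-window means over all start positions."""
    ext = np.concatenate([profile, profile[: width - 1]])
    csum = np.concatenate([[0.0], np.cumsum(ext)])
    return (csum[width:] - csum[:-width]) / width


def compute_M10_L5_RA(series: EpochSeries) -> NonparametricRhythms:
    """M10, L5, their window midpoints, and relative amplitude.

    Both windows slide over the epoch-resolution average day with
    midnight wraparound; M10 takes the maximal 10-h mean and L5 the
    minimal 5-h mean.  RA is undefined (NaN, warning) if the profile is
    identically zero.
    """
    if series.duration_hours < 24.0:
        raise EligibilityError("need >= 24 h of data for M10/L5")
    clock, profile = average_day_profile(series)
    per_hour = int(round(3600 / series.epoch_seconds))
    w10 = int(round(M10_HOURS * per_hour))
    w5 = int(round(L5_HOURS * per_hour))
    m10_means = _window_means(profile, w10)
    l5_means = _window_means(profile, w5)
    i10 = int(np.argmax(m10_means))
    i5 = int(np.argmin(l5_means))
    m10 = float(m10_means[i10])
    l5 = float(l5_means[i5])
    mid10 = float((clock[i10] + M10_HOURS / 2.0) % 24.0)
    mid5 = float((clock[i5] + L5_HOURS / 2.0) % 24.0)
    if m10 + l5 > 0:
        ra = (m10 - l5) / (m10 + l5)
    else:
        warnings.warn("all-zero average profile: RA undefined")
        ra = float("nan")
    return NonparametricRhythms(
        series.subject_id, float("nan"), float("nan"), m10, l5, mid10, mid5, ra
    )


def nonparametric_metrics(series: EpochSeries) -> NonparametricRhythms:
    """IS, IV, M10, L5 and RA for one screened series."""
    out = compute_M10_L5_RA(series)
    hourly = hourly_binned(series)
    out.IS = compute_IS(hourly)
    out.IV = compute_IV(hourly)
    return out


def dichotomize_RA(ra_values: pd.Series) -> pd.Series:
    """Cohort-level split of RA at the median; ties go to "low".

    The median split corrects RA's left-skewness before it enters the
    survival models as a binary predictor.
    """
    ra = pd.Series(ra_values, dtype=float)
    if ra.notna().sum() < 2:
        raise EligibilityError("need >= 2 subjects to dichotomize RA")
    med = float(ra.median())
    cat = pd.Series(
        np.where(ra <= med, "low", "high"), index=ra.index, dtype=object
    )
    cat[ra.isna()] = ""
    if float(ra.max()) == float(ra.min()):
        warnings.warn("all RA values identical: everyone categorized low")
    return cat
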