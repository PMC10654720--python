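"""Actigraphy sleep covariates: nightly sleep duration and fragmentation.

Sleep here is approximated from activity counts alone.  Epochs inside a
night window whose counts fall at or below a rest threshold are scored
"rest"; nightly sleep duration is the summed rest time averaged over
sufficiently observed nights, and sleep fragmentation is the empirical
rest-to-activity transition probability — the chance that an epoch scored
rest is followed by an active epoch.  Under a memoryless (geometric)
model of rest-bout lengths this transition probability is exactly the
bout-ending hazard, so the estimator is unbiased for it.

The scorer is deliberately simple and subject-adaptive: the default
threshold is the 10th percentile of the subject's nonzero counts and the
default night is the 12-h window centred on the L5 midpoint (the least
active 5 h of the average day).  It is a self-contained scorer, not a
reimplementation of any proprietary device algorithm.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .actigraphy_qc import EpochSeries
from .errors import DegenerateSignalError, EligibilityError
from .rhythm_nonparametric import compute_M10_L5_RA

logger = logging.getLogger(__name__)

#: default rest threshold: percentile of the subject's nonzero counts
REST_THRESHOLD_PERCENTILE = 10.0
#: night window length (hours) when centred on the L5 midpoint
NIGHT_HOURS = 12.0
#: minimum fraction of valid epochs for a night to enter the duration mean
MIN_NIGHT_VALID_FRACTION = 0.8


@dataclass
class SleepMetrics:
    subject_id: str
    sleep_duration: float         # hours per night
    sleep_fragmentation: float    # rest→active transition probability
    night_start: float            # clock hours
    night_end: float              # clock hours (window may wrap midnight)
    rest_threshold: float         # counts


def resolve_night_window(
    series: EpochSeries, night: Optional[tuple[float, float]] = None
) -> tuple[float, float]:
    """Explicit (start, end) clock window, or the L5-centred default."""
    if night is not None:
        return float(night[0]) % 24.0, float(night[1]) % 24.0
    l5_mid = compute_M10_L5_RA(series).L5_midpoint
    half = NIGHT_HOURS / 2.0
    return (l5_mid - half) % 24.0, (l5_mid + half) % 24.0


def resolve_rest_threshold(
    series: EpochSeries, threshold: Optional[float] = None
) -> float:
    """Explicit threshold, or the 10th percentile of nonzero valid counts."""
    if threshold is not None:
        if threshold < 0:
            raise DegenerateSignalError("rest threshold must be nonnegative")
        return float(threshold)
    nz = series.valid_counts()
    nz = nz[nz > 0]
    if nz.size == 0:
        return 0.0
    return float(np.percentile(nz, REST_THRESHOLD_PERCENTILE))


def _in_window(clock: np.ndarray, start: float, end: float) -> np.ndarray:
    if start < end:
        return (clock >= start) & (clock < end)
    return (clock >= start) | (clock < end)   # wraps midnight


def score_rest_epochs(
    series: EpochSeries,
    threshold: Optional[float] = None,
    night: Optional[tuple[float, float]] = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, SleepMetrics]:
    """Score each epoch as rest/active within nightly windows.

    Returns (rest flags, in-night mask, night index per epoch, a partially
    filled :class:`SleepMetrics` recording the window and threshold used).
    An epoch is rest iff it is valid, inside the night window, and its
    count is ≤ threshold (boundary counts score as rest).
    """
    start_h, end_h = resolve_night_window(series, night)
    thr = resolve_rest_threshold(series, threshold)
    clock = series.clock_hours
    in_night = _in_window(clock, start_h, end_h) & ~series.gap_mask
    if not in_night.any():
        raise EligibilityError(f"{series.subject_id}: no night coverage")
    rest = in_night & (series.counts <= thr)
    # night occurrence index: hours since start shifted so each window
    # falls inside one 24-h block
    t = series.hours_from_start
    start_clock = clock[0]
    shift = (start_clock - start_h) % 24.0
    night_idx = np.floor((t + shift) / 24.0).astype(int)
    meta = SleepMetrics(series.subject_id, float("nan"), float("nan"),
                        start_h, end_h, thr)
    return rest, in_night, night_idx, meta


def sleep_duration(
    rest: np.ndarray,
    in_night: np.ndarray,
    night_idx: np.ndarray,
    epoch_seconds: float,
    night_hours: float = NIGHT_HOURS,
    min_valid_fraction: float = MIN_NIGHT_VALID_FRACTION,
) -> float:
    """Mean nightly rest hours over nights with enough valid coverage.

    A night contributes only when at least ``min_valid_fraction`` of its
    expected window epochs were observed (not gapped / not truncated).
    """
    expected = night_hours * 3600.0 / epoch_seconds
    hours = []
    for k in np.unique(night_idx[in_night]):
        sel = in_night & (night_idx == k)
        if sel.sum() < min_valid_fraction * expected:
            continue
        hours.append(rest[sel].sum() * epoch_seconds / 3600.0)
    if not hours:
        raise EligibilityError("no night with sufficient valid coverage")
    return float(np.mean(hours))


def sleep_fragmentation(
    rest: np.ndarray, in_night: np.ndarray, night_idx: np.ndarray
) -> float:
    """Rest→active transition probability within nights.

    Counts, over epochs scored rest whose successor inside the same night
    was observed, the fraction whose successor is active.  Undefined
    (NaN, warning) when no rest epoch has an observed successor.
    """
    same_night = (
        in_night[:-1] & in_night[1:] & (night_idx[:-1] == night_idx[1:])
    )
    at_risk = rest[:-1] & same_night
    n_risk = int(at_risk.sum())
    if n_risk == 0:
        warnings.warn("no rest epoch with observed successor: "
                      "fragmentation undefined")
        return float("nan")
    transitions = int((at_risk & ~rest[1:]).sum())
    return transitions / n_risk


def sleep_metrics(
    series: EpochSeries,
    threshold: Optional[float] = None,
    night: Optional[tuple[float, float]] = None,
) -> SleepMetrics:
    """Duration and fragmentation for one screened series."""
    rest, in_night, night_idx, meta = score_rest_epochs(series, threshold, night)
    meta.sleep_duration = sleep_duration(
        rest, in_night, night_idx, series.epoch_seconds
    )
    meta.sleep_fragmentation = sleep_fragmentation(rest, in_night, night_idx)
    return meta
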