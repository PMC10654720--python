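"""Epoch-level actigraphy container and signal-quality screening.

Wrist actigraphy is summarised as nonnegative activity counts per fixed
epoch (15 s by default).  Before any rhythm analysis two artifact rules are
applied and the affected epochs are marked as *gaps* (missing), never
zero-filled:

1. isolated huge spikes — epochs whose count exceeds the subject's global
   mean by more than 10 standard deviations (one-sided: counts are bounded
   below by zero);
2. daytime device-off — maximal runs of zeros strictly longer than 60
   minutes lying inside the daytime window (08:00-20:00 by default), which
   almost always mean the device was taken off.

Both rules only ever extend the gap mask; count values are never altered,
and re-running QC on an already screened series is a no-op.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .errors import DegenerateSignalError, FormatError

logger = logging.getLogger(__name__)

#: default daytime window (clock hours) for the zero-run rule
DAY_START = 8.0
DAY_END = 20.0

#: spike threshold in standard deviations above the global mean
SPIKE_SD_FACTOR = 10.0

#: minimal daytime zero-run duration flagged as a gap (strict inequality)
ZERO_RUN_MINUTES = 60.0


@dataclass
class EpochSeries:
    """Uniformly sampled activity counts with a boolean gap mask.

    Parameters
    ----------
    subject_id:
        Identifier carried through all per-subject outputs.
    start:
        Timestamp of the first epoch.
    epoch_seconds:
        Epoch length in seconds (uniform grid).
    counts:
        Nonnegative activity counts, one per epoch.  Values at gap
        positions are retained but must be ignored by consumers.
    gap_mask:
        True where the epoch is missing/artifactual.
    """

    subject_id: str
    start: pd.Timestamp
    epoch_seconds: float
    counts: np.ndarray
    gap_mask: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 1 or self.counts.size < 1:
            raise FormatError("counts must be a non-empty 1-D array")
        if self.epoch_seconds <= 0:
            raise FormatError("epoch length must be positive")
        if self.gap_mask is None:
            self.gap_mask = np.zeros(self.counts.size, dtype=bool)
        self.gap_mask = np.asarray(self.gap_mask, dtype=bool)
        if self.gap_mask.shape != self.counts.shape:
            raise FormatError("gap mask must match counts in length")
        bad = np.flatnonzero((self.counts < 0) & ~self.gap_mask)
        if bad.size:
            raise FormatError(f"negative count at row {bad[0]}")
        self.start = pd.Timestamp(self.start)

    # ------------------------------------------------------------------
    @property
    def n_epochs(self) -> int:
        return int(self.counts.size)

    @property
    def duration_hours(self) -> float:
        return self.n_epochs * self.epoch_seconds / 3600.0

    @property
    def timestamps(self) -> pd.DatetimeIndex:
        return self.start + pd.to_timedelta(
            np.arange(self.n_epochs) * self.epoch_seconds, unit="s"
        )

    @property
    def hours_from_start(self) -> np.ndarray:
        return np.arange(self.n_epochs) * self.epoch_seconds / 3600.0

    @property
    def clock_hours(self) -> np.ndarray:
        """Clock time of each epoch in fractional hours [0, 24)."""
        start_clock = (
            self.start.hour + self.start.minute / 60.0 + self.start.second / 3600.0
        )
        return (start_clock + self.hours_from_start) % 24.0

    def valid_counts(self) -> np.ndarray:
        return self.counts[~self.gap_mask]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "timestamp": self.timestamps,
                "counts": self.counts,
                "gap": self.gap_mask.astype(int),
            }
        )

    def write_csv(self, path) -> None:
        # %.17g keeps float64 counts bit-exact across a write/load cycle
        self.to_frame().to_csv(path, index=False, float_format="%.17g")


@dataclass
class QCReport:
    """Summary of the screening applied to one recording."""

    subject_id: str
    n_spikes: int = 0
    n_zero_run_gaps: int = 0
    total_gap_minutes: float = 0.0
    fraction_valid: float = 1.0
    eligible: Optional[bool] = None  # six-cycle rule, filled by rhythm stage
    notes: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "subject_id": self.subject_id,
                    "n_spikes": self.n_spikes,
                    "n_zero_run_gaps": self.n_zero_run_gaps,
                    "total_gap_minutes": self.total_gap_minutes,
                    "fraction_valid": self.fraction_valid,
                    "eligible": self.eligible,
                }
            ]
        )


# ----------------------------------------------------------------------
# I/O
# ----------------------------------------------------------------------

def load_epochs(path, subject_id: Optional[str] = None) -> EpochSeries:
    """Read a two-column ``timestamp,counts`` CSV (optional ``gap`` column).

    The timestamp grid must be strictly increasing and uniformly spaced;
    any violation is reported with the first offending row index.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    if not {"timestamp", "counts"}.issubset(df.columns):
        raise FormatError(f"{path}: expected columns 'timestamp' and 'counts'")
    ts = pd.to_datetime(df["timestamp"])
    counts = pd.to_numeric(df["counts"], errors="coerce").to_numpy()
    bad = np.flatnonzero(~np.isfinite(counts))
    if bad.size:
        raise FormatError(f"{path}: non-numeric count at row {bad[0]}")
    bad = np.flatnonzero(counts < 0)
    if bad.size:
        raise FormatError(f"{path}: negative count at row {bad[0]}")
    if len(ts) > 1:
        deltas = np.diff(ts.to_numpy().astype("datetime64[ns]").astype(np.int64))
        if np.any(deltas <= 0):
            row = int(np.flatnonzero(deltas <= 0)[0]) + 1
            raise FormatError(f"{path}: non-increasing timestamp at row {row}")
        if np.any(deltas != deltas[0]):
            row = int(np.flatnonzero(deltas != deltas[0])[0]) + 1
            raise FormatError(f"{path}: irregular epoch spacing at row {row}")
        epoch_seconds = float(deltas[0]) / 1e9
    else:
        epoch_seconds = 15.0
    gap = (
        df["gap"].to_numpy().astype(bool)
        if "gap" in df.columns
        else np.zeros(len(df), dtype=bool)
    )
    sid = subject_id if subject_id is not None else str(path)
    return EpochSeries(sid, ts.iloc[0], epoch_seconds, counts, gap)


# ----------------------------------------------------------------------
# screening rules
# ----------------------------------------------------------------------

def flag_spikes(
    series: EpochSeries, sd_factor: float = SPIKE_SD_FACTOR
) -> tuple[EpochSeries, int]:
    """Mask epochs whose counts exceed mean + ``sd_factor``·SD.

    Mean and SD are taken over the subject's full non-gap recording.  A
    constant recording has no spikes by definition (a warning is logged).
    """
    valid = series.valid_counts()
    if valid.size < 2:
        raise DegenerateSignalError("need >= 2 non-gap epochs to screen spikes")
    mu, sd = float(valid.mean()), float(valid.std(ddof=0))
    if sd == 0.0:
        logger.warning("%s: constant series, no spikes flagged", series.subject_id)
        return series, 0
    spikes = (series.counts > mu + sd_factor * sd) & ~series.gap_mask
    n = int(spikes.sum())
    if n == 0:
        return series, 0
    return replace(series, gap_mask=series.gap_mask | spikes), n


def _zero_runs(is_zero: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as half-open (start, stop) index pairs."""
    padded = np.concatenate([[False], is_zero, [False]])
    d = np.diff(padded.astype(int))
    starts = np.flatnonzero(d == 1)
    stops = np.flatnonzero(d == -1)
    return list(zip(starts, stops))


def flag_daytime_zero_runs(
    series: EpochSeries,
    day_start: float = DAY_START,
    day_end: float = DAY_END,
    min_minutes: float = ZERO_RUN_MINUTES,
) -> tuple[EpochSeries, int]:
    """Mask maximal zero runs > ``min_minutes`` lying inside the day window.

    A run qualifies only when every epoch of the run falls within
    [day_start, day_end) local clock time — zeros at night are presumed
    genuine rest.  The duration comparison is strict (exactly 60 min is
    kept).
    """
    if not 0 <= day_start < day_end <= 24:
        raise FormatError("day window must satisfy 0 <= start < end <= 24")
    clock = series.clock_hours
    in_day = (clock >= day_start) & (clock < day_end)
    is_zero = (series.counts == 0) & ~series.gap_mask
    epoch_min = series.epoch_seconds / 60.0
    mask = series.gap_mask.copy()
    n_runs = 0
    for a, b in _zero_runs(is_zero):
        if (b - a) * epoch_min > min_minutes and in_day[a:b].all():
            mask[a:b] = True
            n_runs += 1
    if n_runs == 0:
        return series, 0
    return replace(series, gap_mask=mask), n_runs


def run_qc(
    series: EpochSeries,
    day_start: float = DAY_START,
    day_end: float = DAY_END,
    sd_factor: float = SPIKE_SD_FACTOR,
) -> tuple[EpochSeries, QCReport]:
    """Apply both screening rules and summarise them in a :class:`QCReport`."""
    report = QCReport(subject_id=series.subject_id)
    try:
        series, report.n_spikes = flag_spikes(series, sd_factor=sd_factor)
    except DegenerateSignalError as exc:
        warnings.warn(str(exc))
        report.notes.append(str(exc))
    series, report.n_zero_run_gaps = flag_daytime_zero_runs(
        series, day_start=day_start, day_end=day_end
    )
    report.total_gap_minutes = float(
        series.gap_mask.sum() * series.epoch_seconds / 60.0
    )
    report.fraction_valid = float(1.0 - series.gap_mask.mean())
    return series, report
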