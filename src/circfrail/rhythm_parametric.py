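"""Parametric circadian metrics via uniform-phase EMD and cosinor.

The ~24-h rest-activity rhythm of older adults is nonstationary: its
amplitude and cycle length drift from day to day and its waveform is not a
sine.  A single fitted cosine (the classical cosinor model) therefore
mis-states rhythm strength and timing for such recordings.  Uniform-phase
empirical mode decomposition (UP-EMD) instead *extracts* the oscillatory
component near 24 h directly from the data: a sinusoidal masking signal at
the target period is added to the series, intrinsic modes are sifted out
until the mode at the target time scale emerges, the mask is subtracted,
and the result is averaged over masks at uniformly spaced phases so that
mask leakage cancels.  Hilbert demodulation of the extracted component
then yields instantaneous amplitude and phase, from which three summary
metrics are formed over the first six complete (peak-to-peak) cycles:

* ``amplitude`` — mean instantaneous amplitude divided by the standard
  deviation of the recording (dimensionless rhythm strength);
* ``acrophase`` — circular mean of the per-cycle peak clock times (h);
* ``cycle_length_sd`` — sample SD of the six cycle lengths (h).

Subjects whose component contains fewer than six complete cycles are
ineligible.  The classical cosinor fit is provided as the comparator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import hilbert

from .actigraphy_qc import EpochSeries
from .errors import DegenerateSignalError, EligibilityError

logger = logging.getLogger(__name__)

#: number of uniformly spaced mask phases
N_PHASES = 16
#: mask amplitude as a multiple of the (detrended) signal SD
MASK_AMP_FACTOR = 2.0
#: Cauchy-type sifting stop criterion and iteration cap
SIFT_SD_STOP = 0.2
SIFT_MAX_ITER = 50
#: analysis grid for UP-EMD / cosinor (min); the ~24-h band is unaffected
ANALYSIS_BIN_MINUTES = 5.0
#: minimum number of complete cycles for eligibility
MIN_CYCLES = 6
#: minimum recording length (days) and maximum gap fraction
MIN_DAYS = 7.0
MAX_GAP_FRACTION = 0.2


@dataclass
class OscillatoryComponent:
    """The extracted ~24-h mode and its Hilbert demodulation products."""

    values: np.ndarray            # component on the analysis grid (counts)
    t_hours: np.ndarray           # hours since recording start
    start_clock_hour: float       # clock time of t=0, fractional hours
    target_period: float          # hours
    inst_amplitude: Optional[np.ndarray] = None
    inst_phase: Optional[np.ndarray] = None   # unwrapped, radians
    peak_times: Optional[np.ndarray] = None   # hours since start
    cycle_lengths: Optional[np.ndarray] = None  # hours

    @property
    def dt_hours(self) -> float:
        return float(self.t_hours[1] - self.t_hours[0])


@dataclass
class ParametricRhythms:
    """Per-subject UP-EMD summary metrics (first six complete cycles)."""

    subject_id: str
    amplitude: float          # normalized units (NaN when ineligible)
    acrophase: float          # clock hours in [0, 24)
    cycle_length_sd: float    # hours
    n_cycles_used: int
    eligible: bool


@dataclass
class CosinorFit:
    """Least-squares single-cosine fit with a fixed 24-h period."""

    subject_id: str
    mesor: float
    amplitude_24h: float
    acrophase_24h: float      # clock hours in [0, 24); NaN when degenerate
    rsquared: float


# ----------------------------------------------------------------------
# resampling
# ----------------------------------------------------------------------

def bin_series(
    series: EpochSeries,
    bin_minutes: float = ANALYSIS_BIN_MINUTES,
    interpolate: bool = True,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Average counts into ``bin_minutes`` bins over non-gap epochs.

    Returns (t_hours at bin centers, values, valid mask).  Fully gapped
    bins are NaN; with ``interpolate`` they are filled linearly (edge bins
    by nearest valid value) so the decomposition sees a complete grid.
    """
    per_bin = max(1, int(round(bin_minutes * 60.0 / series.epoch_seconds)))
    n_bins = series.n_epochs // per_bin
    if n_bins < 1:
        raise EligibilityError("recording shorter than one analysis bin")
    c = series.counts[: n_bins * per_bin].reshape(n_bins, per_bin)
    g = series.gap_mask[: n_bins * per_bin].reshape(n_bins, per_bin)
    n_valid = (~g).sum(axis=1)
    sums = np.where(~g, c, 0.0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = np.where(n_valid > 0, sums / np.maximum(n_valid, 1), np.nan)
    valid = n_valid > 0
    # bin time = mean of the epoch start times it averages (half-epoch
    # short of the geometric bin centre)
    t = (np.arange(n_bins) * per_bin + (per_bin - 1) / 2.0) * (
        series.epoch_seconds / 3600.0
    )
    if interpolate and not valid.all():
        if not valid.any():
            raise EligibilityError("recording is entirely gapped")
        vals = vals.copy()
        vals[~valid] = np.interp(t[~valid], t[valid], vals[valid])
    return t, vals, valid


# ----------------------------------------------------------------------
# EMD internals
# ----------------------------------------------------------------------

def _local_extrema(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    d = np.diff(x)
    # treat flat segments by sign of surrounding slopes
    s = np.sign(d)
    nz = s != 0
    if not nz.any():
        return np.array([], dtype=int), np.array([], dtype=int)
    # propagate last nonzero sign into flats
    idx = np.where(nz, np.arange(s.size), -1)
    np.maximum.accumulate(idx, out=idx)
    s_filled = np.where(idx >= 0, s[np.maximum(idx, 0)], 0)
    turn = np.diff(s_filled)
    maxima = np.flatnonzero(turn < 0) + 1
    minima = np.flatnonzero(turn > 0) + 1
    return maxima, minima


def _envelope(t: np.ndarray, x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Cubic-spline envelope through extrema, mirror-extended at the ends.

    Mirroring the outermost extrema across the boundaries is the usual
    EMD device to keep the spline from collapsing to the data values at
    the edges.
    """
    if knots.size == 0:
        return np.full_like(x, x[0])
    kt, kv = t[knots], x[knots]
    n_mirror = min(2, knots.size)
    left_t = 2 * t[0] - kt[:n_mirror][::-1]
    left_v = kv[:n_mirror][::-1]
    right_t = 2 * t[-1] - kt[-n_mirror:][::-1]
    right_v = kv[-n_mirror:][::-1]
    full_t = np.concatenate([left_t, kt, right_t])
    full_v = np.concatenate([left_v, kv, right_v])
    full_t, idx = np.unique(full_t, return_index=True)
    full_v = full_v[idx]
    if full_t.size < 4:
        return np.interp(t, full_t, full_v)
    return CubicSpline(full_t, full_v)(t)


def _sift_imf(t: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Extract one intrinsic mode function by standard sifting."""
    h = x.copy()
    for _ in range(SIFT_MAX_ITER):
        maxima, minima = _local_extrema(h)
        if maxima.size < 2 or minima.size < 2:
            return h
        mean_env = 0.5 * (_envelope(t, h, maxima) + _envelope(t, h, minima))
        h_new = h - mean_env
        denom = float(np.sum(h * h))
        if denom == 0.0:
            return h_new
        if float(np.sum(mean_env * mean_env)) / denom < SIFT_SD_STOP**2:
            return h_new
        h = h_new
    return h


def _mean_period_hours(t: np.ndarray, x: np.ndarray) -> float:
    """Mean oscillation period from the extrema count (inf if none)."""
    maxima, minima = _local_extrema(x)
    n_ext = maxima.size + minima.size
    if n_ext < 2:
        return float("inf")
    return 2.0 * (t[-1] - t[0]) / n_ext


def _masked_sift(t: np.ndarray, x: np.ndarray, period: float,
                 amp: float) -> np.ndarray:
    """First IMF under a masking signal at ``period``, two opposed phases.

    Adding a dominant sinusoid at the scale being extracted anchors the
    extrema spacing, which prevents the classic mode mixing where a fast
    mode riding a steep slow carrier leaks carrier content; averaging the
    two opposed mask phases cancels mask leakage to first order.
    """
    omega = 2.0 * np.pi / period
    acc = np.zeros_like(x)
    for phi in (0.0, np.pi):
        m = amp * np.cos(omega * t + phi)
        acc += _sift_imf(t, x + m) - m
    return acc / 2.0


#: a candidate mode is accepted as the target-scale mode once its mean
#: period exceeds this fraction of the target period; 0.7 keeps the 12-h
#: harmonic of non-sinusoidal daily waveforms out of the ~24-h mode
MODE_PERIOD_FRACTION = 0.7


def _extract_mode_at(t: np.ndarray, x: np.ndarray, target_period: float,
                     max_levels: int = 14) -> np.ndarray:
    """Strip modes faster than ``target_period`` off ``x``, then sift it.

    At each level a plain pilot sift sets the scale and amplitude of the
    fastest remaining mode; while that scale is well below the target
    period the mode is re-extracted with mask assistance at its own
    scale (which stops carrier leakage) and removed.  The first mode at
    target scale is returned.
    """
    residual = x.copy()
    cut = MODE_PERIOD_FRACTION * target_period
    for _ in range(max_levels):
        pilot = _sift_imf(t, residual)          # plain sift sets the scale
        per = _mean_period_hours(t, pilot)
        if not np.isfinite(per) or per >= cut:
            return pilot
        # the mask must dominate the slope of the slower carrier, not just
        # the fast mode itself, or the fast extraction leaks carrier content
        amp = 2.0 * float(residual.std(ddof=0))
        if amp == 0.0:
            break
        fast = _masked_sift(t, residual, per, amp)
        if _mean_period_hours(t, fast) >= cut:
            return fast
        residual = residual - fast
        maxima, minima = _local_extrema(residual)
        if maxima.size + minima.size < 2:
            break
    return residual - float(residual.mean())


# ----------------------------------------------------------------------
# public operations
# ----------------------------------------------------------------------

def upemd_extract(
    series: EpochSeries,
    target_period: float = 24.0,
    n_phases: int = N_PHASES,
    mask_amp_factor: float = MASK_AMP_FACTOR,
    bin_minutes: float = ANALYSIS_BIN_MINUTES,
) -> OscillatoryComponent:
    """Extract the ~24-h oscillatory component by uniform-phase masked EMD.

    For each of ``n_phases`` phases uniformly spaced over [0, 2π) a
    sinusoidal mask at the target period is added to the (gap-interpolated,
    demeaned) series, intrinsic modes are sifted until the target-scale
    mode emerges, the mask is subtracted, and the results are averaged
    across phases.

    Raises
    ------
    EligibilityError
        If the screened recording is shorter than 7 days or more than 20%
        of epochs are gaps.
    """
    if series.duration_hours < MIN_DAYS * 24.0:
        raise EligibilityError(
            f"{series.subject_id}: recording of {series.duration_hours / 24:.1f} "
            f"days is below the {MIN_DAYS:.0f}-day minimum"
        )
    gap_frac = float(series.gap_mask.mean())
    if gap_frac >= MAX_GAP_FRACTION:
        raise EligibilityError(
            f"{series.subject_id}: gap fraction {gap_frac:.2f} exceeds "
            f"{MAX_GAP_FRACTION:.2f}"
        )
    t, x, _ = bin_series(series, bin_minutes=bin_minutes, interpolate=True)
    x = x - float(x.mean())
    sd = float(x.std(ddof=0))
    if sd == 0.0:
        raise DegenerateSignalError(f"{series.subject_id}: constant recording")
    mask_amp = mask_amp_factor * sd
    omega = 2.0 * np.pi / target_period
    acc = np.zeros_like(x)
    for k in range(n_phases):
        phi = 2.0 * np.pi * k / n_phases
        mask = mask_amp * np.cos(omega * t + phi)
        mode = _extract_mode_at(t, x + mask, target_period)
        acc += mode - mask
    component = acc / n_phases
    start_clock = (
        series.start.hour
        + series.start.minute / 60.0
        + series.start.second / 3600.0
    )
    return OscillatoryComponent(
        values=component,
        t_hours=t,
        start_clock_hour=start_clock,
        target_period=target_period,
    )


def _smooth_phase(phase: np.ndarray, target_period: float,
                  dt_hours: float, window_fraction: float = 0.25) -> np.ndarray:
    """Low-pass the unwrapped phase around its linear trend.

    Residual phase noise from the Hilbert transform of a nearly (but not
    exactly) narrowband component jitters the 2π-crossing times; a Hann
    smoother of about a quarter cycle applied to the detrended phase
    removes that jitter without biasing the trend (the kernel is
    symmetric and the wiggle is reflect-padded at the ends).
    """
    n = phase.size
    width = int(round(window_fraction * target_period / dt_hours))
    if width < 3 or n < 2 * width:
        return phase
    idx = np.arange(n, dtype=float)
    slope, intercept = np.polyfit(idx, phase, 1)
    wiggle = phase - (intercept + slope * idx)
    kernel = np.hanning(width + 2)[1:-1]
    kernel /= kernel.sum()
    padded = np.concatenate([wiggle[width:0:-1], wiggle,
                             wiggle[-2:-width - 2:-1]])
    smoothed = np.convolve(padded, kernel, mode="same")[width: width + n]
    return intercept + slope * idx + smoothed


def hilbert_demodulate(component: OscillatoryComponent) -> OscillatoryComponent:
    """Fill instantaneous amplitude/phase, peak times and cycle lengths.

    The analytic signal of the component gives amplitude (its modulus) and
    unwrapped phase.  Peaks are marked where the unwrapped phase crosses
    multiples of 2π — for a cosine-like mode this is the positive peak —
    and cycle lengths are the successive peak-to-peak intervals.  Crossing
    times are refined by linear interpolation between samples.
    """
    x = np.asarray(component.values, dtype=float)
    if not np.all(np.isfinite(x)):
        raise DegenerateSignalError("component contains non-finite values")
    xc = x - float(x.mean())
    # mirror padding limits the transform's edge ringing; pad then crop
    pad = min(xc.size - 1, int(round(component.target_period / component.dt_hours)))
    padded = np.concatenate([xc[pad:0:-1], xc, xc[-2:-pad - 2:-1]])
    analytic = hilbert(padded)[pad: pad + xc.size]
    amp = np.abs(analytic)
    phase = np.unwrap(np.angle(analytic))
    phase = _smooth_phase(phase, component.target_period, component.dt_hours)
    t = component.t_hours
    # 2πk crossing times, k increasing with time
    k_lo = int(np.ceil(phase.min() / (2 * np.pi)))
    k_hi = int(np.floor(phase.max() / (2 * np.pi)))
    peaks = []
    for k in range(k_lo, k_hi + 1):
        target = 2 * np.pi * k
        below = phase < target
        idx = np.flatnonzero(below[:-1] & ~below[1:])
        if idx.size == 0:
            continue
        i = int(idx[0])
        frac = (target - phase[i]) / (phase[i + 1] - phase[i])
        peaks.append(t[i] + frac * (t[i + 1] - t[i]))
    peak_times = np.array(sorted(peaks))
    component.inst_amplitude = amp
    component.inst_phase = phase
    component.peak_times = peak_times
    component.cycle_lengths = np.diff(peak_times)
    return component


def _circular_mean_hours(hours: np.ndarray) -> float:
    ang = np.asarray(hours, dtype=float) * 2 * np.pi / 24.0
    m = np.angle(np.mean(np.exp(1j * ang)))
    h = float((m * 24.0 / (2 * np.pi)) % 24.0)
    return 0.0 if 24.0 - h < 1e-9 else h


def compute_parametric_metrics(
    component: OscillatoryComponent,
    series_sd: float,
    subject_id: str = "",
    n_cycles: int = MIN_CYCLES,
) -> ParametricRhythms:
    """Summarise the demodulated component over its first six cycles.

    ``series_sd`` is the standard deviation of the subject's screened
    recording on the analysis grid; the amplitude metric is the mean
    instantaneous amplitude divided by it.  Edge samples within half a
    cycle of either end are excluded from the amplitude average to limit
    Hilbert boundary distortion.
    """
    if series_sd <= 0:
        raise DegenerateSignalError(f"{subject_id}: zero-variance recording")
    if component.inst_amplitude is None or component.peak_times is None:
        component = hilbert_demodulate(component)
    peaks = component.peak_times
    n_complete = max(0, peaks.size - 1)
    if n_complete < n_cycles:
        logger.info(
            "%s: only %d complete cycles (<%d), ineligible",
            subject_id, n_complete, n_cycles,
        )
        return ParametricRhythms(
            subject_id, float("nan"), float("nan"), float("nan"),
            n_complete, False,
        )
    used = peaks[: n_cycles + 1]
    cycles = np.diff(used)
    half = 0.5 * component.target_period
    t = component.t_hours
    lo = max(used[0], t[0] + half)
    hi = min(used[-1], t[-1] - half)
    if hi <= lo:       # very short recordings: fall back to the peak span
        lo, hi = used[0], used[-1]
    sel = (t >= lo) & (t <= hi)
    amplitude = float(component.inst_amplitude[sel].mean()) / series_sd
    peak_clock = (component.start_clock_hour + used[:n_cycles]) % 24.0
    acrophase = _circular_mean_hours(peak_clock)
    cycle_sd = float(np.std(cycles, ddof=1))
    return ParametricRhythms(
        subject_id, amplitude, acrophase, cycle_sd, n_cycles, True
    )


def parametric_metrics(
    series: EpochSeries, **upemd_kwargs
) -> tuple[ParametricRhythms, OscillatoryComponent]:
    """Convenience wrapper: extract, demodulate and summarise one series."""
    comp = hilbert_demodulate(upemd_extract(series, **upemd_kwargs))
    _, binned, valid = bin_series(
        series, bin_minutes=upemd_kwargs.get("bin_minutes", ANALYSIS_BIN_MINUTES),
        interpolate=False,
    )
    sd = float(np.nanstd(binned[valid], ddof=0)) if valid.any() else 0.0
    return compute_parametric_metrics(comp, sd, subject_id=series.subject_id), comp


# ----------------------------------------------------------------------
# cosinor comparator
# ----------------------------------------------------------------------

def cosinor_fit(
    series: EpochSeries,
    period: float = 24.0,
    bin_minutes: float = ANALYSIS_BIN_MINUTES,
) -> CosinorFit:
    """Least-squares fit of mesor + A·cos(2π(t − φ)/period) on valid bins.

    The amplitude is reported nonnegative, with the acrophase φ given as
    the clock hour of the fitted peak.  A constant series yields A = 0
    with an undefined (NaN) acrophase.
    """
    t, vals, valid = bin_series(series, bin_minutes=bin_minutes, interpolate=False)
    t, y = t[valid], vals[valid]
    if t.size < 3 or (t[-1] - t[0]) < 24.0:
        raise EligibilityError(f"{series.subject_id}: need >= 24 h of valid data")
    omega = 2 * np.pi / period
    X = np.column_stack([np.ones_like(t), np.cos(omega * t), np.sin(omega * t)])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    mesor, b1, b2 = (float(b) for b in beta)
    amplitude = float(np.hypot(b1, b2))
    resid = y - X @ beta
    tss = float(np.sum((y - y.mean()) ** 2))
    rsq = 1.0 - float(np.sum(resid**2)) / tss if tss > 0 else 0.0
    if amplitude <= 1e-12 or tss == 0.0:
        logger.warning("%s: constant series, cosinor acrophase undefined",
                       series.subject_id)
        return CosinorFit(series.subject_id, mesor, 0.0, float("nan"), rsq)
    psi = np.arctan2(b2, b1)               # omega*t at the fitted peak
    start_clock = (
        series.start.hour + series.start.minute / 60.0 + series.start.second / 3600.0
    )
    acro = (start_clock + psi / omega) % 24.0
    return CosinorFit(series.subject_id, mesor, amplitude, float(acro), rsq)
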