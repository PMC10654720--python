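"""UP-EMD extraction, Hilbert demodulation, summary metrics, cosinor."""

import numpy as np
import pandas as pd
import pytest

from circfrail import (
    EpochSeries, SimConfig, TrueSubjectParams, compute_parametric_metrics,
    cosinor_fit, hilbert_demodulate, parametric_metrics, simulate_actigraphy,
    upemd_extract,
)
from circfrail.errors import EligibilityError
from circfrail.rhythm_parametric import OscillatoryComponent, bin_series
from circfrail.synthetic_cohort import ArtifactConfig

SQRT2 = np.sqrt(2.0)


class TestUpemdExtract:
    def test_pure_sinusoid_recovered(self, make_series):
        s = make_series(days=10)
        comp = upemd_extract(s)
        _, binned, _ = bin_series(s)
        r = np.corrcoef(comp.values, binned - binned.mean())[0, 1]
        assert r > 0.99

    def test_denoises_sinusoid_at_snr_one(self, make_series):
        """At epoch-level SNR 1 the component tracks the clean rhythm
        better than the raw recording does."""
        for seed in (1, 2, 3):
            s = make_series(days=10, amplitude=50.0,
                            noise_sd=50.0 / SQRT2, seed=seed)
            comp = upemd_extract(s)
            t, binned, _ = bin_series(s)
            clean = 50.0 * np.cos(2 * np.pi * (t - 14.0) / 24.0)
            raw15 = s.counts
            t15 = s.hours_from_start
            clean15 = 50.0 * np.cos(2 * np.pi * (t15 - 14.0) / 24.0)
            r_raw = np.corrcoef(raw15, clean15)[0, 1]
            r_comp = np.corrcoef(comp.values, clean)[0, 1]
            assert r_comp > r_raw
            assert r_comp > 0.95

    def test_short_recording_rejected(self, make_series):
        s = make_series(days=5)
        with pytest.raises(EligibilityError, match="day"):
            upemd_extract(s)

    def test_too_gappy_rejected(self, make_series):
        s = make_series(days=8)
        s.gap_mask[: int(0.25 * s.n_epochs)] = True
        with pytest.raises(EligibilityError, match="gap"):
            upemd_extract(s)


class TestHilbertDemodulate:
    def test_constant_amplitude_tracked(self, make_series):
        s = make_series(days=10, amplitude=40.0)
        comp = hilbert_demodulate(upemd_extract(s))
        t = comp.t_hours
        interior = (t > 24) & (t < t[-1] - 24)
        amp = comp.inst_amplitude[interior]
        assert np.allclose(amp, 40.0, rtol=0.05)

    def test_slow_amplitude_modulation_tracked(self):
        # A(t) drifting from 30 to 70 counts over 10 days
        epoch = 300.0
        n = int(10 * 24 * 3600 / epoch)
        t = np.arange(n) * epoch / 3600.0
        a_t = 30.0 + 40.0 * t / t[-1]
        values = a_t * np.cos(2 * np.pi * t / 24.0)
        comp = hilbert_demodulate(OscillatoryComponent(
            values=values, t_hours=t, start_clock_hour=0.0, target_period=24.0
        ))
        interior = (t > 24) & (t < t[-1] - 24)
        rel = comp.inst_amplitude[interior] / a_t[interior]
        assert np.all(np.abs(rel - 1.0) < 0.05)

    def test_zero_component_zero_amplitude(self):
        t = np.arange(0, 240, 1 / 12.0)
        comp = hilbert_demodulate(OscillatoryComponent(
            values=np.zeros_like(t), t_hours=t, start_clock_hour=0.0,
            target_period=24.0,
        ))
        assert np.allclose(comp.inst_amplitude, 0.0)


class TestParametricMetrics:
    def test_pure_sinusoid_normalized_amplitude_sqrt2(self, make_series):
        """Mean instantaneous amplitude over SD of a sinusoid = sqrt(2)."""
        for amplitude in (20.0, 50.0, 400.0):
            s = make_series(days=10, mesor=2 * amplitude, amplitude=amplitude)
            pm, _ = parametric_metrics(s)
            assert pm.eligible
            assert pm.amplitude == pytest.approx(SQRT2, rel=0.02)

    def test_acrophase_and_zero_cycle_sd(self, make_series):
        s = make_series(days=10, acrophase=13.0)
        pm, _ = parametric_metrics(s)
        assert pm.acrophase == pytest.approx(13.0, abs=0.25)
        assert pm.cycle_length_sd < 0.15
        assert pm.n_cycles_used == 6

    def test_circular_mean_wraps_midnight(self):
        from circfrail.rhythm_parametric import _circular_mean_hours
        assert _circular_mean_hours(np.array([23.5, 0.5])) == pytest.approx(0.0, abs=1e-9)
        assert _circular_mean_hours(np.array([23.0, 1.0, 0.0])) == pytest.approx(0.0, abs=1e-9)

    def test_fewer_than_six_cycles_ineligible(self):
        t = np.arange(0, 8 * 24, 1 / 12.0)
        comp = hilbert_demodulate(OscillatoryComponent(
            values=np.cos(2 * np.pi * t / 24.0), t_hours=t,
            start_clock_hour=0.0, target_period=24.0,
        ))
        comp.peak_times = comp.peak_times[:5]   # truncate to 4 cycles
        comp.cycle_lengths = np.diff(comp.peak_times)
        pm = compute_parametric_metrics(comp, 1.0, "s")
        assert not pm.eligible
        assert np.isnan(pm.amplitude)

    def test_amplitude_scale_invariant(self, make_series):
        s1 = make_series(days=10, noise_sd=20.0, seed=2)
        s2 = EpochSeries("x", s1.start, s1.epoch_seconds, s1.counts * 7.5)
        pm1, _ = parametric_metrics(s1)
        pm2, _ = parametric_metrics(s2)
        assert pm2.amplitude == pytest.approx(pm1.amplitude, rel=1e-6)

    def test_acrophase_shifts_with_time_shift(self, make_series):
        delta = 3.0
        s1 = make_series(days=10, acrophase=12.0, noise_sd=10.0, seed=3)
        s2 = make_series(days=10, acrophase=12.0 + delta, noise_sd=10.0, seed=3)
        pm1, _ = parametric_metrics(s1)
        pm2, _ = parametric_metrics(s2)
        assert (pm2.acrophase - pm1.acrophase) % 24 == pytest.approx(delta, abs=0.3)


class TestAgainstCosinorOnStationary:
    def test_upemd_and_cosinor_amplitudes_agree(self, make_series):
        s = make_series(days=10, amplitude=60.0, noise_sd=15.0, seed=8)
        pm, _ = parametric_metrics(s)
        cf = cosinor_fit(s)
        _, binned, valid = bin_series(s, interpolate=False)
        sd = np.nanstd(binned[valid])
        assert pm.amplitude == pytest.approx(cf.amplitude_24h / sd, rel=0.02)


class TestCycleLengthRecovery:
    """The generator's cycle-length jitter is recovered from its ledger.

    Under clean (noise-free) conditions the Hilbert-phase estimator
    tracks moderate jitter closely; its small-jitter noise floor and
    band-limitation shrinkage at extreme jitter are asserted as bounds.
    """

    @staticmethod
    def _estimate(sigma, n, noise_sd=0.0):
        cfg = SimConfig(n_subjects=1, artifacts=ArtifactConfig(0, 0, 0))
        est, led = [], []
        for i in range(n):
            p = TrueSubjectParams(
                subject_id=f"s{i}", seed=6000 + i, days=14, mesor=150.0,
                amplitude_raw=100.0, acrophase_true=13.5,
                cycle_jitter_sd=sigma, squareness=1.5, noise_sd=noise_sd,
            )
            series = simulate_actigraphy(p, cfg)
            pm, _ = parametric_metrics(series)
            if pm.eligible:
                est.append(pm.cycle_length_sd)
                led.append(np.std(p.cycle_lengths[1:7], ddof=1))
        return float(np.mean(est)), float(np.mean(led))

    def test_moderate_jitter_unbiased(self):
        for sigma in (0.25, 0.5):
            est, led = self._estimate(sigma, n=24)
            assert abs(est - led) < 0.1

    def test_zero_jitter_floor_small(self):
        est, _ = self._estimate(0.0, n=12)
        assert est < 0.1

    def test_monotone_in_true_jitter(self):
        e0, _ = self._estimate(0.0, n=12)
        e1, _ = self._estimate(0.5, n=12)
        e2, _ = self._estimate(1.0, n=12)
        assert e0 < e1 < e2


class TestCosinor:
    def test_noiseless_identity(self, make_series):
        # tolerance abs 1e-3: 5-min binning attenuates a 24-h cosine by
        # the sinc factor 1 - 2e-5
        s = make_series(days=7, mesor=10.0, amplitude=3.0, acrophase=14.0)
        cf = cosinor_fit(s)
        assert cf.mesor == pytest.approx(10.0, abs=1e-6)
        assert cf.amplitude_24h == pytest.approx(3.0, abs=1e-3)
        assert cf.acrophase_24h == pytest.approx(14.0, abs=1e-3)

    def test_constant_series_amplitude_zero(self, constant_series):
        cf = cosinor_fit(constant_series)
        assert cf.mesor == pytest.approx(5.0)
        assert cf.amplitude_24h == 0.0
        assert np.isnan(cf.acrophase_24h)

    def test_noisy_estimates_cover_truth(self, make_series):
        """Cosinor LS estimates land within 3 SE of truth almost always."""
        hits = 0
        n_rep = 60
        for seed in range(n_rep):
            # mesor far above zero so the nonnegativity clip never bites
            s = make_series(days=14, mesor=300.0, amplitude=30.0,
                            acrophase=13.0, noise_sd=60.0, seed=seed)
            cf = cosinor_fit(s)
            # analytic SE of LS amplitude at 5-min bins
            _, binned, valid = bin_series(s, interpolate=False)
            resid_sd = 60.0 / np.sqrt(20)     # binned noise SD
            se = resid_sd * np.sqrt(2.0 / valid.sum())
            if abs(cf.amplitude_24h - 30.0) < 3 * se:
                hits += 1
        assert hits >= int(0.9 * n_rep)
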