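"""Epoch spectra, band power, normalizations and slow-wave energy."""
import math

import numpy as np
import pytest

from resisleep.core import (DELTA, NREM, THETA, TOTAL, WAKE, BandDefinition,
                            Channel, ChannelMeta, Hypnogram, Recording)
from resisleep.spectral import (NOT_RECOVERED, SWETrace, band_power,
                                band_power_timecourse, epoch_spectra,
                                normalize_power, slow_wave_energy,
                                swe_recovery_time)


def recording_from(data, fs=100.0, role="EEG_FRONTAL"):
    meta = ChannelMeta(role, fs, 30.0 if fs <= 800 else 1000.0)
    return Recording(channels=[Channel(meta, np.asarray(data, dtype=np.float64))])


def hyp_for(n_epochs, label=NREM, epoch_s=10.0):
    return Hypnogram(labels=np.array([label] * n_epochs), epoch_s=epoch_s)


class TestEpochSpectra:
    def test_ten_second_epochs_give_tenth_hz_bins(self):
        fs = 100.0
        rec = recording_from(np.random.default_rng(0).standard_normal(int(fs * 100)))
        sp = epoch_spectra(rec, hyp_for(10), "EEG_FRONTAL")
        assert sp.df == pytest.approx(0.1)
        np.testing.assert_allclose(np.diff(sp.freqs), 0.1)

    def test_pure_tone_power_concentrates_at_its_frequency(self):
        """>= 95% of 0.5-30 Hz power of a 2 Hz tone lies within 1.9-2.1 Hz."""
        fs = 400.0
        t = np.arange(int(fs * 10)) / fs
        rec = recording_from(np.sin(2 * np.pi * 2.0 * t), fs=fs)
        sp = epoch_spectra(rec, hyp_for(1), "EEG_FRONTAL")
        total = band_power(sp, TOTAL)[0]
        near = band_power(sp, BandDefinition("near2", 1.9, 2.1))[0]
        assert near / total >= 0.95

    def test_zero_signal_gives_zero_spectrum(self):
        rec = recording_from(np.zeros(1000))
        sp = epoch_spectra(rec, hyp_for(1), "EEG_FRONTAL")
        assert np.all(sp.psd == 0)

    def test_white_noise_band_power_scales_with_bandwidth(self):
        """Flat spectrum: equal-width bands carry equal power (within 10%
        over 100 epochs)."""
        fs = 100.0
        rng = np.random.default_rng(42)
        rec = recording_from(rng.standard_normal(int(fs * 1000)))
        sp = epoch_spectra(rec, hyp_for(100), "EEG_FRONTAL")
        b1 = band_power(sp, BandDefinition("a", 2.0, 10.0)).mean()
        b2 = band_power(sp, BandDefinition("b", 12.0, 20.0)).mean()
        assert abs(b1 / b2 - 1.0) < 0.10

    def test_parseval_within_one_percent(self):
        """Spectral integral equals window-corrected time-domain power."""
        fs = 100.0
        rng = np.random.default_rng(7)
        n_ep = 100
        data = rng.standard_normal(int(fs * 10 * n_ep))
        rec = recording_from(data)
        sp = epoch_spectra(rec, hyp_for(n_ep), "EEG_FRONTAL", f_max=None)
        from scipy.signal import get_window
        w = get_window("hann", 1000, fftbins=True)
        u = np.sum(w * w)
        for k in range(n_ep):
            x = data[k * 1000:(k + 1) * 1000]
            time_power = np.sum((x * w) ** 2) / u
            spec_power = sp.psd[k].sum() * sp.df
            assert abs(spec_power / time_power - 1.0) < 0.01

    def test_matches_naive_dft_oracle(self):
        """Independent O(n^2) DFT implementation agrees to 1e-9 relative."""
        fs = 100.0
        rng = np.random.default_rng(3)
        n = int(fs * 1.0)
        data = rng.standard_normal(n)
        rec = recording_from(data)
        sp = epoch_spectra(rec, hyp_for(1, epoch_s=1.0), "EEG_FRONTAL", f_max=None)

        from scipy.signal import get_window
        w = get_window("hann", n, fftbins=True)
        xw = data * w
        u = np.sum(w * w)
        ks = np.arange(n // 2 + 1)
        oracle = np.empty(ks.size)
        for k in ks:
            c = np.sum(xw * np.exp(-2j * np.pi * k * np.arange(n) / n))
            scale = 1.0 if k in (0, n // 2) else 2.0
            oracle[k] = scale * abs(c) ** 2 / (fs * u)
        np.testing.assert_allclose(sp.psd[0], oracle, rtol=1e-9, atol=1e-12)

    def test_artifact_epochs_are_nan(self):
        rec = recording_from(np.ones(3000))
        hyp = Hypnogram(labels=np.array([NREM, "ARTIFACT", NREM]), epoch_s=10.0)
        sp = epoch_spectra(rec, hyp, "EEG_FRONTAL")
        assert np.isnan(sp.psd[1]).all() and np.isfinite(sp.psd[0]).all()

    def test_missing_channel_rejected(self):
        rec = recording_from(np.zeros(1000))
        with pytest.raises(KeyError, match="LFP_IL"):
            epoch_spectra(rec, hyp_for(1), "LFP_IL")


class TestBandTimecourse:
    def _flat_spectra(self, n_epochs=720, value=2.0):
        rec = recording_from(np.random.default_rng(0).standard_normal(
            n_epochs * 1000))
        sp = epoch_spectra(rec, hyp_for(n_epochs), "EEG_FRONTAL")
        sp.psd[:] = value  # constant density
        return sp

    def test_identical_spectra_give_constant_bins(self):
        sp = self._flat_spectra()
        tc = band_power_timecourse(sp, DELTA, bin_min=120.0, state_filter=NREM)
        expected = 2.0 * 36 * 0.1  # 36 bins in 0.5..4.0 inclusive, df=0.1
        np.testing.assert_allclose(tc.values, expected)

    def test_bins_without_qualifying_state_are_missing(self):
        sp = self._flat_spectra(n_epochs=720)
        sp.states[:360] = WAKE
        tc = band_power_timecourse(sp, DELTA, bin_min=60.0, state_filter=NREM)
        assert tc.table.iloc[0]["missing"]
        assert not tc.table.iloc[1]["missing"]
        assert math.isnan(tc.table.iloc[0]["power"])

    def test_band_equal_to_total_gives_100_percent(self):
        sp = self._flat_spectra()
        tc = band_power_timecourse(sp, TOTAL, bin_min=120.0, state_filter=NREM)
        out = normalize_power(tc, "pct_total")
        np.testing.assert_allclose(out.values, 100.0)

    def test_baseline_normalization_of_itself_is_100(self):
        sp = self._flat_spectra()
        tc = band_power_timecourse(sp, DELTA, bin_min=120.0, state_filter=NREM)
        out = normalize_power(tc, "baseline_24h", baseline=tc)
        np.testing.assert_allclose(out.values, 100.0)


class TestSlowWaveEnergy:
    def test_constant_power_energy_is_power_times_time(self):
        """k NREM epochs of constant delta power p: energy = p * 10k."""
        rec = recording_from(np.zeros(20 * 1000))
        sp = epoch_spectra(rec, hyp_for(20), "EEG_FRONTAL")
        sp.psd[:] = 0.0
        sel = (sp.freqs >= 0.5) & (sp.freqs <= 4.0)
        sp.psd[:, sel] = 1.0 / (sel.sum() * sp.df)  # band power exactly 1
        trace = slow_wave_energy(sp)
        np.testing.assert_allclose(trace.cumulative[-1], 10.0 * 20, rtol=1e-9)
        assert np.all(np.diff(trace.cumulative) >= 0)

    def test_all_wake_interval_has_zero_energy(self):
        rec = recording_from(np.random.default_rng(1).standard_normal(10 * 1000))
        sp = epoch_spectra(rec, hyp_for(10, label=WAKE), "EEG_FRONTAL")
        trace = slow_wave_energy(sp)
        assert trace.cumulative[-1] == 0.0

    def test_doubling_delta_amplitude_quadruples_energy(self):
        """Power scales with amplitude squared, so SWE scales ~4x."""
        from resisleep.simulate import (PhenotypeParams, StudyDesign,
                                        generate_hypnogram, generate_signals)
        design = StudyDesign(days=("BASELINE",))
        base = PhenotypeParams.resilient()
        hyp = generate_hypnogram(design, base, "BASELINE", 5)
        hyp = Hypnogram(labels=hyp.labels[:2160], epoch_s=10.0)  # ZT0-6
        meta = [ChannelMeta("EEG_FRONTAL", 100.0, 1000.0)]
        energies = []
        for gain in (1.0, 2.0):
            rec = generate_signals(hyp, base.with_(baseline_swa_gain=gain),
                                   meta, rng_seed=11)
            sp = epoch_spectra(rec, hyp, "EEG_FRONTAL")
            energies.append(slow_wave_energy(sp).cumulative[-1])
        ratio = energies[1] / energies[0]
        assert 3.4 < ratio < 4.3


class TestRecoveryTime:
    def _trace(self, cum, start_s=0.0, epoch_s=10.0):
        cum = np.asarray(cum, dtype=float)
        zt_end = start_s + (np.arange(cum.size) + 1) * epoch_s
        return SWETrace(zt_end_s=zt_end, cumulative=cum)

    def test_identical_traces_recover_immediately(self):
        cum = np.cumsum(np.ones(720))
        t = swe_recovery_time(self._trace(cum), self._trace(cum), bin_min=10.0)
        assert t == 0.0

    def test_half_baseline_never_recovers(self):
        cum = np.cumsum(np.ones(720))
        t = swe_recovery_time(self._trace(0.5 * cum), self._trace(cum),
                              bin_min=10.0)
        assert t == NOT_RECOVERED

    def test_late_catchup_reports_elapsed_minutes(self):
        base = np.cumsum(np.ones(720))            # 2 h of epochs
        rec = np.cumsum(np.where(np.arange(720) < 360, 0.0, 2.5))
        t = swe_recovery_time(self._trace(rec), self._trace(base), bin_min=30.0)
        # catches up at ~100 min; first satisfied bin end is 120 -> start 90
        assert t == 90.0

    def test_misaligned_traces_rejected(self):
        a = self._trace(np.ones(10))
        b = self._trace(np.ones(10), start_s=5.0)
        with pytest.raises(ValueError, match="aligned"):
            swe_recovery_time(a, b)
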