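import numpy as np
import pytest

from placecode import lfp as lfp_mod
from placecode.behaviour import SpeedSeries
from placecode.core import LFPRecording, ValidationError


FS = 1200.0  # ample for the 55-100 Hz band, keeps filtering fast


def tone(freq, duration=60.0, fs=FS, amp=1.0):
    t = np.arange(int(duration * fs)) / fs
    return LFPRecording(samples=amp * np.cos(2 * np.pi * freq * t), fs=fs)


class TestZscore:
    def test_simple(self):
        z = lfp_mod.zscore_lfp(LFPRecording(np.array([1.0, 2.0, 3.0]), fs=1000))
        assert z.mean() == pytest.approx(0.0, abs=1e-12)
        assert z.std() == pytest.approx(1.0)

    def test_idempotent(self, rng):
        x = rng.normal(size=5000)
        z1 = lfp_mod.zscore_lfp(LFPRecording(x, fs=1000))
        z2 = lfp_mod.zscore_lfp(LFPRecording(z1, fs=1000))
        np.testing.assert_allclose(z1, z2, atol=1e-12)

    def test_affine_invariance(self, rng):
        x = rng.normal(size=5000)
        za = lfp_mod.zscore_lfp(LFPRecording(3.7 * x + 11.0, fs=1000))
        zx = lfp_mod.zscore_lfp(LFPRecording(x, fs=1000))
        np.testing.assert_allclose(za, zx, atol=1e-9)

    def test_constant_signal_rejected(self):
        with pytest.raises(ValidationError):
            lfp_mod.zscore_lfp(LFPRecording(np.ones(100), fs=1000))


class TestSessionBandPower:
    def test_theta_tone_dominates(self):
        rec = tone(8.0, duration=120.0)
        power = lfp_mod.session_band_power(rec, [(0.0, 120.0)])
        assert power["theta"] / power["slow_gamma"] > 100
        assert power["theta"] / power["medium_gamma"] > 100

    def test_insufficient_epoch_time_rejected(self):
        rec = tone(8.0, duration=30.0)
        with pytest.raises(ValidationError):
            lfp_mod.session_band_power(rec, [(0.0, 10.0)])

    def test_amplitude_scaling_cancelled_by_zscore(self):
        # session power operates on the z-scored trace: pure gain is removed
        p1 = lfp_mod.session_band_power(tone(8.0, 60.0), [(0.0, 60.0)])
        p2 = lfp_mod.session_band_power(tone(8.0, 60.0, amp=5.0), [(0.0, 60.0)])
        assert p1["theta"] == pytest.approx(p2["theta"], rel=1e-6)


class TestBinnedBandPower:
    def test_tone_power_stationary(self):
        rec = tone(38.0, duration=60.0)
        power = lfp_mod.binned_band_power(rec)["slow_gamma"]
        assert power.std() / power.mean() < 0.05

    def test_amplitude_step_detected(self):
        n = int(60 * FS)
        t = np.arange(n) / FS
        amp = np.where(t < 30, 1.0, 3.0)
        rec = LFPRecording(amp * np.cos(2 * np.pi * 8 * t), fs=FS)
        power = lfp_mod.binned_band_power(rec)["theta"]
        first, second = power[:58].mean(), power[62:].mean()
        assert second / first == pytest.approx(9.0, rel=0.15)

    def test_band_integrals_bounded_by_total_power(self, rng):
        x = rng.normal(size=int(60 * FS))
        rec = LFPRecording(x, fs=FS)
        powers = lfp_mod.binned_band_power(rec)
        total = np.var(lfp_mod.zscore_lfp(rec))  # = 1 by construction
        band_sum = sum(p.mean() for p in powers.values())
        assert band_sum <= total


class TestVelocityStratified:
    def test_coupled_power_increases_with_speed(self, rng):
        n_epochs = 600
        speed_vals = rng.uniform(0, 30, n_epochs)
        speed = SpeedSeries(np.arange(n_epochs) * 0.5, 0.5, speed_vals)
        power = {"theta": 1.0 + 0.1 * speed_vals + rng.normal(0, 0.05, n_epochs)}
        edges, curves, counts = lfp_mod.velocity_stratified_power(power, speed)
        curve = curves["theta"]
        ok = np.isfinite(curve)
        assert np.all(np.diff(curve[ok]) > 0)

    def test_uncoupled_flat(self, rng):
        n_epochs = 2000
        speed = SpeedSeries(np.arange(n_epochs) * 0.5, 0.5,
                            rng.uniform(0, 30, n_epochs))
        power = {"theta": np.full(n_epochs, 2.0)}
        _, curves, _ = lfp_mod.velocity_stratified_power(power, speed)
        c = curves["theta"]
        np.testing.assert_allclose(c[np.isfinite(c)], 2.0, atol=1e-9)

    def test_counts_match_time_in_speed_bins(self, rng):
        from placecode.behaviour import time_in_speed_bins
        n_epochs = 500
        speed = SpeedSeries(np.arange(n_epochs) * 0.5, 0.5,
                            rng.uniform(0, 40, n_epochs))
        power = {"theta": np.ones(n_epochs)}
        _, _, counts = lfp_mod.velocity_stratified_power(power, speed)
        _, seconds = time_in_speed_bins(speed)
        np.testing.assert_allclose(counts, seconds / 0.5)


class TestBandpassAndPhase:
    def test_in_band_tone_retained(self):
        rec = tone(8.0, duration=30.0)
        out = lfp_mod.bandpass(rec, lfp_mod.THETA)
        mid = slice(int(5 * FS), int(25 * FS))
        ratio = out[mid].std() / rec.samples[mid].std()
        assert 10 ** (-1 / 20) < ratio < 10 ** (1 / 20)  # within 1 dB

    def test_out_of_band_tone_attenuated(self):
        rec = tone(25.0, duration=30.0)
        out = lfp_mod.bandpass(rec, lfp_mod.THETA)
        mid = slice(int(5 * FS), int(25 * FS))
        atten = 20 * np.log10(out[mid].std() / rec.samples[mid].std())
        assert atten < -40

    def test_zero_phase(self):
        rec = tone(8.0, duration=30.0)
        out = lfp_mod.bandpass(rec, lfp_mod.THETA)
        mid = slice(int(5 * FS), int(25 * FS))
        x = rec.samples[mid] - rec.samples[mid].mean()
        y = out[mid] - out[mid].mean()
        lags = np.arange(-20, 21)
        xc = [np.dot(x, np.roll(y, l)) for l in lags]
        assert lags[int(np.argmax(xc))] == 0

    def test_infeasible_band_rejected(self):
        # nyquist 103 Hz < medium-gamma upper stop edge 104 Hz
        rec = LFPRecording(np.zeros(1000) + np.arange(1000) % 7, fs=206)
        with pytest.raises(ValidationError):
            lfp_mod.bandpass(rec, lfp_mod.MEDIUM_GAMMA)

    def test_trough_maps_to_phase_zero(self):
        rec = tone(8.0, duration=30.0)
        filt = lfp_mod.bandpass(rec, lfp_mod.THETA)
        phase, amp = lfp_mod.instantaneous_phase_amplitude(filt)
        mid = slice(int(5 * FS), int(25 * FS))
        troughs = np.where((filt[mid] < np.roll(filt[mid], 1))
                           & (filt[mid] < np.roll(filt[mid], -1)))[0][1:-1]
        ph = phase[mid][troughs]
        dist = np.abs(np.angle(np.exp(1j * ph)))
        assert np.max(dist) < 0.05
        peaks = np.where((filt[mid] > np.roll(filt[mid], 1))
                         & (filt[mid] > np.roll(filt[mid], -1)))[0][1:-1]
        dist_pk = np.abs(np.angle(np.exp(1j * (phase[mid][peaks] - np.pi))))
        assert np.max(dist_pk) < 0.05

    def test_constant_amplitude_tone(self):
        rec = tone(8.0, duration=30.0)
        _, amp = lfp_mod.instantaneous_phase_amplitude(
            lfp_mod.bandpass(rec, lfp_mod.THETA))
        mid = amp[int(5 * FS):int(25 * FS)]
        assert mid.std() / mid.mean() < 0.01


class TestStrongOscillationMask:
    def test_constant_power_empty(self):
        amp = np.ones(int(100 * FS))
        mask, _ = lfp_mod.strong_oscillation_mask(amp, FS)
        assert not mask.any()

    def test_single_burst_caught(self):
        amp = np.ones(int(100 * FS))
        b0 = int(40 * FS)
        amp[b0:b0 + int(0.5 * FS)] = 10.0
        mask, _ = lfp_mod.strong_oscillation_mask(amp, FS)
        assert mask.sum() == 1
        assert mask[80]

    def test_gaussian_powers_tail_fraction(self, rng):
        n_bins = 100_000
        powers = rng.normal(10.0, 1.0, n_bins)
        amp = np.repeat(np.sqrt(powers), 10)
        mask, _ = lfp_mod.strong_oscillation_mask(amp, fs=20.0)
        assert mask.mean() == pytest.approx(0.0228, abs=0.005)


class TestPhaseLockingMVL:
    def run(self, phases):
        phases = np.asarray(phases, float)
        fs = 1000.0
        phase_series = np.tile(phases, 100)
        spike_times = (np.arange(phase_series.size) / fs)[:phases.size]
        mask = np.ones(1000, dtype=bool)
        return lfp_mod.phase_locking(spike_times, phase_series, fs, mask,
                                     min_spikes=1)

    def test_identical_phases_mvl_one(self):
        res = self.run(np.full(50, 1.0))
        assert res.mvl == pytest.approx(1.0)

    def test_uniform_grid_mvl_zero(self):
        res = self.run(2 * np.pi * np.arange(16) / 16)
        assert res.mvl == pytest.approx(0.0, abs=1e-12)

    def test_two_phases_quarter_turn(self):
        res = self.run([0.0, np.pi / 2])
        assert res.mvl == pytest.approx(np.sqrt(2) / 2)
        assert res.preferred_phase == pytest.approx(np.pi / 4)

    def test_insufficient_flagged(self):
        res = self.run(np.full(5, 1.0))
        assert res.mvl == pytest.approx(1.0)
        fs = 1000.0
        res2 = lfp_mod.phase_locking(np.arange(5) / fs, np.full(5000, 1.0),
                                     fs, np.ones(10, bool), min_spikes=30)
        assert not res2.sufficient


class TestPhaseLockedFraction:
    def make(self, p):
        return lfp_mod.PhaseLockingResult("theta", 0.1, 0.0, 100, p, True)

    def test_all_significant(self):
        assert lfp_mod.phase_locked_fraction([self.make(0.01)] * 5) == 1.0

    def test_none_significant(self):
        assert lfp_mod.phase_locked_fraction([self.make(0.5)] * 5) == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            lfp_mod.phase_locked_fraction([])
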