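"""Spectral power estimation and spike-LFP phase locking.

Analysis bands are theta 6-12 Hz, slow gamma 30-45 Hz and medium gamma
55-100 Hz; phase extraction uses wider filter passbands (4-14, 28-47,
58-102 Hz) with stop bands 2 Hz beyond each passband edge. Phase is the
Hilbert analytic-signal angle shifted by pi so that the oscillation trough
maps to 0/360 degrees. Session power comes from a DPSS multitaper spectrogram
(20-s windows, 10-s steps) restricted to post-immobility activity epochs;
per-epoch power uses Welch periodograms (50% overlapping Hamming windows) on
500-ms bins.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .behaviour import SpeedSeries
from .circstats import circ_mean, circ_r, rayleigh_test
from .core import LFPRecording, ValidationError

logger = logging.getLogger("placecode")


@dataclass(frozen=True)
class BandDefinition:
    name: str
    pass_lo: float  # analysis band (power integration) low edge, Hz
    pass_hi: float
    filter_lo: float  # phase-extraction filter passband, Hz
    filter_hi: float

    def __post_init__(self) -> None:
        if not self.pass_lo < self.pass_hi:
            raise ValidationError("pass_lo must be < pass_hi")
        if not self.filter_lo < self.filter_hi:
            raise ValidationError("filter_lo must be < filter_hi")
        if self.filter_hi <= self.pass_lo or self.filter_lo >= self.pass_hi:
            raise ValidationError("filter band must overlap the analysis band")
        # the conventional medium-gamma filter passband (58-102 Hz) clips the
        # bottom 3 Hz of its analysis band; containment is therefore not enforced


THETA = BandDefinition("theta", 6.0, 12.0, 4.0, 14.0)
SLOW_GAMMA = BandDefinition("slow_gamma", 30.0, 45.0, 28.0, 47.0)
MEDIUM_GAMMA = BandDefinition("medium_gamma", 55.0, 100.0, 58.0, 102.0)
BANDS = (THETA, SLOW_GAMMA, MEDIUM_GAMMA)


@dataclass
class PhaseLockingResult:
    band: str
    mvl: float
    preferred_phase: float  # radians, trough = 0
    n_spikes: int
    rayleigh_p: float
    sufficient: bool


def zscore_lfp(lfp: LFPRecording) -> np.ndarray:
    """Standardise the trace to mean 0, sd 1; degenerate (constant) input raises."""
    sd = np.std(lfp.samples)
    if sd == 0:
        raise ValidationError("constant LFP signal cannot be z-scored")
    return (lfp.samples - np.mean(lfp.samples)) / sd


def _multitaper_psd(x: np.ndarray, fs: float, tw: float = 3.0, k: int = 5):
    """Average of K DPSS-tapered periodograms (time-bandwidth product TW)."""
    n = x.size
    tapers = signal.windows.dpss(n, tw, Kmax=k)
    spectra = np.abs(np.fft.rfft(tapers * x[None, :], axis=1)) ** 2
    psd = spectra.mean(axis=0) / fs
    psd[1:-1] *= 2.0  # one-sided
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    return freqs, psd


def session_band_power(lfp: LFPRecording,
                       epochs: list[tuple[float, float]],
                       window_s: float = 20.0, step_s: float = 10.0,
                       tw: float = 3.0, k: int = 5,
                       bands: tuple[BandDefinition, ...] = BANDS) -> dict[str, float]:
    """Mean multitaper spectrogram power per analysis band.

    The z-scored trace is restricted to the supplied post-immobility activity
    epochs, which are concatenated before windowing (windows are longer than
    single epochs); window positions falling across a join are retained, as the
    concatenated signal is treated as one record.
    """
    z = zscore_lfp(lfp)
    pieces = []
    for start, end in epochs:
        i0 = int(round(start * lfp.fs))
        i1 = int(round(end * lfp.fs))
        pieces.append(z[max(i0, 0):min(i1, z.size)])
    if not pieces:
        raise ValidationError("no activity epochs supplied")
    x = np.concatenate(pieces)
    win = int(round(window_s * lfp.fs))
    step = int(round(step_s * lfp.fs))
    if x.size < win:
        raise ValidationError(
            f"total epoch time {x.size / lfp.fs:.1f} s < window {window_s} s"
        )
    starts = range(0, x.size - win + 1, step)
    acc = {b.name: 0.0 for b in bands}
    n_win = 0
    for s in starts:
        freqs, psd = _multitaper_psd(x[s:s + win], lfp.fs, tw, k)
        for b in bands:
            sel = (freqs >= b.pass_lo) & (freqs <= b.pass_hi)
            acc[b.name] += float(psd[sel].mean())
        n_win += 1
    return {name: val / n_win for name, val in acc.items()}


def binned_band_power(lfp: LFPRecording, epoch_s: float = 0.5,
                      bands: tuple[BandDefinition, ...] = BANDS,
                      nperseg: int | None = None) -> dict[str, np.ndarray]:
    """Welch band power (PSD integral) per 500-ms epoch for each band."""
    z = zscore_lfp(lfp)
    n_epoch = int(round(epoch_s * lfp.fs))
    n_bins = z.size // n_epoch
    if n_bins == 0:
        raise ValidationError("recording shorter than one epoch")
    if nperseg is None:
        nperseg = n_epoch // 2
    segs = z[:n_bins * n_epoch].reshape(n_bins, n_epoch)
    freqs, psd = signal.welch(segs, fs=lfp.fs, window="hamming",
                              nperseg=nperseg, noverlap=nperseg // 2, axis=1)
    out = {}
    for b in bands:
        out[b.name] = _band_integral(freqs, psd, b.pass_lo, b.pass_hi)
    return out


def _band_integral(freqs: np.ndarray, psd: np.ndarray, lo: float,
                   hi: float) -> np.ndarray:
    """Trapezoidal PSD integral over [lo, hi] with the PSD linearly
    interpolated at the exact band edges (rows of ``psd`` are epochs)."""
    inner = (freqs > lo) & (freqs < hi)
    grid = np.concatenate([[lo], freqs[inner], [hi]])
    lo_col = np.array([np.interp(lo, freqs, row) for row in psd])
    hi_col = np.array([np.interp(hi, freqs, row) for row in psd])
    vals = np.column_stack([lo_col, psd[:, inner], hi_col])
    return np.trapezoid(vals, grid, axis=1)


def velocity_stratified_power(band_powers: dict[str, np.ndarray],
                              speed: SpeedSeries, speed_bin: float = 3.0,
                              max_speed: float = 45.0, min_epochs: int = 5):
    """Mean per-epoch band power stratified by running-speed bin.

    Returns (bin_left_edges, {band: mean power per bin}, counts); bins with
    fewer than ``min_epochs`` defined epochs hold NaN.
    """
    edges = np.arange(0.0, max_speed + speed_bin, speed_bin)
    n_bins = len(edges) - 1
    first = next(iter(band_powers.values()))
    n = min(len(speed), first.size)
    sp = speed.speed[:n]
    defined = np.isfinite(sp)
    idx = np.full(n, -1)
    idx[defined] = np.clip((sp[defined] // speed_bin).astype(int), 0, n_bins - 1)
    counts = np.bincount(idx[idx >= 0], minlength=n_bins)
    curves = {}
    for name, power in band_powers.items():
        sums = np.bincount(idx[idx >= 0], weights=power[:n][idx >= 0],
                           minlength=n_bins)
        with np.errstate(invalid="ignore", divide="ignore"):
            mean = sums / counts
        mean[counts < min_epochs] = np.nan
        curves[name] = mean
    return edges[:-1], curves, counts


def bandpass(lfp: LFPRecording, band: BandDefinition,
             stopband_atten_db: float = 40.0) -> np.ndarray:
    """Zero-phase FIR band-pass to the band's filter passband.

    Stop-band edges sit 2 Hz outside the passband; the Kaiser design meets
    >= 40 dB stop-band attenuation with <= 1 dB passband ripple, and the
    linear-phase kernel is applied centred, so the net phase response is zero
    (essential for phase-locking estimates).
    """
    nyq = lfp.fs / 2.0
    stop_lo = band.filter_lo - 2.0
    stop_hi = band.filter_hi + 2.0
    if stop_lo <= 0 or stop_hi >= nyq:
        raise ValidationError(
            f"band {band.name} ({stop_lo}-{stop_hi} Hz stop edges) "
            f"infeasible at fs={lfp.fs}"
        )
    width = 2.0 / nyq * np.pi
    numtaps, beta = signal.kaiserord(stopband_atten_db, 2.0 / nyq)
    numtaps |= 1  # odd length for a type-I linear-phase FIR
    if lfp.samples.size <= 3 * numtaps:
        raise ValidationError(
            f"signal too short ({lfp.samples.size} samples) for a "
            f"{numtaps}-tap filter"
        )
    taps = signal.firwin(numtaps, [band.filter_lo - 1.0, band.filter_hi + 1.0],
                         window=("kaiser", beta), pass_zero=False, fs=lfp.fs)
    # symmetric odd-length FIR applied centred => exactly zero phase
    return signal.fftconvolve(lfp.samples, taps, mode="same")


def instantaneous_phase_amplitude(filtered: np.ndarray):
    """Phase (trough = 0, in [0, 2pi)) and amplitude of the analytic signal.

    The Hilbert analytic signal assigns phase 0 to the oscillation peak; a
    pi shift re-references phase 0 to the trough.
    """
    analytic = signal.hilbert(filtered)
    phase = np.mod(np.angle(analytic) + np.pi, 2 * np.pi)
    return phase, np.abs(analytic)


def strong_oscillation_mask(amplitude: np.ndarray, fs: float,
                            epoch_s: float = 0.5, n_sd: float = 2.0):
    """Epochs whose band power exceeds mean + 2 SD of the session distribution.

    Power per 500-ms epoch is the mean squared instantaneous amplitude.
    Returns (mask, epoch_power).
    """
    n_epoch = int(round(epoch_s * fs))
    n_bins = amplitude.size // n_epoch
    if n_bins == 0:
        raise ValidationError("recording shorter than one epoch")
    power = (amplitude[:n_bins * n_epoch].reshape(n_bins, n_epoch) ** 2).mean(axis=1)
    thr = power.mean() + n_sd * power.std()
    return power > thr, power


def phase_locking(spike_times: np.ndarray, phase: np.ndarray, fs: float,
                  strong_mask: np.ndarray, band_name: str = "",
                  epoch_s: float = 0.5,
                  min_spikes: int = 30) -> PhaseLockingResult:
    """Mean resultant vector of spike phases during strong-oscillation epochs.

    mvl = |sum_j exp(i theta_j) / N|; preferred phase = arg of the resultant
    (trough = 0 convention inherited from the phase series). Results with
    fewer than ``min_spikes`` contributing spikes are flagged insufficient.
    """
    spike_times = np.asarray(spike_times, dtype=float)
    idx = np.clip((spike_times * fs).astype(int), 0, phase.size - 1)
    epoch_idx = (spike_times / epoch_s).astype(int)
    in_strong = (epoch_idx >= 0) & (epoch_idx < strong_mask.size)
    keep = np.zeros(spike_times.size, dtype=bool)
    keep[in_strong] = strong_mask[epoch_idx[in_strong]]
    theta = phase[idx[keep]]
    n = theta.size
    if n == 0:
        return PhaseLockingResult(band_name, float("nan"), float("nan"), 0,
                                  float("nan"), False)
    mvl = float(circ_r(theta))
    pref = float(circ_mean(theta))
    p = rayleigh_test(theta)[0] if n >= 3 else float("nan")
    return PhaseLockingResult(band_name, mvl, pref, n, p, n >= min_spikes)


def phase_locked_fraction(results: list[PhaseLockingResult],
                          alpha: float = 0.05) -> float:
    """Fraction of sufficiently-sampled cells with Rayleigh p < alpha."""
    ok = [r for r in results if r.sufficient]
    if not ok:
        raise ValidationError("no cells with sufficient spikes")
    return sum(r.rayleigh_p < alpha for r in ok) / len(ok)
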