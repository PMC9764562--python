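"""Synthetic 6-session experiments with the statistical structure the pipeline assumes.

Foraging is an Ornstein-Uhlenbeck velocity random walk reflected at the wall of
a 62-cm cylinder, sampled at 50 Hz. Place cells are inhomogeneous Poisson
processes (1-ms thinning) with Gaussian spatial tuning, optional doublet-burst
injection and optional von-Mises theta-phase modulation. The LFP is a sum of
band-limited oscillations (8, 38 and 75 Hz carriers with slow frequency
jitter, avoiding the 48-52 Hz notch region) over 1/f-like background noise,
sampled at 4.8 kHz. Across-day effect structure (rate/tuning-width multipliers,
theta-phase shift, partial remapping) is injected per genotype so the
downstream pipeline's effect estimates can be checked against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator

import numpy as np
from scipy.special import i0

from .core import (
    LFPRecording,
    SessionDataset,
    SessionSchedule,
    SpikeTrain,
    Trajectory,
    ValidationError,
)
from .lfp import THETA, BandDefinition, bandpass, instantaneous_phase_amplitude


@dataclass(frozen=True)
class SpeedParams:
    """OU foraging-speed parameters; defaults emulate adult-rat foraging."""

    mean_speed_cm_s: float = 10.0
    tau_s: float = 1.0
    pause_rate_hz: float = 0.0  # rate of entering a pause (per second)
    pause_mean_s: float = 2.0


@dataclass(frozen=True)
class CellSpec:
    """Ground-truth tuning of one simulated place cell."""

    field_center: tuple[float, float]
    field_sigma: float  # cm
    peak_rate: float  # Hz
    baseline_rate: float = 0.05
    burst_doublet_prob: float = 0.15
    phase_kappa_by_band: dict[str, float] = field(default_factory=dict)
    preferred_phase_by_band: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.peak_rate > self.baseline_rate >= 0:
            raise ValidationError("need peak_rate > baseline_rate >= 0")
        if self.field_sigma <= 0:
            raise ValidationError("field_sigma must be > 0")
        if any(k < 0 for k in self.phase_kappa_by_band.values()):
            raise ValidationError("kappa must be >= 0")


@dataclass(frozen=True)
class EffectSpec:
    """Across-day change injected on day 2 (identity = no change)."""

    genotype: str
    rate_multiplier_day2: float = 1.0
    sigma_multiplier_day2: float = 1.0
    theta_phase_shift_day2: float = 0.0  # radians
    remap_fraction_day2: float = 0.0  # fraction of cells redrawing their field

    def __post_init__(self) -> None:
        if self.rate_multiplier_day2 <= 0 or self.sigma_multiplier_day2 <= 0:
            raise ValidationError("multipliers must be > 0")
        if not 0 <= self.remap_fraction_day2 <= 1:
            raise ValidationError("remap fraction must be in [0, 1]")


def simulate_trajectory(duration: float, fs: float = 50.0,
                        arena_radius: float = 31.0,
                        speed_params: SpeedParams = SpeedParams(),
                        seed: int | np.random.Generator = 0) -> Trajectory:
    """Reflected Ornstein-Uhlenbeck foraging path confined to the arena disc.

    Each velocity component follows an OU process whose stationary speed
    distribution is Rayleigh with the requested mean; wall collisions reflect
    the velocity about the wall normal. With ``pause_rate_hz`` > 0 a two-state
    Markov chain inserts immobility bouts of mean ``pause_mean_s``.
    """
    if duration <= 0:
        raise ValidationError("duration must be > 0")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    dt = 1.0 / fs
    n = int(round(duration * fs))
    sp = speed_params
    sigma_v = sp.mean_speed_cm_s / np.sqrt(np.pi / 2.0)
    x = np.empty(n); y = np.empty(n)
    px = py = 0.0
    vx = rng.normal(0, sigma_v) if sigma_v > 0 else 0.0
    vy = rng.normal(0, sigma_v) if sigma_v > 0 else 0.0
    noise_scale = sigma_v * np.sqrt(2 * dt / sp.tau_s)
    decay = 1.0 - dt / sp.tau_s
    paused = False
    p_enter = sp.pause_rate_hz * dt
    p_exit = dt / sp.pause_mean_s if sp.pause_mean_s > 0 else 1.0
    eps = rng.normal(size=(n, 2))
    u = rng.random(n)
    for i in range(n):
        if sp.pause_rate_hz > 0:
            if paused:
                if u[i] < p_exit:
                    paused = False
            elif u[i] < p_enter:
                paused = True
        if not paused and sigma_v > 0:
            vx = vx * decay + noise_scale * eps[i, 0]
            vy = vy * decay + noise_scale * eps[i, 1]
            px += vx * dt
            py += vy * dt
            r = np.hypot(px, py)
            if r > arena_radius:
                nx, ny = px / r, py / r
                # reflect position and velocity about the wall tangent
                over = r - arena_radius
                px -= 2 * over * nx
                py -= 2 * over * ny
                vdotn = vx * nx + vy * ny
                vx -= 2 * vdotn * nx
                vy -= 2 * vdotn * ny
        x[i] = px
        y[i] = py
    return Trajectory(timestamps=np.arange(n) * dt, x=x, y=y,
                      arena_radius=arena_radius)


def _rate_on_grid(traj: Trajectory, spec: CellSpec, dt_ms: float = 1.0):
    """Tuning-curve rate lambda(t) interpolated onto a 1-ms grid."""
    d2 = (traj.x - spec.field_center[0]) ** 2 + (traj.y - spec.field_center[1]) ** 2
    rate_samp = spec.baseline_rate + (spec.peak_rate - spec.baseline_rate) * np.exp(
        -d2 / (2.0 * spec.field_sigma**2)
    )
    t_fine = np.arange(traj.timestamps[0], traj.timestamps[-1], dt_ms / 1000.0)
    return t_fine, np.interp(t_fine, traj.timestamps, rate_samp)


def simulate_place_cell(traj: Trajectory, spec: CellSpec,
                        seed: int | np.random.Generator = 0,
                        cluster_id: str = "cell",
                        theta_phase: np.ndarray | None = None,
                        theta_fs: float | None = None,
                        feature_centre: np.ndarray | None = None,
                        feature_dim: int = 8,
                        feature_sd: float = 1.0,
                        waveform_width_us: float = 320.0) -> SpikeTrain:
    """Inhomogeneous-Poisson place-cell spikes by 1-ms thinning.

    ``theta_phase`` (at ``theta_fs``) optionally multiplies the spatial rate by
    a mean-one von-Mises factor exp(kappa cos(phi - mu)) / I0(kappa), yielding
    theta phase locking with the concentration given in
    ``spec.phase_kappa_by_band['theta']``. Doublets at 4-8 ms ISI are injected
    per spike with probability ``spec.burst_doublet_prob``. Per-spike features
    are drawn from an isotropic Gaussian around ``feature_centre``.
    """
    if len(traj) < 2:
        raise ValidationError("trajectory too short to simulate from")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    t_fine, lam = _rate_on_grid(traj, spec)
    kappa = spec.phase_kappa_by_band.get("theta", 0.0)
    if theta_phase is not None and kappa > 0:
        if theta_fs is None:
            raise ValidationError("theta_fs required with theta_phase")
        mu = spec.preferred_phase_by_band.get("theta", 0.0)
        idx = np.clip((t_fine * theta_fs).astype(int), 0, theta_phase.size - 1)
        lam = lam * np.exp(kappa * np.cos(theta_phase[idx] - mu)) / i0(kappa)
    dt = float(t_fine[1] - t_fine[0]) if t_fine.size > 1 else 1e-3
    spikes = t_fine[rng.random(t_fine.size) < lam * dt]
    if spec.burst_doublet_prob > 0 and spikes.size:
        extra = spikes[rng.random(spikes.size) < spec.burst_doublet_prob]
        doublets = extra + rng.uniform(0.004, 0.008, extra.size)
        spikes = np.sort(np.concatenate([spikes, doublets]))
    if feature_centre is None:
        feature_centre = np.zeros(feature_dim)
    features = rng.normal(feature_centre, feature_sd,
                          size=(spikes.size, len(feature_centre)))
    return SpikeTrain(cluster_id=cluster_id, spike_times=spikes,
                      features=features, mean_waveform_width=waveform_width_us)


def _one_over_f_noise(n: int, fs: float, rng: np.random.Generator,
                      sd: float = 1.0) -> np.ndarray:
    white = rng.normal(size=n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    scale = np.ones_like(freqs)
    nz = freqs > 1.0
    scale[nz] = 1.0 / np.sqrt(freqs[nz])
    noise = np.fft.irfft(spec * scale, n)
    s = noise.std()
    return noise / s * sd if s > 0 else noise


def _jittered_carrier(n: int, fs: float, f0: float, rng: np.random.Generator,
                      jitter_frac: float = 0.03, jitter_tau_s: float = 2.0) -> np.ndarray:
    """Unit-amplitude oscillation with slow OU jitter of instantaneous frequency."""
    from scipy.signal import lfilter

    dt = 1.0 / fs
    decay = 1.0 - dt / jitter_tau_s
    scale = np.sqrt(2 * dt / jitter_tau_s)
    ou = lfilter([scale], [1.0, -decay], rng.normal(size=n))
    f_inst = f0 * (1.0 + jitter_frac * ou)
    phase = 2 * np.pi * np.cumsum(f_inst) * dt
    return np.cos(phase)


def simulate_lfp(duration: float, fs: float = 4800.0,
                 theta_amp: float = 1.0, sgamma_amp: float = 0.4,
                 mgamma_amp: float = 0.25, noise_sd: float = 0.5,
                 speed_coupling: float = 0.0,
                 traj: Trajectory | None = None,
                 seed: int | np.random.Generator = 0,
                 session: SessionSchedule | None = None) -> LFPRecording:
    """Band-limited theta/gamma oscillations plus 1/f background noise.

    Carriers sit at 8, 38 and 75 Hz (clear of the 48-52 Hz notch region) with
    slow frequency jitter. With ``speed_coupling`` c > 0 and a trajectory,
    oscillation amplitudes scale as 1 + c * (speed / mean speed - 1).
    """
    if fs <= 204.0:
        raise ValidationError("fs too low for the 55-100 Hz band")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n = int(round(duration * fs))
    sig = np.zeros(n)
    mod = np.ones(n)
    if speed_coupling != 0.0:
        if traj is None:
            raise ValidationError("speed coupling requires a trajectory")
        dt_traj = traj.median_dt
        inst = np.hypot(np.gradient(traj.x, dt_traj), np.gradient(traj.y, dt_traj))
        t = np.arange(n) / fs
        sp = np.interp(t, traj.timestamps, inst)
        mean_sp = max(sp.mean(), 1e-9)
        mod = np.clip(1.0 + speed_coupling * (sp / mean_sp - 1.0), 0.0, None)
    for amp, f0 in ((theta_amp, 8.0), (sgamma_amp, 38.0), (mgamma_amp, 75.0)):
        if amp > 0:
            sig += amp * mod * _jittered_carrier(n, fs, f0, rng)
    if noise_sd > 0:
        sig += _one_over_f_noise(n, fs, rng, noise_sd)
    return LFPRecording(samples=sig, fs=fs, session=session)


def simulate_phase_locked_spikes(lfp: LFPRecording, band: BandDefinition,
                                 kappa: float, mu: float, n_spikes: int,
                                 seed: int | np.random.Generator = 0,
                                 cluster_id: str = "locked") -> SpikeTrain:
    """Spike times whose band phase follows von-Mises(mu, kappa).

    Rejection sampling against the band-filtered Hilbert phase of the supplied
    LFP, so generator and analyser share one phase convention (trough = 0).
    kappa = 0 yields phase-uniform spiking.
    """
    if kappa < 0:
        raise ValidationError("kappa must be >= 0")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    phase, _ = instantaneous_phase_amplitude(bandpass(lfp, band))
    accepted: list[np.ndarray] = []
    total = 0
    n_samples = phase.size
    while total < n_spikes:
        cand = rng.integers(0, n_samples, size=4 * n_spikes)
        acc_p = np.exp(kappa * (np.cos(phase[cand] - mu) - 1.0))
        keep = cand[rng.random(cand.size) < acc_p]
        accepted.append(keep)
        total += keep.size
    idx = np.concatenate(accepted)[:n_spikes]
    times = np.sort(idx / lfp.fs + rng.uniform(0, 1.0 / lfp.fs, n_spikes))
    return SpikeTrain(cluster_id=cluster_id, spike_times=times)


def draw_cell_specs(n_cells: int, rng: np.random.Generator,
                    arena_radius: float = 31.0,
                    theta_kappa_range: tuple[float, float] = (0.1, 0.5)) -> list[CellSpec]:
    """Random place-cell population: fields inside the arena, rates in the
    active-pyramidal range, modest theta locking (population MVL ~ 0-0.2)."""
    specs = []
    for _ in range(n_cells):
        r = arena_radius * 0.85 * np.sqrt(rng.random())
        ang = rng.uniform(0, 2 * np.pi)
        specs.append(CellSpec(
            field_center=(r * np.cos(ang), r * np.sin(ang)),
            field_sigma=rng.uniform(5.0, 12.0),
            peak_rate=rng.uniform(2.0, 8.0),
            baseline_rate=rng.uniform(0.02, 0.15),
            burst_doublet_prob=rng.uniform(0.05, 0.3),
            phase_kappa_by_band={"theta": rng.uniform(*theta_kappa_range)},
            preferred_phase_by_band={"theta": rng.uniform(0, 2 * np.pi)},
        ))
    return specs


def _disc_gaussian_mass(center: tuple[float, float], sigma: float,
                        radius: float, grid_cm: float = 1.0) -> float:
    """Integral of the unit-peak Gaussian tuning bump over the arena disc."""
    g = np.arange(-radius, radius + grid_cm, grid_cm)
    gx, gy = np.meshgrid(g, g, indexing="ij")
    inside = gx**2 + gy**2 <= radius**2
    d2 = (gx - center[0]) ** 2 + (gy - center[1]) ** 2
    return float(np.sum(np.exp(-d2[inside] / (2 * sigma**2))) * grid_cm**2)


def _apply_day2(spec: CellSpec, eff: EffectSpec,
                rng: np.random.Generator, arena_radius: float) -> CellSpec:
    center = spec.field_center
    if eff.remap_fraction_day2 > 0 and rng.random() < eff.remap_fraction_day2:
        r = arena_radius * 0.85 * np.sqrt(rng.random())
        ang = rng.uniform(0, 2 * np.pi)
        center = (r * np.cos(ang), r * np.sin(ang))
    phases = dict(spec.preferred_phase_by_band)
    if "theta" in phases:
        phases["theta"] = float(np.mod(phases["theta"] + eff.theta_phase_shift_day2,
                                       2 * np.pi))
    # the rate multiplier targets the session MEAN rate. The in-field
    # contribution to the mean scales with the tuning bump's mass inside the
    # arena (wall truncation included), so the gain is compensated by the mass
    # ratio to decouple the rate and tuning-width knobs.
    m = eff.rate_multiplier_day2
    s = eff.sigma_multiplier_day2
    new_sigma = spec.field_sigma * s
    new_baseline = spec.baseline_rate * m
    mass_old = _disc_gaussian_mass(spec.field_center, spec.field_sigma, arena_radius)
    mass_new = _disc_gaussian_mass(center, new_sigma, arena_radius)
    new_peak = new_baseline + (
        (spec.peak_rate - spec.baseline_rate) * m * mass_old / mass_new)
    return replace(
        spec,
        field_center=center,
        peak_rate=new_peak,
        baseline_rate=new_baseline,
        field_sigma=new_sigma,
        preferred_phase_by_band=phases,
    )


def simulate_experiment(
    effects: list[EffectSpec],
    n_animals_per_genotype: int = 7,
    cells_per_animal: int = 30,
    session_duration: float = 600.0,
    fs_position: float = 50.0,
    lfp_fs: float = 4800.0,
    include_lfp: bool = True,
    arena_radius: float = 31.0,
    speed_params: SpeedParams = SpeedParams(pause_rate_hz=0.05),
    seed: int = 0,
) -> tuple[Iterator[SessionDataset], dict]:
    """Lazy stream of the full 2-day x 3-session design for every animal.

    Defaults emulate the source study's scale: 7 animals per genotype,
    ~30 simultaneously recorded cells each, six 10-min sessions. Day-2
    sessions apply each genotype's :class:`EffectSpec` to the day-1 cell
    specs. Returns ``(iterator of SessionDataset, ground_truth)`` where the
    ground truth maps (genotype, animal, cell) to the injected CellSpec
    parameters per day. Deterministic given ``seed``.
    """
    master = np.random.default_rng(seed)
    truth: dict = {"effects": {e.genotype: e for e in effects}, "cells": {}}
    plan = []  # (genotype, animal_id, cell specs by day, per-animal seed)
    for eff in effects:
        for a in range(n_animals_per_genotype):
            animal_id = f"{eff.genotype}_rat{a + 1}"
            rng_a = np.random.default_rng(master.integers(2**31))
            day1 = draw_cell_specs(cells_per_animal, rng_a, arena_radius)
            day2 = [_apply_day2(s, eff, rng_a, arena_radius) for s in day1]
            feat_centres = rng_a.normal(0, 6.0, size=(cells_per_animal, 8))
            for c, (s1, s2) in enumerate(zip(day1, day2)):
                truth["cells"][(eff.genotype, animal_id, f"c{c + 1}")] = {
                    "day1": s1, "day2": s2}
            plan.append((eff.genotype, animal_id, (day1, day2), feat_centres,
                         master.integers(2**31)))

    def _generate() -> Iterator[SessionDataset]:
        for genotype, animal_id, specs_by_day, feat_centres, aseed in plan:
            rng = np.random.default_rng(aseed)
            for s_idx in range(1, 7):
                sched = SessionSchedule.from_index(s_idx)
                specs = specs_by_day[sched.day - 1]
                traj = simulate_trajectory(session_duration, fs_position,
                                           arena_radius, speed_params, rng)
                lfp_rec = None
                theta_phase = None
                if include_lfp:
                    lfp_rec = simulate_lfp(session_duration, lfp_fs,
                                           speed_coupling=0.5, traj=traj,
                                           seed=rng, session=sched)
                    theta_phase, _ = instantaneous_phase_amplitude(
                        bandpass(lfp_rec, THETA))
                trains = []
                for c, spec in enumerate(specs):
                    trains.append(simulate_place_cell(
                        traj, spec, seed=rng, cluster_id=f"c{c + 1}",
                        theta_phase=theta_phase, theta_fs=lfp_fs,
                        feature_centre=feat_centres[c],
                    ))
                    trains[-1].genotype_label = genotype
                    trains[-1].session = sched
                yield SessionDataset(trajectory=traj, spike_trains=trains,
                                     lfp=lfp_rec, animal_id=animal_id,
                                     genotype=genotype, session=sched)

    return _generate(), truth
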