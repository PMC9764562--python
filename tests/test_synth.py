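import numpy as np
import pytest
from scipy import stats
from scipy.special import i0, i1

from placecode import behaviour as bhv
from placecode import lfp as lfp_mod
from placecode import maps
from placecode import units
from placecode.circstats import circ_dist, circ_mean, circ_r
from placecode.core import ValidationError
from placecode.synth import (
    CellSpec,
    EffectSpec,
    SpeedParams,
    simulate_experiment,
    simulate_lfp,
    simulate_phase_locked_spikes,
    simulate_place_cell,
    simulate_trajectory,
)


class TestTrajectory:
    def test_sample_count_and_confinement(self):
        traj = simulate_trajectory(600.0, fs=50.0, seed=0)
        assert len(traj) == 30_000
        assert np.all(np.hypot(traj.x, traj.y) <= 31.0 + 1e-9)

    def test_zero_speed_stays_put(self):
        traj = simulate_trajectory(60.0, seed=0,
                                   speed_params=SpeedParams(mean_speed_cm_s=0.0))
        assert bhv.path_length(traj) == 0.0

    def test_mean_speed_contract(self):
        traj = simulate_trajectory(600.0, seed=42,
                                   speed_params=SpeedParams(mean_speed_cm_s=10.0))
        mean_speed = bhv.path_length(traj) / traj.duration
        assert mean_speed == pytest.approx(10.0, rel=0.10)

    def test_deterministic_under_seed(self):
        a = simulate_trajectory(30.0, seed=7)
        b = simulate_trajectory(30.0, seed=7)
        np.testing.assert_array_equal(a.x, b.x)

    def test_coverage_contract(self):
        traj = simulate_trajectory(600.0, seed=3,
                                   speed_params=SpeedParams(pause_rate_hz=0.05))
        assert bhv.coverage(traj) > 93.0


class TestPlaceCell:
    def test_homogeneous_poisson_count(self):
        """peak = baseline -> homogeneous Poisson; count in the 99% band."""
        traj = simulate_trajectory(1000.0, seed=1)
        spec = CellSpec(field_center=(0, 0), field_sigma=10.0,
                        peak_rate=1.0 + 1e-9, baseline_rate=1.0,
                        burst_doublet_prob=0.0)
        train = simulate_place_cell(traj, spec, seed=2)
        lo, hi = stats.poisson.ppf([0.005, 0.995], 1000)
        assert lo <= len(train) <= hi

    def test_rate_map_peak_recovers_field_center(self):
        traj = simulate_trajectory(600.0, seed=5)
        spec = CellSpec(field_center=(8.0, -5.0), field_sigma=8.0,
                        peak_rate=10.0, baseline_rate=0.1,
                        burst_doublet_prob=0.0)
        train = simulate_place_cell(traj, spec, seed=6)
        rmap = maps.rate_map(traj, train)
        ij = np.unravel_index(np.nanargmax(
            np.where(rmap.valid_mask, rmap.smoothed_rate, -np.inf)),
            rmap.smoothed_rate.shape)
        cx = rmap.bin_centres[ij[0]]
        cy = rmap.bin_centres[ij[1]]
        assert abs(cx - 8.0) <= 2.5
        assert abs(cy - (-5.0)) <= 2.5

    def test_no_doublets_low_burst_probability(self):
        traj = simulate_trajectory(600.0, seed=8)
        spec = CellSpec(field_center=(0, 0), field_sigma=10.0,
                        peak_rate=1.5, baseline_rate=0.5,
                        burst_doublet_prob=0.0)
        train = simulate_place_cell(traj, spec, seed=9)
        bp = units.burst_probability(train).burst_probability
        assert bp < 0.02

    def test_empty_trajectory_rejected(self):
        with pytest.raises(ValidationError):
            Trajectory = type("T", (), {})  # noqa: N806 - sentinel
            simulate_place_cell(
                simulate_trajectory(0.02, seed=0),
                CellSpec((0, 0), 5.0, 5.0), seed=0)


class TestLFP:
    def test_pure_theta_tone_band_power(self):
        rec = simulate_lfp(60.0, fs=1200.0, theta_amp=1.0, sgamma_amp=0.0,
                           mgamma_amp=0.0, noise_sd=0.0, seed=0)
        power = lfp_mod.binned_band_power(rec)
        total = sum(p.mean() for p in power.values())
        assert power["theta"].mean() / total >= 0.95

    def test_white_noise_band_powers_proportional_to_bandwidth(self, rng):
        from placecode.core import LFPRecording
        rec = LFPRecording(rng.normal(size=int(300 * 1200)), fs=1200.0)
        power = lfp_mod.binned_band_power(rec)
        means = {k: v.mean() for k, v in power.items()}
        widths = {"theta": 6.0, "slow_gamma": 15.0, "medium_gamma": 45.0}
        for a, b in [("theta", "slow_gamma"), ("slow_gamma", "medium_gamma")]:
            assert means[a] / means[b] == pytest.approx(
                widths[a] / widths[b], rel=0.10)

    def test_zero_amplitude_degenerate_downstream(self):
        rec = simulate_lfp(10.0, fs=1200.0, theta_amp=0.0, sgamma_amp=0.0,
                           mgamma_amp=0.0, noise_sd=0.0, seed=0)
        with pytest.raises(ValidationError):
            lfp_mod.zscore_lfp(rec)

    def test_fs_too_low_rejected(self):
        with pytest.raises(ValidationError):
            simulate_lfp(10.0, fs=150.0, seed=0)


@pytest.fixture(scope="module")
def theta_lfp():
    return simulate_lfp(120.0, fs=1200.0, theta_amp=1.0, sgamma_amp=0.1,
                        mgamma_amp=0.05, noise_sd=0.2, seed=10)


class TestPhaseLockedSpikes:

    @staticmethod
    def spike_phases(lfp_rec, train):
        phase, _ = lfp_mod.instantaneous_phase_amplitude(
            lfp_mod.bandpass(lfp_rec, lfp_mod.THETA))
        idx = np.clip((train.spike_times * lfp_rec.fs).astype(int),
                      0, phase.size - 1)
        return phase[idx]

    def test_kappa_zero_uniform(self, theta_lfp):
        train = simulate_phase_locked_spikes(theta_lfp, lfp_mod.THETA,
                                             kappa=0.0, mu=1.0,
                                             n_spikes=1000, seed=1)
        mvl = circ_r(self.spike_phases(theta_lfp, train))
        assert mvl < 2 / np.sqrt(1000) * 1.5

    def test_large_kappa_high_mvl(self, theta_lfp):
        train = simulate_phase_locked_spikes(theta_lfp, lfp_mod.THETA,
                                             kappa=50.0, mu=np.pi,
                                             n_spikes=1000, seed=2)
        assert circ_r(self.spike_phases(theta_lfp, train)) > 0.95

    def test_preferred_phase_recovery(self, theta_lfp):
        mu = 2.2
        train = simulate_phase_locked_spikes(theta_lfp, lfp_mod.THETA,
                                             kappa=4.0, mu=mu,
                                             n_spikes=2000, seed=3)
        est = circ_mean(self.spike_phases(theta_lfp, train))
        assert abs(circ_dist(est, mu)) < 0.1

    def test_negative_kappa_rejected(self, theta_lfp):
        with pytest.raises(ValidationError):
            simulate_phase_locked_spikes(theta_lfp, lfp_mod.THETA,
                                         kappa=-1.0, mu=0.0, n_spikes=10)


class TestExperiment:
    @staticmethod
    def day_means(effects, seed, n_animals=2, cells=10):
        from placecode.pipeline import run_experiment
        ds_iter, truth = simulate_experiment(
            effects, n_animals_per_genotype=n_animals, cells_per_animal=cells,
            session_duration=300.0, include_lfp=False, seed=seed)
        res = run_experiment(ds_iter, compute_lfp=False, compute_quality=False)
        act = res["cells"][res["cells"].is_active]
        return act.groupby("day")[["rate_hz", "si_bits_per_spike"]].mean()

    def test_identity_effects_null(self):
        m = self.day_means([EffectSpec("KO")], seed=21, n_animals=3, cells=15)
        ratio = m.loc[2, "rate_hz"] / m.loc[1, "rate_hz"]
        assert 0.9 < ratio < 1.1

    def test_determinism_under_seed(self):
        a, _ = simulate_experiment([EffectSpec("WT")], n_animals_per_genotype=1,
                                   cells_per_animal=3, session_duration=60.0,
                                   include_lfp=False, seed=5)
        b, _ = simulate_experiment([EffectSpec("WT")], n_animals_per_genotype=1,
                                   cells_per_animal=3, session_duration=60.0,
                                   include_lfp=False, seed=5)
        for ds_a, ds_b in zip(a, b):
            np.testing.assert_array_equal(ds_a.trajectory.x, ds_b.trajectory.x)
            for ta, tb in zip(ds_a.spike_trains, ds_b.spike_trains):
                np.testing.assert_array_equal(ta.spike_times, tb.spike_times)

    def test_ground_truth_records_day2_changes(self):
        _, truth = simulate_experiment(
            [EffectSpec("WT", rate_multiplier_day2=0.7,
                        sigma_multiplier_day2=0.7)],
            n_animals_per_genotype=1, cells_per_animal=4,
            session_duration=60.0, include_lfp=False, seed=2)
        for rec in truth["cells"].values():
            assert rec["day2"].field_sigma == pytest.approx(
                0.7 * rec["day1"].field_sigma)


def test_population_mvl_in_realistic_range(rng):
    """Default theta-locking concentrations give per-cell MVLs mostly below
    0.3, matching the 0-0.2 range typical of pyramidal-cell recordings."""
    from placecode.synth import draw_cell_specs
    from scipy.special import i0 as _i0, i1 as _i1
    specs = draw_cell_specs(200, rng)
    expected_mvl = np.array([_i1(s.phase_kappa_by_band["theta"])
                             / _i0(s.phase_kappa_by_band["theta"])
                             for s in specs])
    assert np.mean(expected_mvl < 0.3) > 0.95
    assert expected_mvl.mean() < 0.2


def test_mvl_asymptote_matches_bessel_ratio(rng):
    """von-Mises MVL converges to I1(kappa)/I0(kappa)."""
    for kappa in (1.0, 4.0):
        ang = rng.vonmises(0.3, kappa, 5000)
        assert circ_r(ang) == pytest.approx(i1(kappa) / i0(kappa), abs=0.02)
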