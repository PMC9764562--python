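import numpy as np
import pytest

from placecode import behaviour as bhv
from placecode import maps
from placecode.core import SpikeTrain, Trajectory, ValidationError

from conftest import four_bin_map


def uniform_scan_trajectory(dwell_s=0.2, bin_size=2.5, radius=31.0):
    centres, _, inside = bhv.arena_bin_centres(radius, bin_size)
    cx, cy = np.meshgrid(centres, centres, indexing="ij")
    n_rep = int(round(dwell_s / 0.02))
    px = np.repeat(cx[inside], n_rep)
    py = np.repeat(cy[inside], n_rep)
    t = np.arange(px.size) * 0.02
    return Trajectory(timestamps=t, x=px, y=py, arena_radius=radius)


class TestOccupancy:
    def test_dwell_counted(self, stationary_trajectory):
        occ, valid, _ = maps.occupancy_map(stationary_trajectory)
        assert occ.max() == pytest.approx(60.0, rel=1e-6)
        assert valid.sum() == 1

    def test_brief_dwell_unvisited(self):
        t = np.arange(4) * 0.02  # 4 samples x 20 ms = 80 ms < 100 ms
        traj = Trajectory(timestamps=t, x=np.zeros_like(t), y=np.zeros_like(t))
        _, valid, _ = maps.occupancy_map(traj)
        assert valid.sum() == 0

    def test_occupancy_conserves_time(self, line_trajectory):
        occ, _, _ = maps.occupancy_map(line_trajectory)
        assert occ.sum() == pytest.approx(60.0, rel=1e-6)


class TestRateMap:
    def test_stationary_identity(self, stationary_trajectory):
        """Rat still at p for T seconds, n spikes at p: lambda(p) = n/T
        (kernel numerator and denominator cancel)."""
        n, T = 30, 60.0
        spikes = SpikeTrain("c", np.linspace(1, T - 1, n))
        rmap = maps.rate_map(stationary_trajectory, spikes)
        assert np.nanmax(rmap.smoothed_rate) == pytest.approx(n / T, rel=1e-6)

    def test_smoothing_shrinks_peak(self, rng):
        traj = uniform_scan_trajectory()
        idx = rng.choice(len(traj), 200)
        spikes = SpikeTrain("c", np.sort(traj.timestamps[idx]))
        peak_small = np.nanmax(maps.rate_map(traj, spikes, h=2.5).smoothed_rate)
        peak_large = np.nanmax(maps.rate_map(traj, spikes, h=5.0).smoothed_rate)
        assert peak_large <= peak_small + 1e-12

    def test_denominator_matches_fine_quadrature(self, rng):
        """Riemann-sum occupancy density agrees with a 10x-oversampled
        quadrature of the same integral within 1%."""
        t = np.arange(0, 60, 0.02)
        x = 15 * np.sin(0.1 * t)
        y = 15 * np.cos(0.13 * t)
        traj = Trajectory(timestamps=t, x=x, y=y)
        dens = maps.kernel_occupancy_density(traj, h=2.5)
        t_f = np.arange(0, t[-1], 0.002)
        traj_f = Trajectory(timestamps=t_f, x=15 * np.sin(0.1 * t_f),
                            y=15 * np.cos(0.13 * t_f))
        dens_f = maps.kernel_occupancy_density(traj_f, h=2.5)
        sel = dens_f > 0.5  # bins with meaningful weight
        assert np.allclose(dens[sel], dens_f[sel], rtol=0.01)

    def test_spike_mass_conserved(self, rng):
        """sum over bins of rate * occupancy approximates the spike count."""
        traj = uniform_scan_trajectory()
        idx = rng.choice(len(traj), 500)
        spikes = SpikeTrain("c", np.sort(traj.timestamps[idx]))
        rmap = maps.rate_map(traj, spikes)
        mass = np.nansum(rmap.smoothed_rate[rmap.valid_mask]
                         * rmap.occupancy[rmap.valid_mask])
        assert mass == pytest.approx(500, rel=0.05)


class TestSpatialInformation:
    def test_uniform_firing_zero_bits(self):
        assert maps.spatial_information(four_bin_map([2, 2, 2, 2])) == pytest.approx(0.0)

    def test_single_bin_of_four_is_two_bits(self):
        assert maps.spatial_information(four_bin_map([4, 0, 0, 0])) == pytest.approx(2.0)

    def test_silent_cell_undefined(self):
        with pytest.raises(ValidationError):
            maps.spatial_information(four_bin_map([0, 0, 0, 0]))


class TestSparsity:
    def test_uniform_is_one(self):
        assert maps.sparsity(four_bin_map([3, 3, 3, 3])) == pytest.approx(1.0)

    def test_single_bin_of_four(self):
        assert maps.sparsity(four_bin_map([4, 0, 0, 0])) == pytest.approx(0.25)

    def test_bounded_by_one_on_random_maps(self, rng):
        for _ in range(200):
            rates = rng.exponential(2.0, 4)
            occ = rng.uniform(0.5, 2.0, 4)
            s = maps.sparsity(four_bin_map(rates, occ))
            assert 0 < s <= 1 + 1e-12


class TestPercentActiveBins:
    def test_fraction(self, stationary_trajectory):
        spikes = SpikeTrain("c", np.array([1.0, 2.0]))
        rmap = maps.rate_map(stationary_trajectory, spikes)
        assert maps.percent_active_bins(rmap) == pytest.approx(100.0)

    def test_no_spikes_zero(self, stationary_trajectory):
        rmap = maps.rate_map(stationary_trajectory, SpikeTrain("c", []))
        assert maps.percent_active_bins(rmap) == 0.0


def block_map(shape=(12, 12), block=None, rates=None):
    rate = np.zeros(shape)
    if block is not None:
        for (i, j), v in zip(block, rates):
            rate[i, j] = v
    occ = np.full(shape, 1.0)
    valid = np.ones(shape, dtype=bool)
    return maps.RateMap(bin_size=2.5, occupancy=occ, smoothed_rate=rate,
                        valid_mask=valid, spike_counts=(rate > 0).astype(float))


class TestPlaceFields:
    @staticmethod
    def square(rmap_rate, top, left, size, value):
        rmap_rate[top:top + size, left:left + size] = value

    def test_3x3_block_is_one_field(self):
        rate = np.zeros((12, 12))
        self.square(rate, 2, 2, 3, 5.0)
        rmap = maps.RateMap(2.5, np.ones((12, 12)), rate,
                            np.ones((12, 12), bool), (rate > 0).astype(float))
        fields = maps.detect_place_fields(rmap)
        assert len(fields) == 1
        assert fields[0].n_bins == 9
        assert fields[0].area_cm2 == pytest.approx(56.25)
        assert fields[0].is_main

    def test_8_bins_insufficient(self):
        rate = np.zeros((12, 12))
        rate[2:4, 2:6] = 5.0  # 2x4 = 8 bins
        rmap = maps.RateMap(2.5, np.ones((12, 12)), rate,
                            np.ones((12, 12), bool), (rate > 0).astype(float))
        assert maps.detect_place_fields(rmap) == []

    def test_main_field_contains_global_peak(self):
        rate = np.zeros((14, 14))
        self.square(rate, 1, 1, 3, 5.0)
        self.square(rate, 8, 8, 4, 6.0)  # larger block holds the peak
        rmap = maps.RateMap(2.5, np.ones((14, 14)), rate,
                            np.ones((14, 14), bool), (rate > 0).astype(float))
        fields = maps.detect_place_fields(rmap)
        assert len(fields) == 2
        main = [f for f in fields if f.is_main][0]
        assert main.n_bins == 16

    def test_scale_invariance(self, rng):
        rate = rng.exponential(1.0, (12, 12))
        rmap = maps.RateMap(2.5, np.ones((12, 12)), rate,
                            np.ones((12, 12), bool), (rate > 0).astype(float))
        f1 = maps.detect_place_fields(rmap)
        rmap2 = maps.RateMap(2.5, rmap.occupancy, 7.3 * rate,
                             rmap.valid_mask, rmap.spike_counts)
        f2 = maps.detect_place_fields(rmap2)
        assert len(f1) == len(f2)
        for a, b in zip(f1, f2):
            np.testing.assert_array_equal(a.bin_indices, b.bin_indices)


class TestStability:
    def make_map(self, rate):
        rate = np.asarray(rate, float)
        return maps.RateMap(2.5, np.ones_like(rate), rate,
                            np.ones_like(rate, dtype=bool))

    def test_self_correlation_is_one(self, rng):
        rate = rng.exponential(1.0, (5, 5))
        m = self.make_map(rate)
        out, reason = maps.map_stability(m, m, 1.0, 1.0)
        assert reason is None
        r, z = out
        assert r == pytest.approx(1.0)
        assert z == pytest.approx(np.arctanh(1 - 1e-7))

    def test_orthogonal_pair_near_zero(self):
        a = np.array([[1.0, 2.0, 3.0, 4.0]] * 4)
        b = np.array([[1.0, 2.0], [2.0, 1.0]]).repeat(2, 0).repeat(2, 1)
        out, _ = maps.map_stability(self.make_map(a), self.make_map(b), 1.0, 1.0,
                                    min_joint_bins=10)
        r, z = out
        assert abs(r) < 1e-12
        assert abs(z) < 1e-12

    def test_si_criterion_excludes(self, rng):
        rate = rng.exponential(1.0, (5, 5))
        m = self.make_map(rate)
        out, reason = maps.map_stability(m, m, 0.4, 1.0)
        assert out is None
        assert "SI" in reason

    def test_too_few_joint_bins_excluded(self, rng):
        rate = rng.exponential(1.0, (2, 2))
        m = self.make_map(rate)
        out, reason = maps.map_stability(m, m, 1.0, 1.0)
        assert out is None
        assert "bins" in reason
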