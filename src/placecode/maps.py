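"""Occupancy and firing-rate maps, spatial tuning metrics, field detection.

The rate map is a Gaussian-kernel density ratio evaluated at the centres of
2.5-cm bins: lambda(x) = sum_spikes g(|S_i - x| / h) / int_0^T g(|y(t) - x| / h) dt
with g(u) = exp(-u^2 / 2) and smoothing h = 2.5 cm. The denominator integral is
a Riemann sum over the 50-Hz position samples. Bins occupied for less than
100 ms are treated as unvisited and carry no rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .behaviour import SpeedSeries, arena_bin_centres, mask_times
from .core import SpikeTrain, Trajectory, ValidationError


@dataclass
class RateMap:
    """Binned occupancy plus kernel-smoothed rate over the arena grid."""

    bin_size: float
    occupancy: np.ndarray  # seconds per bin (raw, unsmoothed)
    smoothed_rate: np.ndarray  # Hz per bin; NaN where invalid
    valid_mask: np.ndarray  # occupancy >= min AND centre inside the arena
    spike_counts: np.ndarray | None = None  # raw spikes per bin (for % active)
    bin_centres: np.ndarray | None = field(default=None, repr=False)

    @property
    def occupancy_probability(self) -> np.ndarray:
        """P_i over valid bins (sums to 1); NaN elsewhere."""
        p = np.full_like(self.occupancy, np.nan, dtype=float)
        tot = self.occupancy[self.valid_mask].sum()
        if tot > 0:
            p[self.valid_mask] = self.occupancy[self.valid_mask] / tot
        return p

    @property
    def mean_rate(self) -> float:
        """Occupancy-weighted overall rate R = sum P_i R_i."""
        p = self.occupancy_probability[self.valid_mask]
        return float(np.sum(p * self.smoothed_rate[self.valid_mask]))


@dataclass
class PlaceField:
    bin_indices: np.ndarray  # (k, 2) grid indices
    area_cm2: float
    peak_rate: float
    is_main: bool

    @property
    def n_bins(self) -> int:
        return self.bin_indices.shape[0]


def _grid(traj_radius: float, bin_size: float):
    centres, _, inside = arena_bin_centres(traj_radius, bin_size)
    return centres, inside


def occupancy_map(traj: Trajectory, speed: SpeedSeries | None = None,
                  mask: np.ndarray | None = None, bin_size: float = 2.5,
                  min_occupancy: float = 0.1):
    """Seconds per bin from (optionally movement-masked) position samples.

    Returns (occupancy, valid, centres): bins below ``min_occupancy`` or with
    centres outside the arena are invalid.
    """
    centres, inside = _grid(traj.arena_radius, bin_size)
    half = bin_size * len(centres) / 2
    keep = np.ones(len(traj), dtype=bool)
    if mask is not None:
        if speed is None:
            raise ValidationError("mask projection requires the SpeedSeries")
        keep = mask_times(speed, mask, traj.timestamps)
    dt = traj.median_dt
    ix = np.clip(((traj.x[keep] + half) // bin_size).astype(int), 0, len(centres) - 1)
    iy = np.clip(((traj.y[keep] + half) // bin_size).astype(int), 0, len(centres) - 1)
    occ = np.zeros((len(centres), len(centres)))
    np.add.at(occ, (ix, iy), dt)
    valid = (occ >= min_occupancy) & inside
    return occ, valid, centres


def kernel_occupancy_density(traj: Trajectory, speed: SpeedSeries | None = None,
                             mask: np.ndarray | None = None,
                             bin_size: float = 2.5, h: float = 2.5) -> np.ndarray:
    """Denominator field int g(|y(t)-x|/h) dt at every bin centre.

    This depends only on the trajectory, so it is computed once per session
    and shared across all cells' rate maps.
    """
    centres, _ = _grid(traj.arena_radius, bin_size)
    keep = np.ones(len(traj), dtype=bool)
    if mask is not None:
        if speed is None:
            raise ValidationError("mask projection requires the SpeedSeries")
        keep = mask_times(speed, mask, traj.timestamps)
    dt = traj.median_dt
    px, py = traj.x[keep], traj.y[keep]
    # separable kernel: exp(-(dx^2+dy^2)/2h^2) = exp(-dx^2/2h^2) * exp(-dy^2/2h^2)
    gx = np.exp(-((px[:, None] - centres[None, :]) ** 2) / (2 * h * h))
    gy = np.exp(-((py[:, None] - centres[None, :]) ** 2) / (2 * h * h))
    return dt * np.einsum("ti,tj->ij", gx, gy)


def rate_map(traj: Trajectory, spikes: SpikeTrain,
             speed: SpeedSeries | None = None, mask: np.ndarray | None = None,
             bin_size: float = 2.5, h: float = 2.5, min_occupancy: float = 0.1,
             occupancy_density: np.ndarray | None = None) -> RateMap:
    """Gaussian-kernel firing-rate map of one cell on the session grid.

    Spike positions are the trajectory positions interpolated at spike times.
    ``occupancy_density`` may be precomputed via :func:`kernel_occupancy_density`
    (it is identical for every cell in a session).
    """
    occ, valid, centres = occupancy_map(traj, speed, mask, bin_size, min_occupancy)
    if occupancy_density is None:
        occupancy_density = kernel_occupancy_density(traj, speed, mask, bin_size, h)

    st = spikes.spike_times
    if mask is not None:
        st = st[mask_times(speed, mask, st)]
    sx = np.interp(st, traj.timestamps, traj.x)
    sy = np.interp(st, traj.timestamps, traj.y)

    if st.size:
        gx = np.exp(-((sx[:, None] - centres[None, :]) ** 2) / (2 * h * h))
        gy = np.exp(-((sy[:, None] - centres[None, :]) ** 2) / (2 * h * h))
        numer = np.einsum("ti,tj->ij", gx, gy)
    else:
        numer = np.zeros((len(centres), len(centres)))

    rate = np.full_like(numer, np.nan)
    ok = valid & (occupancy_density > 0)
    rate[ok] = numer[ok] / occupancy_density[ok]

    # raw spike counts per bin (for % active bins)
    half = bin_size * len(centres) / 2
    counts = np.zeros((len(centres), len(centres)))
    if st.size:
        ix = np.clip(((sx + half) // bin_size).astype(int), 0, len(centres) - 1)
        iy = np.clip(((sy + half) // bin_size).astype(int), 0, len(centres) - 1)
        np.add.at(counts, (ix, iy), 1)

    return RateMap(bin_size=bin_size, occupancy=occ, smoothed_rate=rate,
                   valid_mask=ok, spike_counts=counts, bin_centres=centres)


def spatial_information(rmap: RateMap) -> float:
    """Skaggs information, sum P_i (R_i/R) log2(R_i/R) bits/spike.

    Bins with zero rate contribute zero (x log x -> 0 limit). Undefined for a
    silent cell (R = 0).
    """
    p = rmap.occupancy_probability[rmap.valid_mask]
    r = rmap.smoothed_rate[rmap.valid_mask]
    R = np.sum(p * r)
    if not R > 0:
        raise ValidationError("spatial information undefined: overall rate is 0")
    ratio = r / R
    term = np.zeros_like(ratio)
    pos = ratio > 0
    term[pos] = p[pos] * ratio[pos] * np.log2(ratio[pos])
    return float(term.sum())


def sparsity(rmap: RateMap) -> float:
    """(sum P_i R_i)^2 / sum P_i R_i^2; 1 for uniform, small for compact firing."""
    p = rmap.occupancy_probability[rmap.valid_mask]
    r = rmap.smoothed_rate[rmap.valid_mask]
    denom = np.sum(p * r * r)
    if not denom > 0:
        raise ValidationError("sparsity undefined: all-zero rates")
    return float(np.sum(p * r) ** 2 / denom)


def percent_active_bins(rmap: RateMap) -> float:
    """Bins containing raw spikes over visited bins, as a percentage."""
    if rmap.spike_counts is None:
        raise ValidationError("rate map built without spike counts")
    visited = rmap.valid_mask
    if visited.sum() == 0:
        return 0.0
    active = (rmap.spike_counts > 0) & visited
    return 100.0 * active.sum() / visited.sum()


def detect_place_fields(rmap: RateMap, min_bins: int = 9,
                        threshold_frac: float = 0.2,
                        connectivity: int = 4) -> list[PlaceField]:
    """Connected supra-threshold regions of >= min_bins bins.

    Threshold is relative: rate > threshold_frac * map maximum. The main field
    is the component containing the global peak bin; contiguity is edge-sharing
    (4-connectivity) by default, corner-sharing optional.
    """
    rate = np.where(rmap.valid_mask, rmap.smoothed_rate, np.nan)
    if not np.any(np.isfinite(rate)) or np.nanmax(rate) <= 0:
        return []
    peak = np.nanmax(rate)
    supra = np.where(np.isfinite(rate), rate > threshold_frac * peak, False)
    structure = (ndimage.generate_binary_structure(2, 1) if connectivity == 4
                 else ndimage.generate_binary_structure(2, 2))
    labels, n = ndimage.label(supra, structure=structure)
    peak_idx = np.unravel_index(np.nanargmax(rate), rate.shape)
    fields = []
    for lab in range(1, n + 1):
        idx = np.argwhere(labels == lab)
        if idx.shape[0] < min_bins:
            continue
        fields.append(PlaceField(
            bin_indices=idx,
            area_cm2=idx.shape[0] * rmap.bin_size ** 2,
            peak_rate=float(np.nanmax(rate[labels == lab])),
            is_main=bool(labels[peak_idx] == lab),
        ))
    return fields


def main_field_size(rmap: RateMap, **kwargs) -> float:
    """Area (cm^2) of the main place field, NaN when no field qualifies."""
    fields = detect_place_fields(rmap, **kwargs)
    for f in fields:
        if f.is_main:
            return f.area_cm2
    return float("nan")


_R_CLIP = 1.0 - 1e-7


def map_stability(map_a: RateMap, map_b: RateMap, si_a: float, si_b: float,
                  si_threshold: float = 0.5, min_joint_bins: int = 10):
    """Fisher-z Pearson correlation between two sessions' rate maps.

    Computed over bins valid in both maps; the pair is excluded (returns
    ``(None, reason)``) when either session's spatial information fails the
    SI > 0.5 bits/spike inclusion criterion or fewer than ``min_joint_bins``
    joint bins exist. Otherwise returns ``((r, z), None)`` with z = atanh(r),
    |r| clipped below 1 to keep z finite.
    """
    if map_a.smoothed_rate.shape != map_b.smoothed_rate.shape:
        raise ValidationError("rate maps must share one grid")
    if not (si_a > si_threshold and si_b > si_threshold):
        return None, f"SI criterion failed (SI={si_a:.3f}, {si_b:.3f})"
    joint = map_a.valid_mask & map_b.valid_mask
    if joint.sum() < min_joint_bins:
        return None, f"only {int(joint.sum())} jointly valid bins"
    a = map_a.smoothed_rate[joint]
    b = map_b.smoothed_rate[joint]
    if np.std(a) == 0 or np.std(b) == 0:
        return None, "constant rate map"
    r = float(np.corrcoef(a, b)[0, 1])
    z = float(np.arctanh(np.clip(r, -_R_CLIP, _R_CLIP)))
    return (r, z), None
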