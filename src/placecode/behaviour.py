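"""Trajectory-derived behavioural measures and movement masks.

Running speed is computed as path length per 500-ms epoch, matching the
epoching used for LFP power stratification; the movement criterion is a strict
``speed > 3 cm/s``. Immobility is its complement (speed <= threshold).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Trajectory, ValidationError


@dataclass
class SpeedSeries:
    """Per-epoch running speed; epochs tile the session without overlap."""

    epoch_starts: np.ndarray  # s
    epoch_duration: float  # s
    speed: np.ndarray  # cm/s; NaN where tracking is insufficient

    def __post_init__(self) -> None:
        self.epoch_starts = np.asarray(self.epoch_starts, dtype=float)
        self.speed = np.asarray(self.speed, dtype=float)
        if self.epoch_starts.shape != self.speed.shape:
            raise ValidationError("epoch_starts and speed must align")
        with np.errstate(invalid="ignore"):
            if np.any(self.speed < 0):
                raise ValidationError("speed must be >= 0")

    def __len__(self) -> int:
        return self.epoch_starts.size

    @property
    def defined(self) -> np.ndarray:
        return np.isfinite(self.speed)

    def epoch_of(self, times: np.ndarray) -> np.ndarray:
        """Epoch index for each time; -1 outside the tiled range."""
        times = np.asarray(times, dtype=float)
        t0 = self.epoch_starts[0]
        idx = np.floor((times - t0) / self.epoch_duration).astype(int)
        idx[(idx < 0) | (idx >= len(self))] = -1
        return idx


def compute_speed(traj: Trajectory, epoch_duration: float = 0.5) -> SpeedSeries:
    """Path length per epoch divided by epoch duration.

    Epochs with fewer than 2 position samples have undefined (NaN) speed.
    The within-epoch path includes the segment connecting to the previous
    epoch's last sample, so a constant-velocity run yields the exact speed.
    """
    if len(traj) < 2:
        raise ValidationError("need >= 2 samples to compute speed")
    t0, t1 = traj.timestamps[0], traj.timestamps[-1]
    n_epochs = max(1, int(np.ceil((t1 - t0) / epoch_duration - 1e-9)))
    starts = t0 + epoch_duration * np.arange(n_epochs)

    # assign each inter-sample segment to the epoch of its midpoint
    seg_len = np.hypot(np.diff(traj.x), np.diff(traj.y))
    seg_mid = 0.5 * (traj.timestamps[:-1] + traj.timestamps[1:])
    seg_epoch = np.clip(
        np.floor((seg_mid - t0) / epoch_duration).astype(int), 0, n_epochs - 1
    )
    path = np.bincount(seg_epoch, weights=seg_len, minlength=n_epochs)

    counts = np.bincount(
        np.clip(np.floor((traj.timestamps - t0) / epoch_duration).astype(int),
                0, n_epochs - 1),
        minlength=n_epochs,
    )
    speed = path / epoch_duration
    speed[counts < 2] = np.nan
    return SpeedSeries(epoch_starts=starts, epoch_duration=epoch_duration, speed=speed)


def movement_mask(speed: SpeedSeries, threshold: float = 3.0) -> np.ndarray:
    """True for epochs of locomotion, strictly ``speed > threshold``.

    Undefined-speed epochs are excluded (False).
    """
    with np.errstate(invalid="ignore"):
        return np.asarray(speed.speed > threshold)


def mask_times(speed: SpeedSeries, mask: np.ndarray, times: np.ndarray) -> np.ndarray:
    """Project a per-epoch mask onto arbitrary time points (spikes, samples)."""
    idx = speed.epoch_of(times)
    out = np.zeros(len(np.atleast_1d(times)), dtype=bool)
    valid = idx >= 0
    out[valid] = np.asarray(mask)[idx[valid]]
    return out


def masked_duration(speed: SpeedSeries, mask: np.ndarray) -> float:
    """Total time (s) covered by True epochs."""
    return float(np.sum(np.asarray(mask)) * speed.epoch_duration)


def path_length(traj: Trajectory, speed: SpeedSeries | None = None,
                mask: np.ndarray | None = None) -> float:
    """Total Euclidean path length (cm), optionally restricted to masked epochs."""
    seg_len = np.hypot(np.diff(traj.x), np.diff(traj.y))
    if mask is None:
        return float(seg_len.sum())
    if speed is None:
        raise ValidationError("mask projection requires the SpeedSeries")
    seg_mid = 0.5 * (traj.timestamps[:-1] + traj.timestamps[1:])
    keep = mask_times(speed, mask, seg_mid)
    return float(seg_len[keep].sum())


def arena_bin_centres(arena_radius: float, bin_size: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Square grid anchored at the arena centre.

    Returns (x_centres, y_centres, inside) where ``inside`` marks bins whose
    centre lies within the arena disc.
    """
    n_half = int(np.ceil(arena_radius / bin_size))
    edges = bin_size * np.arange(-n_half, n_half + 1)
    centres = 0.5 * (edges[:-1] + edges[1:])
    cx, cy = np.meshgrid(centres, centres, indexing="ij")
    inside = np.hypot(cx, cy) <= arena_radius
    return centres, centres, inside


def coverage(traj: Trajectory, bin_size: float = 2.5,
             min_occupancy: float = 0.1) -> float:
    """Percentage of in-arena bins visited for at least ``min_occupancy`` s."""
    centres, _, inside = arena_bin_centres(traj.arena_radius, bin_size)
    half = bin_size * len(centres) / 2
    dt = traj.median_dt
    ix = np.clip(((traj.x + half) // bin_size).astype(int), 0, len(centres) - 1)
    iy = np.clip(((traj.y + half) // bin_size).astype(int), 0, len(centres) - 1)
    occ = np.zeros((len(centres), len(centres)))
    np.add.at(occ, (ix, iy), dt)
    visited = (occ >= min_occupancy) & inside
    return 100.0 * visited.sum() / inside.sum()


def post_immobility_activity_epochs(
    speed: SpeedSeries,
    threshold: float = 3.0,
    run_duration: float = 4.0,
    min_immobility_epochs: int = 1,
) -> list[tuple[float, float]]:
    """First ``run_duration`` s of each movement run preceded by immobility.

    A qualifying run is a maximal block of consecutive supra-threshold epochs
    lasting at least ``run_duration`` s, immediately preceded by at least
    ``min_immobility_epochs`` sub-threshold (or undefined) epochs. Runs
    starting at the session onset do not qualify (no observed immobility).
    Returns (start, end) times in seconds.
    """
    mov = movement_mask(speed, threshold)
    need = int(round(run_duration / speed.epoch_duration))
    epochs: list[tuple[float, float]] = []
    i = 0
    n = len(mov)
    while i < n:
        if mov[i]:
            j = i
            while j < n and mov[j]:
                j += 1
            run_len = j - i
            preceded = i >= min_immobility_epochs and not mov[i - min_immobility_epochs:i].any()
            if run_len >= need and preceded:
                start = speed.epoch_starts[i]
                epochs.append((float(start), float(start + run_duration)))
            i = j
        else:
            i += 1
    return epochs


def time_in_speed_bins(
    speed: SpeedSeries, bin_width: float = 3.0, max_speed: float = 45.0
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of defined-epoch time (s) per speed bin [k*w, (k+1)*w).

    Conserves total defined time: the last bin absorbs speeds >= max_speed.
    Returns (bin_left_edges, seconds_per_bin).
    """
    edges = np.arange(0.0, max_speed + bin_width, bin_width)
    sp = speed.speed[speed.defined]
    idx = np.clip((sp // bin_width).astype(int), 0, len(edges) - 2)
    seconds = np.bincount(idx, minlength=len(edges) - 1) * speed.epoch_duration
    return edges[:-1], seconds
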