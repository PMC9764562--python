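"""Domain containers shared by every analysis stage.

All time axes are in seconds on one shared per-session clock; positions are
arena-centred Cartesian centimetres. Containers validate their invariants at
construction and never silently repair data — misaligned inputs raise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

logger = logging.getLogger("placecode")

#: tolerance (cm) for positions nominally outside the arena wall (tracking jitter)
ARENA_TOLERANCE_CM = 2.0


class FormatError(ValueError):
    """Malformed input table (missing columns, ragged rows)."""


class ValidationError(ValueError):
    """Structurally well-formed input violating a domain invariant."""


@dataclass(frozen=True)
class SessionSchedule:
    """Position of one 10-min session in the 2-day x 3-session protocol."""

    day: int
    session_in_day: int

    def __post_init__(self) -> None:
        if self.day not in (1, 2):
            raise ValidationError(f"day must be 1 or 2, got {self.day}")
        if self.session_in_day not in (1, 2, 3):
            raise ValidationError(
                f"session_in_day must be in 1..3, got {self.session_in_day}"
            )

    @property
    def session_index(self) -> int:
        """Overall session number 1..6 (1-3 on day 1, 4-6 on day 2)."""
        return 3 * (self.day - 1) + self.session_in_day

    @classmethod
    def from_index(cls, session_index: int) -> "SessionSchedule":
        if not 1 <= session_index <= 6:
            raise ValidationError(f"session_index must be in 1..6, got {session_index}")
        day = (session_index - 1) // 3 + 1
        return cls(day=day, session_in_day=session_index - 3 * (day - 1))


@dataclass
class Trajectory:
    """Head-position samples (nominally 50 Hz) in an open cylindrical arena.

    Out-of-arena points (beyond ``arena_radius`` + tolerance) are retained but
    flagged in ``out_of_arena``; sampling gaps larger than twice the median
    interval are flagged in ``gap_after``, never interpolated.
    """

    timestamps: np.ndarray
    x: np.ndarray
    y: np.ndarray
    arena_radius: float = 31.0

    out_of_arena: np.ndarray = field(init=False, repr=False)
    gap_after: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (self.timestamps.shape == self.x.shape == self.y.shape):
            raise ValidationError("timestamps, x, y must have equal length")
        if self.timestamps.size == 0:
            raise ValidationError("empty trajectory")
        dt = np.diff(self.timestamps)
        if np.any(dt <= 0):
            raise ValidationError("timestamps must be strictly increasing")
        r = np.hypot(self.x, self.y)
        self.out_of_arena = r > self.arena_radius + ARENA_TOLERANCE_CM
        if self.out_of_arena.any():
            logger.warning(
                "%d/%d position samples outside arena radius %.1f cm (flagged)",
                int(self.out_of_arena.sum()), self.timestamps.size, self.arena_radius,
            )
        if dt.size:
            self.gap_after = np.concatenate([dt > 2.0 * np.median(dt), [False]])
        else:
            self.gap_after = np.zeros(1, dtype=bool)

    def __len__(self) -> int:
        return self.timestamps.size

    @property
    def duration(self) -> float:
        return float(self.timestamps[-1] - self.timestamps[0])

    @property
    def median_dt(self) -> float:
        if len(self) < 2:
            raise ValidationError("need >= 2 samples for a sampling interval")
        return float(np.median(np.diff(self.timestamps)))


@dataclass
class SpikeTrain:
    """Spike times of one sorted cluster with per-spike waveform features."""

    cluster_id: str
    spike_times: np.ndarray
    features: np.ndarray | None = None
    mean_waveform_width: float = float("nan")  # microseconds
    genotype_label: str = ""
    session: SessionSchedule | None = None

    def __post_init__(self) -> None:
        self.spike_times = np.asarray(self.spike_times, dtype=float)
        if self.spike_times.ndim != 1:
            raise ValidationError("spike_times must be 1-D")
        if np.any(np.diff(self.spike_times) < 0):
            raise ValidationError("spike_times must be sorted ascending")
        if self.features is not None:
            self.features = np.atleast_2d(np.asarray(self.features, dtype=float))
            if self.features.shape[0] != self.spike_times.size:
                raise ValidationError(
                    "one feature vector per spike required "
                    f"({self.features.shape[0]} != {self.spike_times.size})"
                )
        if not np.isnan(self.mean_waveform_width) and self.mean_waveform_width <= 0:
            raise ValidationError("mean_waveform_width must be > 0 us")

    def __len__(self) -> int:
        return self.spike_times.size

    @property
    def feature_dim(self) -> int | None:
        return None if self.features is None else self.features.shape[1]


@dataclass
class LFPRecording:
    """One-channel local field potential trace."""

    samples: np.ndarray
    fs: float = 4800.0
    session: SessionSchedule | None = None
    #: highest analysed frequency (Hz); fs must exceed twice this
    max_analysis_freq: float = 102.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValidationError("LFP samples must be 1-D")
        if not np.all(np.isfinite(self.samples)):
            raise ValidationError("LFP contains non-finite samples")
        if self.fs <= 2.0 * self.max_analysis_freq:
            raise ValidationError(
                f"fs={self.fs} Hz cannot resolve {self.max_analysis_freq} Hz"
            )

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        return self.samples.size / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.fs


@dataclass
class SessionDataset:
    """Everything recorded in one session: trajectory, spike trains, LFP."""

    trajectory: Trajectory
    spike_trains: Sequence[SpikeTrain]
    lfp: LFPRecording | None = None
    animal_id: str = ""
    genotype: str = ""
    session: SessionSchedule | None = None

    #: spike times may lead/lag the tracking window by at most this much (s)
    CLOCK_SLACK_S = 1.0

    def __post_init__(self) -> None:
        t0 = self.trajectory.timestamps[0] - self.CLOCK_SLACK_S
        t1 = self.trajectory.timestamps[-1] + self.CLOCK_SLACK_S
        for train in self.spike_trains:
            if len(train) and (train.spike_times[0] < t0 or train.spike_times[-1] > t1):
                raise ValidationError(
                    f"cluster {train.cluster_id}: spikes outside tracked window "
                    f"[{t0:.2f}, {t1:.2f}] s — clocks not aligned?"
                )
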