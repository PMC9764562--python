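"""Analysis configuration: every tunable constant in one validated place.

Defaults follow the in vivo protocol this pipeline targets: 2.5-cm spatial
bins, 3 cm/s movement threshold, 100-ms occupancy validity, 10-ms burst ISI,
place fields of >= 9 contiguous bins above 20% of the map peak, SI > 0.5
bits/spike for stability inclusion, and 30-cell / 1000-rep / +-5% rate-matched
down-sampling. The config is serialised into every output for provenance.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .core import ValidationError


@dataclass
class AnalysisConfig:
    # spatial binning / rate maps
    bin_size_cm: float = 2.5
    smoothing_h_cm: float = 2.5
    min_occupancy_s: float = 0.1
    arena_radius_cm: float = 31.0

    # behaviour
    speed_threshold_cm_s: float = 3.0
    speed_epoch_s: float = 0.5
    post_immobility_run_s: float = 4.0
    speed_bin_width_cm_s: float = 3.0

    # unit classification
    iso_d_threshold: float = 15.0
    l_ratio_threshold: float = 0.2
    waveform_width_us: float = 250.0
    pyramidal_max_rate_hz: float = 5.0
    active_min_rate_hz: float = 0.1
    burst_isi_ms: float = 10.0
    chi2_df: int = 8

    # place fields / stability
    field_min_bins: int = 9
    field_threshold_frac: float = 0.2
    field_connectivity: int = 4  # 4 or 8
    stability_si_threshold: float = 0.5
    stability_min_joint_bins: int = 10

    # LFP
    lfp_window_s: float = 20.0
    lfp_step_s: float = 10.0
    multitaper_tw: float = 3.0
    multitaper_k: int = 5
    strong_oscillation_sd: float = 2.0
    min_spikes_phase_locking: int = 30

    # down-sampling control
    subsample_size: int = 30
    subsample_reps: int = 1000
    subsample_rate_tol: float = 0.05

    seed: int = 0
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        positive = [
            "bin_size_cm", "smoothing_h_cm", "min_occupancy_s", "arena_radius_cm",
            "speed_epoch_s", "post_immobility_run_s", "speed_bin_width_cm_s",
            "waveform_width_us", "pyramidal_max_rate_hz", "burst_isi_ms",
            "lfp_window_s", "lfp_step_s", "strong_oscillation_sd",
        ]
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")
        if self.speed_threshold_cm_s < 0 or self.active_min_rate_hz < 0:
            raise ValidationError("thresholds must be >= 0")
        if self.field_connectivity not in (4, 8):
            raise ValidationError("field_connectivity must be 4 or 8")
        if not 0 < self.field_threshold_frac < 1:
            raise ValidationError("field_threshold_frac must be in (0,1)")
        if not 0 < self.subsample_rate_tol < 1:
            raise ValidationError("subsample_rate_tol must be in (0,1)")
        if self.active_min_rate_hz >= self.pyramidal_max_rate_hz:
            raise ValidationError("active rate band is empty")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))
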