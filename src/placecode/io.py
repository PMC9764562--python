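"""CSV readers/writers for positions, spikes, LFP and tidy metric tables.

Dialect: UTF-8, comma-delimited, mandatory header row, times in seconds as
floats. All readers validate domain invariants on load; all writers round-trip
losslessly at float precision (``repr``-exact via pandas ``float_format=None``).
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core import (
    FormatError,
    LFPRecording,
    SpikeTrain,
    Trajectory,
    ValidationError,
)

logger = logging.getLogger("placecode")

METRICS_COLUMNS = ["cell", "animal", "genotype", "day", "session", "metric", "value"]


def _read_csv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    return df


def read_position_table(path: str | Path) -> Trajectory:
    """Load a ``time,x,y`` table (s, cm, cm) into a validated Trajectory."""
    df = _read_csv(path, ["time", "x", "y"])
    return Trajectory(
        timestamps=df["time"].to_numpy(float),
        x=df["x"].to_numpy(float),
        y=df["y"].to_numpy(float),
    )


def write_position_table(traj: Trajectory, path: str | Path) -> None:
    pd.DataFrame({"time": traj.timestamps, "x": traj.x, "y": traj.y}).to_csv(
        path, index=False
    )


def read_spike_table(path: str | Path) -> list[SpikeTrain]:
    """Load a ``cluster_id,spike_time,f1..fd`` table into per-cluster trains.

    Spike times are sorted within each cluster; an empty file yields an empty
    list with a warning. Feature columns are optional but must be complete
    (no ragged rows) when present.
    """
    df = _read_csv(path, ["cluster_id", "spike_time"])
    if df.empty:
        logger.warning("%s: empty spike table", path)
        return []
    feat_cols = [c for c in df.columns if c.startswith("f") and c[1:].isdigit()]
    feat_cols.sort(key=lambda c: int(c[1:]))
    if feat_cols and df[feat_cols].isna().any().any():
        raise FormatError(f"{path}: ragged feature columns (NaN entries)")
    trains = []
    for cid, sub in df.groupby("cluster_id", sort=True):
        order = np.argsort(sub["spike_time"].to_numpy(), kind="stable")
        trains.append(
            SpikeTrain(
                cluster_id=str(cid),
                spike_times=sub["spike_time"].to_numpy(float)[order],
                features=sub[feat_cols].to_numpy(float)[order] if feat_cols else None,
            )
        )
    return trains


def write_spike_table(trains: Iterable[SpikeTrain], path: str | Path) -> None:
    frames = []
    for tr in trains:
        d: dict = {"cluster_id": tr.cluster_id, "spike_time": tr.spike_times}
        if tr.features is not None:
            for j in range(tr.features.shape[1]):
                d[f"f{j + 1}"] = tr.features[:, j]
        frames.append(pd.DataFrame(d))
    out = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=["cluster_id", "spike_time"])
    )
    out.to_csv(path, index=False)


def read_lfp_table(path: str | Path, fs: float = 4800.0) -> LFPRecording:
    df = _read_csv(path, ["voltage"])
    return LFPRecording(samples=df["voltage"].to_numpy(float), fs=fs)


def write_lfp_table(lfp: LFPRecording, path: str | Path) -> None:
    pd.DataFrame({"voltage": lfp.samples}).to_csv(path, index=False)


def write_metrics_table(records: Sequence[Mapping], path: str | Path) -> None:
    """Write tidy long-format per-cell metric rows for external model fitting.

    Every record must carry exactly the keys
    ``cell, animal, genotype, day, session, metric, value``; heterogeneous
    records raise rather than silently widening the schema.
    """
    for i, rec in enumerate(records):
        if set(rec) != set(METRICS_COLUMNS):
            raise ValidationError(
                f"record {i} keys {sorted(rec)} != schema {sorted(METRICS_COLUMNS)}"
            )
    pd.DataFrame(list(records), columns=METRICS_COLUMNS).to_csv(path, index=False)


def read_metrics_table(path: str | Path) -> pd.DataFrame:
    return _read_csv(path, METRICS_COLUMNS)
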