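"""End-to-end per-session and per-experiment analysis orchestration.

``run_session`` applies the full per-session chain — speed/movement masking,
cluster quality, pyramidal classification, activity filtering, rate and burst
statistics, rate maps with spatial tuning metrics, LFP band power and spike
phase locking — and returns tidy per-cell rows plus session-level results.
``run_experiment`` folds sessions into an experiment-level table with
successive-session map-stability pairs and genotype/day summaries. Every
exclusion is logged with its criterion.
"""

from __future__ import annotations

import logging
from typing import Iterable

import numpy as np
import pandas as pd

from . import behaviour as bhv
from . import lfp as lfp_mod
from . import maps as maps_mod
from . import units as units_mod
from .config import AnalysisConfig
from .core import SessionDataset

logger = logging.getLogger("placecode")


def _cluster_quality(dataset: SessionDataset) -> dict[str, units_mod.ClusterQuality]:
    """Iso-D / L-ratio of each cluster against all other clusters' spikes."""
    feats = {t.cluster_id: t.features for t in dataset.spike_trains
             if t.features is not None and len(t) > t.features.shape[1]}
    out: dict[str, units_mod.ClusterQuality] = {}
    for cid, f in feats.items():
        others = [g for oid, g in feats.items() if oid != cid]
        if not others:
            continue
        non = np.vstack(others)
        try:
            iso = units_mod.isolation_distance(f, non)
            lr = units_mod.l_ratio(f, non, df=8)
        except Exception as e:  # noqa: BLE001 - per-cell isolation of failures
            logger.warning("cluster %s: quality metrics failed (%s)", cid, e)
            continue
        out[cid] = units_mod.ClusterQuality(
            isolation_distance=iso, l_ratio=lr,
            n_spikes=f.shape[0], feature_dim=f.shape[1])
    return out


def run_session(dataset: SessionDataset, config: AnalysisConfig | None = None,
                compute_lfp: bool = True,
                compute_quality: bool = True) -> dict:
    """Run the full analysis chain on one session.

    Returns a dict with ``cells`` (per-cell metric rows), ``maps``
    (cluster_id -> (RateMap, SI)), ``behaviour`` (session-level measures) and
    ``lfp`` (band powers; None when no LFP is attached or ``compute_lfp`` is
    off).
    """
    cfg = config or AnalysisConfig()
    sched = dataset.session
    speed = bhv.compute_speed(dataset.trajectory, cfg.speed_epoch_s)
    mask = bhv.movement_mask(speed, cfg.speed_threshold_cm_s)
    masked_time = bhv.masked_duration(speed, mask)

    behaviour_row = {
        "animal": dataset.animal_id, "genotype": dataset.genotype,
        "day": sched.day if sched else None,
        "session": sched.session_index if sched else None,
        "path_length_cm": bhv.path_length(dataset.trajectory),
        "path_length_moving_cm": bhv.path_length(dataset.trajectory, speed, mask),
        "coverage_pct": bhv.coverage(dataset.trajectory, cfg.bin_size_cm,
                                     cfg.min_occupancy_s),
        "movement_time_s": masked_time,
    }

    quality = _cluster_quality(dataset) if compute_quality else {}
    occ_density = maps_mod.kernel_occupancy_density(
        dataset.trajectory, speed, mask, cfg.bin_size_cm, cfg.smoothing_h_cm)

    lfp_result = None
    phase_by_band: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    if compute_lfp and dataset.lfp is not None:
        epochs = bhv.post_immobility_activity_epochs(
            speed, cfg.speed_threshold_cm_s, cfg.post_immobility_run_s)
        lfp_result = {"post_immobility_epochs": epochs}
        try:
            lfp_result["band_power"] = lfp_mod.session_band_power(
                dataset.lfp, epochs, cfg.lfp_window_s, cfg.lfp_step_s,
                cfg.multitaper_tw, cfg.multitaper_k)
        except Exception as e:  # noqa: BLE001
            logger.warning("session band power unavailable: %s", e)
            lfp_result["band_power"] = None
        binned = lfp_mod.binned_band_power(dataset.lfp, cfg.speed_epoch_s)
        lfp_result["binned_power"] = binned
        lfp_result["velocity_stratified"] = lfp_mod.velocity_stratified_power(
            binned, speed, cfg.speed_bin_width_cm_s)
        for band in lfp_mod.BANDS:
            filtered = lfp_mod.bandpass(dataset.lfp, band)
            phase, amp = lfp_mod.instantaneous_phase_amplitude(filtered)
            strong, _ = lfp_mod.strong_oscillation_mask(
                amp, dataset.lfp.fs, cfg.speed_epoch_s, cfg.strong_oscillation_sd)
            phase_by_band[band.name] = (phase, strong)

    rows = []
    maps_out: dict[str, tuple[maps_mod.RateMap, float]] = {}
    for train in dataset.spike_trains:
        row: dict = {
            "cell": train.cluster_id, "animal": dataset.animal_id,
            "genotype": dataset.genotype or train.genotype_label,
            "day": sched.day if sched else None,
            "session": sched.session_index if sched else None,
            "n_spikes": len(train),
        }
        spike_moving = bhv.mask_times(speed, mask, train.spike_times)
        rate = units_mod.mean_firing_rate(train, masked_time, spike_moving)
        row["rate_hz"] = rate

        q = quality.get(train.cluster_id)
        row["iso_d"] = q.isolation_distance if q else np.nan
        row["l_ratio"] = q.l_ratio if q else np.nan
        row["is_pyramidal"] = units_mod.classify_pyramidal(
            rate, q, train.mean_waveform_width,
            cfg.iso_d_threshold, cfg.l_ratio_threshold,
            cfg.waveform_width_us, cfg.pyramidal_max_rate_hz,
        ) if compute_quality else True
        row["is_active"] = units_mod.is_active(
            rate, cfg.active_min_rate_hz, cfg.pyramidal_max_rate_hz)
        if not row["is_active"]:
            logger.info("cell %s s%s excluded from spatial metrics: rate %.3f Hz "
                        "outside (%.1f, %.1f)", train.cluster_id,
                        row["session"], rate, cfg.active_min_rate_hz,
                        cfg.pyramidal_max_rate_hz)

        moving_train = type(train)(
            cluster_id=train.cluster_id,
            spike_times=train.spike_times[spike_moving])
        bstats = units_mod.burst_probability(moving_train, cfg.burst_isi_ms)
        row["burst_probability"] = bstats.burst_probability
        row["burst_spike_fraction"] = (
            units_mod.burst_spike_fraction(moving_train, cfg.burst_isi_ms)
            if len(moving_train) else np.nan)

        row["si_bits_per_spike"] = np.nan
        row["sparsity"] = np.nan
        row["field_size_cm2"] = np.nan
        row["pct_active_bins"] = np.nan
        if row["is_active"]:
            rmap = maps_mod.rate_map(
                dataset.trajectory, train, speed, mask, cfg.bin_size_cm,
                cfg.smoothing_h_cm, cfg.min_occupancy_s, occ_density)
            try:
                si = maps_mod.spatial_information(rmap)
                row["si_bits_per_spike"] = si
                row["sparsity"] = maps_mod.sparsity(rmap)
                row["pct_active_bins"] = maps_mod.percent_active_bins(rmap)
                row["field_size_cm2"] = maps_mod.main_field_size(
                    rmap, min_bins=cfg.field_min_bins,
                    threshold_frac=cfg.field_threshold_frac,
                    connectivity=cfg.field_connectivity)
                maps_out[train.cluster_id] = (rmap, si)
            except Exception as e:  # noqa: BLE001
                logger.info("cell %s: spatial metrics undefined (%s)",
                            train.cluster_id, e)

        for band_name, (phase, strong) in phase_by_band.items():
            res = lfp_mod.phase_locking(
                train.spike_times[spike_moving], phase, dataset.lfp.fs,
                strong, band_name, cfg.speed_epoch_s,
                cfg.min_spikes_phase_locking)
            row[f"mvl_{band_name}"] = res.mvl if res.sufficient else np.nan
            row[f"pref_phase_{band_name}"] = (res.preferred_phase
                                              if res.sufficient else np.nan)
            row[f"rayleigh_p_{band_name}"] = (res.rayleigh_p
                                              if res.sufficient else np.nan)
        rows.append(row)

    return {"cells": pd.DataFrame(rows), "maps": maps_out,
            "behaviour": behaviour_row, "lfp": lfp_result}


def run_experiment(datasets: Iterable[SessionDataset],
                   config: AnalysisConfig | None = None,
                   compute_lfp: bool = True,
                   compute_quality: bool = True) -> dict:
    """Fold per-session results into experiment-level tables.

    Returns a dict with ``cells`` (per-cell per-session rows), ``stability``
    (Fisher-z rate-map correlations of successive session pairs per cell),
    ``behaviour``, ``lfp`` (session band powers) and ``summary``
    (genotype x day means of the headline metrics).
    """
    cfg = config or AnalysisConfig()
    cell_frames, behaviour_rows, lfp_rows, stability_rows = [], [], [], []
    # rate maps of the previous session per animal, for successive-pair stability
    prev_maps: dict[str, tuple[int, dict]] = {}

    for ds in datasets:
        res = run_session(ds, cfg, compute_lfp=compute_lfp,
                          compute_quality=compute_quality)
        cell_frames.append(res["cells"])
        behaviour_rows.append(res["behaviour"])
        s_idx = ds.session.session_index if ds.session else None
        if res["lfp"] and res["lfp"].get("band_power"):
            lfp_rows.append({"animal": ds.animal_id, "genotype": ds.genotype,
                             "day": ds.session.day, "session": s_idx,
                             **res["lfp"]["band_power"]})
        if s_idx is not None:
            prev = prev_maps.get(ds.animal_id)
            if prev and prev[0] == s_idx - 1:
                for cid, (map_b, si_b) in res["maps"].items():
                    if cid not in prev[1]:
                        continue
                    map_a, si_a = prev[1][cid]
                    out, reason = maps_mod.map_stability(
                        map_a, map_b, si_a, si_b,
                        cfg.stability_si_threshold, cfg.stability_min_joint_bins)
                    row = {"cell": cid, "animal": ds.animal_id,
                           "genotype": ds.genotype,
                           "pair": f"S{s_idx - 1}-S{s_idx}",
                           "session_a": s_idx - 1, "session_b": s_idx,
                           "r": np.nan, "z": np.nan, "excluded": reason}
                    if out is not None:
                        row["r"], row["z"] = out
                    stability_rows.append(row)
            prev_maps[ds.animal_id] = (s_idx, res["maps"])

    cells = pd.concat(cell_frames, ignore_index=True) if cell_frames else pd.DataFrame()
    summary = None
    if not cells.empty:
        active = cells[cells["is_active"] & cells["is_pyramidal"]]
        keep = [c for c in ["rate_hz", "burst_probability", "si_bits_per_spike",
                            "sparsity", "field_size_cm2", "pct_active_bins"]
                if c in active.columns]
        summary = (active.groupby(["genotype", "day"])[keep]
                   .mean().reset_index())
    return {
        "cells": cells,
        "stability": pd.DataFrame(stability_rows),
        "behaviour": pd.DataFrame(behaviour_rows),
        "lfp": pd.DataFrame(lfp_rows),
        "summary": summary,
        "config": cfg,
    }


def metrics_long_format(cells: pd.DataFrame) -> list[dict]:
    """Melt the per-cell table into tidy rows for external mixed-model software."""
    id_cols = ["cell", "animal", "genotype", "day", "session"]
    value_cols = [c for c in cells.columns
                  if c not in id_cols and cells[c].dtype.kind in "fc"]
    long = cells.melt(id_vars=id_cols, value_vars=value_cols,
                      var_name="metric", value_name="value")
    return long.to_dict("records")
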