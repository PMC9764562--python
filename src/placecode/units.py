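"""Cluster quality, pyramidal classification, firing-rate and burst statistics.

Quality metrics operate on already-sorted clusters: isolation distance is the
squared Mahalanobis distance (w.r.t. the cluster's own mean and covariance) of
the n_c-th closest non-cluster spike, and L_ratio is the chi-square tail mass
of all non-cluster spikes divided by the cluster size. Classification uses
Iso-D > 15, L_ratio < 0.2, waveform width > 250 us and movement-masked mean
rate < 5 Hz; a cell is active in a session if that rate also exceeds 0.1 Hz.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import SpikeTrain, ValidationError

logger = logging.getLogger("placecode")


@dataclass
class ClusterQuality:
    isolation_distance: float  # NaN when undefined (too few non-cluster spikes)
    l_ratio: float
    n_spikes: int
    feature_dim: int


@dataclass
class BurstStats:
    n_bursts: int
    n_singles: int
    isi_threshold_ms: float

    @property
    def burst_probability(self) -> float:
        denom = self.n_bursts + self.n_singles
        return self.n_bursts / denom if denom else 0.0


def waveform_energy(waveform_samples: np.ndarray) -> float:
    """Sum of squared moduli of the waveform samples."""
    x = np.asarray(waveform_samples)
    if x.size == 0:
        raise ValidationError("empty waveform")
    if not np.all(np.isfinite(x)):
        raise ValidationError("non-finite waveform samples")
    return float(np.sum(np.abs(x) ** 2))


def _mahalanobis_sq(points: np.ndarray, mean: np.ndarray, cov: np.ndarray,
                    ridge: float = 0.0) -> np.ndarray:
    cov = cov + ridge * np.eye(cov.shape[0])
    try:
        cinv = np.linalg.inv(cov)
    except np.linalg.LinAlgError as e:
        raise ValidationError(
            "singular cluster covariance; pass ridge > 0 to regularise"
        ) from e
    # reject near-singular covariance that inv() silently tolerates
    if np.linalg.cond(cov) > 1e12:
        raise ValidationError(
            "ill-conditioned cluster covariance; pass ridge > 0 to regularise"
        )
    d = points - mean
    return np.einsum("ij,jk,ik->i", d, cinv, d)


def isolation_distance(cluster_features: np.ndarray,
                       noncluster_features: np.ndarray,
                       ridge: float = 0.0) -> float:
    """Squared Mahalanobis distance of the n_c-th closest non-cluster spike.

    Higher is better isolated. Returns NaN (undefined, not a rejection) when
    fewer non-cluster spikes than cluster spikes exist.
    """
    cf = np.atleast_2d(np.asarray(cluster_features, float))
    nf = np.atleast_2d(np.asarray(noncluster_features, float))
    n_c = cf.shape[0]
    if nf.shape[0] < n_c:
        logger.info("isolation_distance undefined: %d non-cluster < %d cluster",
                    nf.shape[0], n_c)
        return float("nan")
    mu = cf.mean(axis=0)
    cov = np.cov(cf, rowvar=False)
    d2 = _mahalanobis_sq(nf, mu, np.atleast_2d(cov), ridge)
    return float(np.sort(d2)[n_c - 1])


def l_ratio(cluster_features: np.ndarray, noncluster_features: np.ndarray,
            df: int | None = None, ridge: float = 0.0) -> float:
    """L / n_c, with L the summed chi-square upper-tail mass of non-cluster spikes.

    ``df`` defaults to the feature dimensionality; the conventional value for
    four-channel two-feature reductions is 8.
    """
    cf = np.atleast_2d(np.asarray(cluster_features, float))
    nf = np.atleast_2d(np.asarray(noncluster_features, float))
    if df is None:
        df = cf.shape[1]
    mu = cf.mean(axis=0)
    cov = np.cov(cf, rowvar=False)
    d2 = _mahalanobis_sq(nf, mu, np.atleast_2d(cov), ridge)
    L = float(np.sum(stats.chi2.sf(d2, df)))
    return L / cf.shape[0]


def mean_firing_rate(train: SpikeTrain, masked_time: float,
                     spike_mask: np.ndarray | None = None) -> float:
    """Masked spike count / masked time (Hz)."""
    if masked_time <= 0:
        raise ValidationError("mean rate undefined over zero masked time")
    n = len(train) if spike_mask is None else int(np.sum(spike_mask))
    return n / masked_time


def classify_pyramidal(rate_hz: float, quality: ClusterQuality | None,
                       waveform_width_us: float,
                       iso_d_threshold: float = 15.0,
                       l_ratio_threshold: float = 0.2,
                       width_threshold_us: float = 250.0,
                       max_rate_hz: float = 5.0) -> bool:
    """True iff Iso-D > 15, L_ratio < 0.2, width > 250 us and rate < 5 Hz.

    All inequalities are strict. Missing quality (undefined Iso-D) fails the
    criterion with a logged reason rather than raising.
    """
    if quality is None or not np.isfinite(quality.isolation_distance):
        logger.info("classify_pyramidal: quality unavailable -> not pyramidal")
        return False
    return (
        quality.isolation_distance > iso_d_threshold
        and quality.l_ratio < l_ratio_threshold
        and waveform_width_us > width_threshold_us
        and rate_hz < max_rate_hz
    )


def is_active(rate_hz: float, min_rate_hz: float = 0.1,
              max_rate_hz: float = 5.0) -> bool:
    """Session-level activity criterion: 0.1 Hz < movement-masked rate < 5 Hz."""
    return min_rate_hz < rate_hz < max_rate_hz


def _burst_groups(spike_times: np.ndarray, isi_threshold_ms: float) -> list[np.ndarray]:
    """Maximal groups of >= 2 spikes whose consecutive ISIs are all < threshold."""
    if spike_times.size < 2:
        return []
    isi_ms = np.diff(spike_times) * 1000.0
    linked = isi_ms < isi_threshold_ms
    groups = []
    start = 0
    for i in range(len(linked)):
        if not linked[i]:
            if i > start:
                groups.append(np.arange(start, i + 1))
            start = i + 1
    if len(linked) > start:
        groups.append(np.arange(start, len(spike_times)))
    return groups


def burst_probability(train: SpikeTrain, isi_threshold_ms: float = 10.0) -> BurstStats:
    """N_B / (N_B + N_S) with bursts = maximal ISI<threshold spike groups."""
    groups = _burst_groups(train.spike_times, isi_threshold_ms)
    n_in_bursts = sum(len(g) for g in groups)
    return BurstStats(
        n_bursts=len(groups),
        n_singles=len(train) - n_in_bursts,
        isi_threshold_ms=isi_threshold_ms,
    )


def burst_spike_fraction(train: SpikeTrain, isi_threshold_ms: float = 10.0) -> float:
    """Alternative burstiness: spikes belonging to bursts / total spikes."""
    if len(train) == 0:
        raise ValidationError("burst_spike_fraction undefined for 0 spikes")
    groups = _burst_groups(train.spike_times, isi_threshold_ms)
    return sum(len(g) for g in groups) / len(train)
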