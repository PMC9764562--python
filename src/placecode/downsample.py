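"""Firing-rate-constrained down-sampling controls.

Tests whether a between-condition difference in some cell-level metric is
secondary to a difference in mean firing rate: 30-cell subsamples are drawn
with replacement 1000 times, each constrained to a target mean rate (+-5%),
and the fraction of subsamples whose metric distribution differs from the full
population (Welch t-test, or Watson-Williams for circular metrics, at
p < 0.05) is reported as the modulation probability.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .circstats import watson_williams
from .core import ValidationError

logger = logging.getLogger("placecode")


class FeasibilityError(ValidationError):
    """Rate constraint unattainable within the attempt budget."""


@dataclass
class DownsamplingResult:
    target_rate: float
    tolerance: float
    subsample_size: int
    n_subsamples: int
    n_attempts: int
    subsample_indices: np.ndarray  # (reps, n) int
    subsample_metric_means: np.ndarray | None = None
    modulation_probability: float | None = None
    n_tested: int = 0
    extra: dict = field(default_factory=dict)


def constrained_subsample(rates: np.ndarray, target_rate: float,
                          n: int = 30, reps: int = 1000, tol: float = 0.05,
                          seed: int | np.random.Generator = 0,
                          max_attempts: int = 10**6,
                          batch: int = 4096) -> DownsamplingResult:
    """Rejection-sample ``reps`` with-replacement subsamples of size ``n``
    whose mean firing rate lies within ``target_rate * (1 +- tol)``.

    Raises :class:`FeasibilityError` (reporting the achieved acceptance rate)
    when the attempt budget (``max_attempts`` draws per accepted subsample) is
    exhausted.
    """
    rates = np.asarray(rates, dtype=float)
    if rates.size < n:
        raise ValidationError(f"population of {rates.size} < subsample size {n}")
    if target_rate <= 0:
        raise ValidationError("target_rate must be > 0")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    lo, hi = target_rate * (1 - tol), target_rate * (1 + tol)
    budget = max_attempts * reps
    accepted: list[np.ndarray] = []
    n_acc = 0
    attempts = 0
    while n_acc < reps:
        if attempts >= budget:
            raise FeasibilityError(
                f"rate constraint [{lo:.4g}, {hi:.4g}] Hz unattainable: "
                f"{n_acc}/{attempts} accepted "
                f"(acceptance rate {n_acc / max(attempts, 1):.2e})"
            )
        m = min(batch, budget - attempts)
        idx = rng.integers(0, rates.size, size=(m, n))
        means = rates[idx].mean(axis=1)
        ok = (means >= lo) & (means <= hi)
        accepted.append(idx[ok])
        n_acc += int(ok.sum())
        attempts += m
    indices = np.concatenate(accepted, axis=0)[:reps]
    return DownsamplingResult(
        target_rate=target_rate, tolerance=tol, subsample_size=n,
        n_subsamples=reps, n_attempts=attempts, subsample_indices=indices,
    )


def modulation_probability(result: DownsamplingResult, metric: np.ndarray,
                           alpha: float = 0.05,
                           circular: bool = False) -> DownsamplingResult:
    """Fraction of subsamples whose metric differs from the full population.

    Welch two-sample t-test of each subsample's metric values against all
    cells' values; circular metrics (preferred phase) use Watson-Williams
    instead. Subsamples in which the metric is undefined (NaN) for more than
    half the cells are skipped with a log message. The result is updated in
    place (means, probability) and returned.
    """
    metric = np.asarray(metric, dtype=float)
    pop = metric[np.isfinite(metric)]
    if pop.size < 2:
        raise ValidationError("population metric essentially undefined")
    n_sig = 0
    n_tested = 0
    skipped = 0
    means = np.full(result.subsample_indices.shape[0], np.nan)
    for i, idx in enumerate(result.subsample_indices):
        vals = metric[idx]
        vals = vals[np.isfinite(vals)]
        if vals.size < result.subsample_size / 2:
            skipped += 1
            continue
        if circular:
            means[i] = float(np.angle(np.mean(np.exp(1j * vals))))
            p, _ = watson_williams(vals, pop)
        else:
            means[i] = vals.mean()
            p = stats.ttest_ind(vals, pop, equal_var=False).pvalue
        n_tested += 1
        n_sig += p < alpha
    if skipped:
        logger.info("modulation_probability: skipped %d/%d subsamples "
                    "(metric undefined for > 50%% of cells)",
                    skipped, result.subsample_indices.shape[0])
    if n_tested == 0:
        raise ValidationError("no testable subsamples")
    result.subsample_metric_means = means
    result.modulation_probability = n_sig / n_tested
    result.n_tested = n_tested
    return result


def rate_change_matched_subsample(
    rate_pre: np.ndarray, rate_post: np.ndarray, stability_z: np.ndarray,
    reference_decrease: float | None = None, mode: str = "matched-decrease",
    n: int = 30, reps: int = 1000, tol: float = 0.05,
    seed: int | np.random.Generator = 0, max_attempts: int = 10**6,
    alpha: float = 0.05,
) -> DownsamplingResult:
    """Down-sampling matched on the session-3 to session-4 rate change.

    Subsamples are constrained on the mean rate decrease (pre - post): in
    ``matched-decrease`` mode to ``reference_decrease`` (+-5% of it, sign
    preserved); in ``null-decrease`` mode to zero change within +-5% of the
    reference decrease magnitude. The Fisher-z between-day stability of each
    subsample is then tested against the full population, yielding the
    modulation probability for map stability.
    """
    rate_pre = np.asarray(rate_pre, float)
    rate_post = np.asarray(rate_post, float)
    stability_z = np.asarray(stability_z, float)
    if not (rate_pre.shape == rate_post.shape == stability_z.shape):
        raise ValidationError("per-cell arrays must align")
    decrease = rate_pre - rate_post
    if reference_decrease is None:
        reference_decrease = float(np.nanmean(decrease))
    slack = tol * abs(reference_decrease)
    if slack == 0:
        raise ValidationError("reference decrease of 0 gives an empty band")
    if mode == "matched-decrease":
        lo, hi = reference_decrease - slack, reference_decrease + slack
    elif mode == "null-decrease":
        lo, hi = -slack, slack
    else:
        raise ValidationError(f"unknown mode {mode!r}")

    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    budget = max_attempts * reps
    accepted: list[np.ndarray] = []
    n_acc = 0
    attempts = 0
    while n_acc < reps:
        if attempts >= budget:
            raise FeasibilityError(
                f"decrease constraint [{lo:.4g}, {hi:.4g}] Hz unattainable: "
                f"{n_acc}/{attempts} accepted"
            )
        m = min(4096, budget - attempts)
        idx = rng.integers(0, decrease.size, size=(m, n))
        means = decrease[idx].mean(axis=1)
        ok = (means >= lo) & (means <= hi)
        accepted.append(idx[ok])
        n_acc += int(ok.sum())
        attempts += m
    result = DownsamplingResult(
        target_rate=reference_decrease, tolerance=tol, subsample_size=n,
        n_subsamples=reps, n_attempts=attempts,
        subsample_indices=np.concatenate(accepted, axis=0)[:reps],
        extra={"mode": mode},
    )
    return modulation_probability(result, stability_z, alpha=alpha)
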