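"""Circular hypothesis tests, proportion tests and Fisher-z utilities.

Implements the circular statistics toolbox routines this analysis relies on:
the Rayleigh uniformity test (Zar's small-sample-corrected approximation), the
Watson-Williams k-sample test of mean directions with the kappa-based
correction factor, and the Harrison-Kanji two-factor ANOVA for angles.
Proportion testing and FDR correction delegate to statsmodels.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.proportion import proportions_ztest

from .core import ValidationError

logger = logging.getLogger("placecode")


def circ_r(angles: np.ndarray, axis: int | None = None) -> np.ndarray | float:
    """Mean resultant vector length of a sample of angles (radians)."""
    angles = np.asarray(angles, dtype=float)
    c = np.mean(np.cos(angles), axis=axis)
    s = np.mean(np.sin(angles), axis=axis)
    return np.hypot(c, s)


def circ_mean(angles: np.ndarray, axis: int | None = None) -> np.ndarray | float:
    """Circular mean direction in [0, 2pi)."""
    angles = np.asarray(angles, dtype=float)
    c = np.mean(np.cos(angles), axis=axis)
    s = np.mean(np.sin(angles), axis=axis)
    return np.mod(np.arctan2(s, c), 2 * np.pi)


def circ_dist(a, b) -> np.ndarray | float:
    """Signed circular difference a - b wrapped to (-pi, pi]."""
    return np.angle(np.exp(1j * (np.asarray(a) - np.asarray(b))))


def circ_kappa(r: float, n: int | None = None) -> float:
    """Maximum-likelihood-style concentration estimate from a resultant length.

    Uses the Fisher/Best-Fisher approximation with the small-sample correction
    applied when n < 15.
    """
    r = float(r)
    if r < 0.53:
        kappa = 2 * r + r**3 + 5 * r**5 / 6
    elif r < 0.85:
        kappa = -0.4 + 1.39 * r + 0.43 / (1 - r)
    else:
        kappa = 1.0 / (r**3 - 4 * r**2 + 3 * r)
    if n is not None and 1 < n < 15:
        if kappa < 2:
            kappa = max(kappa - 2.0 / (n * kappa), 0.0)
        else:
            kappa = (n - 1) ** 3 * kappa / (n**3 + n)
    return kappa


def rayleigh_test(angles: np.ndarray) -> tuple[float, float]:
    """Rayleigh test of circular uniformity.

    Returns (p, Z) with Z = n * rbar^2 and Zar's approximation
    p = exp(sqrt(1 + 4n + 4(n^2 - R^2)) - (1 + 2n)), R = n * rbar.
    """
    angles = np.asarray(angles, dtype=float)
    n = angles.size
    if n < 3:
        raise ValidationError("Rayleigh test requires n >= 3")
    rbar = circ_r(angles)
    R = n * rbar
    Z = R * R / n
    p = float(np.exp(np.sqrt(1 + 4 * n + 4 * (n * n - R * R)) - (1 + 2 * n)))
    return min(p, 1.0), float(Z)


def rayleigh_p_batch(r: np.ndarray, n: int) -> np.ndarray:
    """Vectorised Rayleigh p-values from resultant lengths at fixed n."""
    R = n * np.asarray(r, dtype=float)
    p = np.exp(np.sqrt(1 + 4 * n + 4 * (n * n - R * R)) - (1 + 2 * n))
    return np.minimum(p, 1.0)


def watson_williams(*groups: np.ndarray) -> tuple[float, float]:
    """Watson-Williams test for equality of mean directions across k samples.

    Circular one-way ANOVA analogue; returns (p, F). Assumes comparable,
    reasonably high concentration across groups — a warning is logged when the
    pooled concentration estimate falls below 1.
    """
    if len(groups) < 2:
        raise ValidationError("need >= 2 groups")
    groups = [np.asarray(g, dtype=float) for g in groups]
    ns = np.array([g.size for g in groups])
    if np.any(ns < 2):
        raise ValidationError("every group needs n >= 2")
    if np.any(ns < 5):
        logger.warning("Watson-Williams: group with n < 5; test is approximate")
    N = int(ns.sum())
    k = len(groups)
    Ri = np.array([n * circ_r(g) for n, g in zip(ns, groups)])
    all_angles = np.concatenate(groups)
    R = N * circ_r(all_angles)

    rw = Ri.sum() / N
    kappa = circ_kappa(rw, N)
    if kappa < 1:
        logger.warning(
            "Watson-Williams: pooled kappa estimate %.2f < 1; "
            "concentration assumption questionable", kappa,
        )
    beta = 1 + 3.0 / (8.0 * kappa) if kappa > 0 else 1.0
    denom = N - Ri.sum()
    if denom <= 0:
        return 0.0, float("inf")
    F = beta * ((N - k) * (Ri.sum() - R)) / ((k - 1) * denom)
    p = float(stats.f.sf(F, k - 1, N - k))
    return p, float(F)


@dataclass
class HarrisonKanjiResult:
    p_factor_a: float
    p_factor_b: float
    p_interaction: float
    f_factor_a: float
    f_factor_b: float
    f_interaction: float
    kappa: float


def harrison_kanji(angles: np.ndarray, factor_a: np.ndarray,
                   factor_b: np.ndarray) -> HarrisonKanjiResult:
    """Two-factor ANOVA for circular data (Harrison-Kanji).

    Tests main effects of two categorical factors and their interaction on the
    mean direction, via the resultant-length decomposition with the kappa-based
    bias correction for the main effects. Valid for concentrated data; a
    warning is logged when the pooled concentration estimate is below 2.
    """
    angles = np.asarray(angles, dtype=float)
    factor_a = np.asarray(factor_a)
    factor_b = np.asarray(factor_b)
    if not (angles.shape == factor_a.shape == factor_b.shape):
        raise ValidationError("angles and factor labels must align")
    a_levels = np.unique(factor_a)
    b_levels = np.unique(factor_b)
    n = angles.size

    gn = np.zeros((a_levels.size, b_levels.size))
    gR = np.zeros_like(gn)
    for i, a in enumerate(a_levels):
        for j, b in enumerate(b_levels):
            sel = (factor_a == a) & (factor_b == b)
            gn[i, j] = sel.sum()
            if gn[i, j] == 0:
                raise ValidationError(f"empty design cell ({a!r}, {b!r})")
            gR[i, j] = gn[i, j] * circ_r(angles[sel])

    pn = gn.sum(axis=1)
    qn = gn.sum(axis=0)
    pR = np.array([pn[i] * circ_r(angles[factor_a == a])
                   for i, a in enumerate(a_levels)])
    qR = np.array([qn[j] * circ_r(angles[factor_b == b])
                   for j, b in enumerate(b_levels)])
    tR = n * circ_r(angles)
    kappa = circ_kappa(tR / n, n)
    if kappa < 2:
        logger.warning(
            "Harrison-Kanji: pooled kappa estimate %.2f < 2; "
            "the F approximation assumes concentrated data", kappa,
        )

    df_a = a_levels.size - 1
    df_b = b_levels.size - 1
    df_i = df_a * df_b
    df_r = n - a_levels.size * b_levels.size
    if df_r <= 0:
        raise ValidationError("no residual degrees of freedom")

    eff_a = float(np.sum(pR**2 / pn) - tR**2 / n)
    eff_b = float(np.sum(qR**2 / qn) - tR**2 / n)
    eff_cells = float(np.sum(gR**2 / gn))
    eff_i = eff_cells - np.sum(pR**2 / pn) - np.sum(qR**2 / qn) + tR**2 / n
    eff_r = n - eff_cells

    ms_r = eff_r / df_r
    beta = 1.0 / (1.0 - 1.0 / (5 * kappa) - 1.0 / (10 * kappa**2)) if kappa > 0 else 1.0

    f_a = beta * (eff_a / df_a) / ms_r
    f_b = beta * (eff_b / df_b) / ms_r
    f_i = (eff_i / df_i) / ms_r
    return HarrisonKanjiResult(
        p_factor_a=float(stats.f.sf(f_a, df_a, df_r)),
        p_factor_b=float(stats.f.sf(f_b, df_b, df_r)),
        p_interaction=float(stats.f.sf(f_i, df_i, df_r)),
        f_factor_a=float(f_a), f_factor_b=float(f_b), f_interaction=float(f_i),
        kappa=kappa,
    )


def two_proportion_ztest(k1: int, n1: int, k2: int, n2: int) -> tuple[float, float]:
    """Two-sided pooled-variance z-test on two proportions; returns (z, p)."""
    if n1 <= 0 or n2 <= 0:
        raise ValidationError("sample sizes must be positive")
    if not (0 <= k1 <= n1 and 0 <= k2 <= n2):
        raise ValidationError("counts must satisfy 0 <= k <= n")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        z, p = proportions_ztest([k1, k2], [n1, n2], alternative="two-sided")
    if np.isnan(p):  # both proportions 0 or 1: no evidence of difference
        return 0.0, 1.0
    return float(z), float(p)


def benjamini_hochberg(p_values: np.ndarray, alpha: float = 0.05):
    """Benjamini-Hochberg step-up FDR control.

    Returns (reject_mask, adjusted_p); adjusted p-values are monotone
    non-decreasing with rank.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return reject, p_adj


def fisher_z(r: float | np.ndarray) -> float | np.ndarray:
    """Variance-stabilising transform z = atanh(r); |r| >= 1 clipped with warning."""
    r = np.asarray(r, dtype=float)
    clip = 1.0 - 1e-7
    if np.any(np.abs(r) >= 1):
        logger.warning("fisher_z: |r| >= 1 clipped to %.7f", clip)
    out = np.arctanh(np.clip(r, -clip, clip))
    return float(out) if out.ndim == 0 else out


def fisher_z_inverse(z: float | np.ndarray) -> float | np.ndarray:
    out = np.tanh(np.asarray(z, dtype=float))
    return float(out) if out.ndim == 0 else out
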