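"""Group-level descriptive statistics and interval estimates.

Small-cohort digital-mobility studies report medians with interquartile
ranges, 90% confidence intervals for medians via the bias-corrected and
accelerated (BCa) bootstrap with 999 replicates, exact Clopper–Pearson
intervals for proportions, and Pearson/Spearman correlations against a
reference test (here the 6-min walking distance).  This module wraps those
estimators with reproducible seeding and a common interval container.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "IntervalEstimate",
    "median_iqr",
    "bca_median_ci",
    "clopper_pearson_ci",
    "correlations",
]

DEFAULT_LEVEL = 0.90
DEFAULT_REPLICATES = 999


@dataclass(frozen=True)
class IntervalEstimate:
    point: float
    lower: float
    upper: float
    level: float
    method: str  # bca | clopper_pearson | fisher_z | bootstrap
    n: int
    replicates: int | None = None
    seed: int | None = None


def median_iqr(values) -> tuple[float, float, float]:
    """Median and quartiles (Q1, Q3) with linear interpolation (type-7).

    Type-7 is the default quantile definition of R and numpy alike, so the
    IQR matches what the usual statistical environments print.
    """
    v = np.asarray(values, float)
    if v.size == 0:
        raise ValueError("median_iqr of an empty sequence")
    q1, med, q3 = np.quantile(v, [0.25, 0.5, 0.75])  # method="linear"
    return float(med), float(q1), float(q3)


def bca_median_ci(
    values,
    level: float = DEFAULT_LEVEL,
    replicates: int = DEFAULT_REPLICATES,
    seed: int = 0,
) -> IntervalEstimate:
    """BCa bootstrap confidence interval for the median.

    Acceleration comes from the jackknife; results are bit-reproducible for
    a fixed (seed, replicates).  An all-identical sample yields the
    degenerate interval (x, x, x) with a warning.
    """
    v = np.asarray(values, float)
    if v.size < 3:
        raise ValueError("BCa median CI needs n >= 3")
    if replicates < 199:
        raise ValueError("use at least 199 bootstrap replicates")
    point = float(np.median(v))
    if np.all(v == v[0]):
        warnings.warn("all values identical: degenerate bootstrap interval")
        return IntervalEstimate(point, point, point, level, "bca", v.size, replicates, seed)
    res = sps.bootstrap(
        (v,),
        np.median,
        confidence_level=level,
        n_resamples=replicates,
        method="BCa",
        vectorized=True,
        axis=-1,
        rng=np.random.default_rng(seed),
    )
    lo, hi = res.confidence_interval
    return IntervalEstimate(point, float(lo), float(hi), level, "bca", v.size, replicates, seed)


def clopper_pearson_ci(successes: int, n: int, level: float = DEFAULT_LEVEL) -> IntervalEstimate:
    """Exact (beta-quantile) binomial confidence interval for a proportion."""
    if not 0 <= successes <= n or n < 1:
        raise ValueError("need 0 <= successes <= n, n >= 1")
    ci = sps.binomtest(successes, n).proportion_ci(confidence_level=level, method="exact")
    return IntervalEstimate(
        point=successes / n,
        lower=float(ci.low),
        upper=float(ci.high),
        level=level,
        method="clopper_pearson",
        n=n,
    )


def _spearman(x, y, axis=-1):
    rx = sps.rankdata(x, axis=axis)
    ry = sps.rankdata(y, axis=axis)
    rx = rx - rx.mean(axis=axis, keepdims=True)
    ry = ry - ry.mean(axis=axis, keepdims=True)
    num = (rx * ry).sum(axis=axis)
    den = np.sqrt((rx**2).sum(axis=axis) * (ry**2).sum(axis=axis))
    return num / den


def correlations(
    x,
    y,
    level: float = DEFAULT_LEVEL,
    replicates: int = DEFAULT_REPLICATES,
    seed: int = 0,
    spearman_method: str = "bca",
) -> tuple[IntervalEstimate, IntervalEstimate]:
    """Pearson and Spearman correlations with confidence intervals.

    Pearson's interval uses the Fisher z transform; Spearman's uses a seeded
    BCa bootstrap of the rank correlation (resampling participants with
    replacement), or Fisher z on ranks with ``spearman_method="fisher_z"``.
    Ties receive average ranks.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be paired 1-d sequences")
    if x.size < 4:
        raise ValueError("correlation needs n >= 4")
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValueError("missing values are not allowed")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in x or y")

    pr = sps.pearsonr(x, y)
    pci = pr.confidence_interval(confidence_level=level)
    pearson = IntervalEstimate(
        float(pr.statistic), float(pci.low), float(pci.high), level, "fisher_z", x.size
    )

    rho = float(_spearman(x, y))
    if abs(rho) == 1.0:
        # Perfectly monotone pairs: every resample has |rho| = 1.
        spearman = IntervalEstimate(rho, rho, rho, level, "bca", x.size, replicates, seed)
    elif spearman_method == "fisher_z":
        z = np.arctanh(rho)
        se = 1.0 / np.sqrt(x.size - 3)
        zq = sps.norm.ppf(0.5 + level / 2)
        spearman = IntervalEstimate(
            rho, float(np.tanh(z - zq * se)), float(np.tanh(z + zq * se)),
            level, "fisher_z", x.size,
        )
    else:
        res = sps.bootstrap(
            (x, y),
            _spearman,
            confidence_level=level,
            n_resamples=replicates,
            method="BCa",
            vectorized=True,
            paired=True,
            axis=-1,
            rng=np.random.default_rng(seed),
        )
        spearman = IntervalEstimate(
            rho,
            float(res.confidence_interval.low),
            float(res.confidence_interval.high),
            level, "bca", x.size, replicates, seed,
        )
    return pearson, spearman
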