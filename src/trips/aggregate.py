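"""Whole-era summaries and the detrended sampling-proxy diagnostic.

An era-level sampling rate and detection probability are richness-weighted
means of the per-stage estimates, and the era's total richness follows by
binomial maximum likelihood at the mean detection probability applied to
the number of unique taxa observed across the era. The detrended
correlation compares estimated per-stage detection probabilities against
the log10 count of fossil-bearing collections after removing a linear
trend, a standard check of how much bias a collections proxy captures.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
from scipy.stats import pearsonr

from . import core
from .core import RichnessEstimate, SamplingEstimate

__all__ = [
    "EraSummary",
    "weighted_mean",
    "era_total_richness",
    "era_summary",
    "detrended_correlation",
]


@dataclass
class EraSummary:
    """Richness-weighted era means and the extrapolated total richness."""

    mean_rate: float
    mean_rate_lo: float
    mean_rate_hi: float
    mean_probability: float
    mean_probability_lo: float
    mean_probability_hi: float
    total_observed: int
    total_richness: int
    total_richness_lo: int
    total_richness_hi: float

    def to_dict(self) -> dict:
        return asdict(self)


def weighted_mean(values: Sequence[float], weights: Sequence[float]) -> float:
    """Weighted arithmetic mean; weights are estimated per-stage richness."""
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if values.shape != weights.shape:
        raise ValueError("values and weights must have equal length")
    if np.any(weights < 0):
        raise ValueError("weights must be non-negative")
    total = weights.sum()
    if total == 0:
        raise ValueError("weights must not all be zero")
    return float((values * weights).sum() / total)


def era_total_richness(
    total_observed: int,
    mean_p: float,
    p_lo: float | None = None,
    p_hi: float | None = None,
    conf: float = 0.95,
) -> tuple[int, int, float]:
    """Era-wide richness extrapolation from the mean detection probability.

    Returns ``(estimate, lower, upper)``; bounds equal the estimate when no
    probability bounds are given.
    """
    n_true = core.estimate_richness(total_observed, mean_p)
    if p_lo is None or p_hi is None:
        return n_true, n_true, float(n_true)
    lo, hi = core.richness_interval(total_observed, p_lo, p_hi, conf=conf)
    return n_true, lo, hi


def era_summary(
    sampling: Sequence[SamplingEstimate],
    richness: Sequence[RichnessEstimate],
    total_observed: int,
    conf: float = 0.95,
) -> EraSummary:
    """Era means weighted by estimated richness, plus the total extrapolation.

    Non-estimable stages carry no sampling information and are omitted from
    the weights and means. CI bounds of the means are the richness-weighted
    means of the per-stage bounds.
    """
    pairs = [
        (s, r)
        for s, r in zip(sampling, richness)
        if s.estimable and math.isfinite(s.lambda_hat)
    ]
    if not pairs:
        raise ValueError("no estimable stages")
    w = np.array([r.n_true for _, r in pairs], dtype=float)
    rate = weighted_mean([s.lambda_hat for s, _ in pairs], w)
    rate_lo = weighted_mean([s.lambda_lo for s, _ in pairs], w)
    rate_hi = weighted_mean([s.lambda_hi for s, _ in pairs], w)
    p = weighted_mean([s.p_hat for s, _ in pairs], w)
    p_lo = weighted_mean([s.p_lo for s, _ in pairs], w)
    p_hi = weighted_mean([s.p_hi for s, _ in pairs], w)
    n, lo, hi = era_total_richness(total_observed, p, p_lo, p_hi, conf=conf)
    return EraSummary(rate, rate_lo, rate_hi, p, p_lo, p_hi, total_observed, n, lo, hi)


def detrended_correlation(
    probabilities: Sequence[float],
    collection_counts: Sequence[float],
    covariate: Sequence[float] | None = None,
):
    """Pearson correlation of detection probabilities with detrended log10 counts.

    The counts (one per stage, in time order) are log10-transformed and the
    residuals of an ordinary least-squares line against the stage rank
    (or an explicit ``covariate``, e.g. stage midpoint ages) are correlated
    with the probabilities. Returns ``(r, p_value, residuals)``.
    """
    x = np.asarray(probabilities, dtype=float)
    y = np.asarray(collection_counts, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need equal-length series of at least 3 stages")
    if np.any(y <= 0):
        raise ValueError("collection counts must be positive")
    t = (
        np.arange(x.size, dtype=float)
        if covariate is None
        else np.asarray(covariate, dtype=float)
    )
    logy = np.log10(y)
    slope, intercept = np.polyfit(t, logy, 1)
    resid = logy - (slope * t + intercept)
    if np.allclose(resid, 0.0) or np.std(x) == 0:
        raise ValueError("zero variance after detrending: correlation undefined")
    r, pval = pearsonr(x, resid)
    return float(r), float(pval), resid
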