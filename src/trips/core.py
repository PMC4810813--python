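"""The TRiPS estimator.

Fossil sampling within a geological interval of duration ``d`` (Myr) is
modelled as a homogeneous Poisson process with rate ``lambda`` (observations
per lineage per Myr), identical for all lineages of the clade. Because a
taxon enters the data only if it was observed at least once, the observation
counts of the observed taxa follow a zero-truncated Poisson distribution
with mean ``lambda * d``:

    P(O = k | O > 0) = (lambda*d)^k exp(-lambda*d) / (k! (1 - exp(-lambda*d)))

``estimate_lambda`` maximises this likelihood over the observed counts and
returns a 95% profile-likelihood confidence interval (chi-square with 1
d.f.). The rate converts to a per-interval detection probability
``p = 1 - exp(-lambda*d)``, and the true richness ``N_true`` is the integer
maximising the binomial likelihood of observing ``N_t`` of ``N_true``
species each with probability ``p``. Confidence bounds on richness are the
chi-square profile-likelihood bounds of that binomial likelihood in N,
evaluated at the upper (lower bound) and lower (upper bound) confidence
limits of ``p``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from fractions import Fraction
from typing import Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.special import gammaln
from scipy.stats import chi2

__all__ = [
    "SamplingEstimate",
    "RichnessEstimate",
    "loglik_lambda",
    "estimate_lambda",
    "sampling_probability",
    "estimate_richness",
    "richness_interval",
    "trips_stage",
    "trips_replicated",
]

#: Upper 0.95 quantile of the chi-square distribution with 1 d.f.
CHI2_95_1 = 3.841459


def _halfq(conf: float) -> float:
    """Half the chi-square(1) cutoff for a given confidence level."""
    if conf == 0.95:
        return CHI2_95_1 / 2.0
    return chi2.ppf(conf, 1) / 2.0


@dataclass
class SamplingEstimate:
    """Per-stage sampling rate and detection probability with 95% CI."""

    stage: str
    duration: float
    n_observed: int
    lambda_hat: float
    lambda_lo: float
    lambda_hi: float
    p_hat: float
    p_lo: float
    p_hi: float
    estimable: bool

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class RichnessEstimate:
    """Per-stage observed and maximum-likelihood true richness with 95% CI.

    ``n_hi`` is ``inf`` when the lower sampling-probability bound is 0
    (richness then unbounded above).
    """

    stage: str
    n_observed: int
    n_true: int
    n_lo: int
    n_hi: float

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# zero-truncated Poisson likelihood for the sampling rate


def loglik_lambda(counts: Sequence[int], d: float, lam: float) -> float:
    """Zero-truncated Poisson log-likelihood of rate ``lam``.

    ``counts`` are the per-taxon observation counts of the *observed* taxa
    (all >= 1); ``d`` is the interval duration in Myr. Returns -inf at
    ``lam == 0``.
    """
    counts = np.asarray(counts)
    if counts.size == 0:
        raise ValueError("counts must be nonempty")
    if np.any(counts < 1):
        raise ValueError("all counts must be >= 1 (zero-truncated model)")
    if d <= 0:
        raise ValueError("duration must be positive")
    if lam < 0:
        raise ValueError("rate must be non-negative")
    if lam == 0.0:
        return -math.inf
    x = lam * d
    n = counts.size
    s = float(counts.sum())
    return (
        s * math.log(x)
        - n * x
        - float(gammaln(counts + 1).sum())
        - n * math.log(-math.expm1(-x))
    )


def _profile(x: float, s: float, n: float) -> float:
    """Count-independent part of the log-likelihood as a function of x = lam*d."""
    return s * math.log(x) - n * x - n * math.log(-math.expm1(-x))


def estimate_lambda(
    counts: Sequence[int], d: float, conf: float = 0.95
) -> tuple[float, float, float]:
    """Maximum-likelihood sampling rate with profile-likelihood CI.

    The MLE solves the moment identity ``x / (1 - exp(-x)) = mean(counts)``
    in ``x = lam*d`` (equivalent to maximising the truncated-Poisson
    likelihood). All-singleton data (every count equal to 1) gives the
    boundary estimate 0 exactly, with lower bound 0; the upper bound is the
    profile-likelihood root, which remains well defined.

    Returns ``(lambda_hat, lambda_lo, lambda_hi)``.
    """
    counts = np.asarray(counts)
    if counts.size == 0:
        raise ValueError("counts must be nonempty")
    if np.any(counts < 1):
        raise ValueError("all counts must be >= 1 (zero-truncated model)")
    if d <= 0:
        raise ValueError("duration must be positive")
    n = counts.size
    s = float(counts.sum())
    mean = s / n
    halfq = _halfq(conf)

    if mean <= 1.0:
        # all singletons: likelihood sup at the lam -> 0 boundary, value 0
        hi = brentq(lambda x: _profile(x, s, n) + halfq, 1e-12, 50.0, xtol=1e-10)
        return 0.0, 0.0, hi / d

    # x/(1-e^{-x}) is increasing from 1 and > x, so [tiny, mean] brackets
    xhat = brentq(
        lambda x: x / -math.expm1(-x) - mean, 1e-12, mean, xtol=1e-12, rtol=1e-12
    )
    llmax = _profile(xhat, s, n)
    cutoff = llmax - halfq

    def f(x: float) -> float:
        return _profile(x, s, n) - cutoff

    # lower root: log-likelihood -> -inf as x -> 0 whenever any count >= 2
    lo = brentq(f, 1e-300, xhat, xtol=1e-12)
    # upper root: grow the bracket geometrically
    xr = xhat * 2 + 1.0
    while f(xr) > 0:
        xr *= 2.0
    hi = brentq(f, xhat, xr, xtol=1e-10)
    return xhat / d, lo / d, hi / d


def sampling_probability(lam: float, d: float) -> float:
    """Detection probability ``1 - exp(-lam*d)`` over an interval of length d."""
    if lam < 0:
        raise ValueError("rate must be non-negative")
    if d <= 0:
        raise ValueError("duration must be positive")
    return -math.expm1(-lam * d)


# ---------------------------------------------------------------------------
# binomial richness estimation


def _binom_loglik(N, n_obs: int, p: float):
    """log Binomial(n_obs; N, p) up to the constant -log(n_obs!)."""
    N = np.asarray(N, dtype=float)
    return gammaln(N + 1) - gammaln(N - n_obs + 1) + (N - n_obs) * math.log1p(-p)


def estimate_richness(n_obs: int, p: float) -> int:
    """Integer N >= n_obs maximising the binomial likelihood of n_obs successes.

    The likelihood ratio L(N)/L(N-1) = N(1-p)/(N-n_obs) exceeds 1 precisely
    while N < n_obs/p, so the maximiser is floor(n_obs/p); an exact tie
    (n_obs/p integral, L equal at n_obs/p and n_obs/p - 1) is broken towards
    the larger N. Computed in exact rational arithmetic on the binary value
    of ``p`` so the result is exact at any magnitude.
    """
    if n_obs < 0:
        raise ValueError("n_obs must be non-negative")
    if not 0.0 < p <= 1.0:
        raise ValueError("richness is not estimable at p = 0 (unbounded)")
    if n_obs == 0:
        return 0
    return max(n_obs, math.floor(Fraction(n_obs) / Fraction(p)))


def _richness_profile_bounds(n_obs: int, p: float, halfq: float) -> tuple[int, int]:
    """Chi-square profile-likelihood bounds for N at fixed p."""
    nhat = estimate_richness(n_obs, p)
    cutoff = float(_binom_loglik(nhat, n_obs, p)) - halfq

    def ok(N: int) -> bool:
        return float(_binom_loglik(N, n_obs, p)) >= cutoff

    # likelihood is unimodal in N: bisect on each flank
    lo_lo, lo_hi = n_obs, nhat
    while lo_lo < lo_hi:  # smallest N with ll >= cutoff
        mid = (lo_lo + lo_hi) // 2
        if ok(mid):
            lo_hi = mid
        else:
            lo_lo = mid + 1
    step = 1
    hi = nhat
    while ok(hi + step):  # grow past the upper crossing
        hi += step
        step *= 2
    hi_lo, hi_hi = hi, hi + step
    while hi_lo < hi_hi:  # largest N with ll >= cutoff
        mid = (hi_lo + hi_hi + 1) // 2
        if ok(mid):
            hi_lo = mid
        else:
            hi_hi = mid - 1
    return lo_lo, hi_lo


def richness_interval(
    n_obs: int, p_lo: float, p_hi: float, conf: float = 0.95
) -> tuple[int, float]:
    """Confidence bounds on true richness from the bounds on p.

    The lower richness bound is the profile-likelihood lower bound of the
    binomial likelihood in N at ``p_hi``; the upper richness bound is the
    profile upper bound at ``p_lo``. ``p_lo == 0`` gives an unbounded upper
    limit, returned as ``inf``.
    """
    if not 0.0 <= p_lo <= p_hi <= 1.0:
        raise ValueError("require 0 <= p_lo <= p_hi <= 1")
    if n_obs < 0:
        raise ValueError("n_obs must be non-negative")
    if n_obs == 0:
        return 0, 0.0 if p_lo > 0 else math.inf
    halfq = _halfq(conf)
    if p_hi == 1.0:
        n_lo = n_obs  # certain detection: no unseen species below
    else:
        n_lo, _ = _richness_profile_bounds(n_obs, p_hi, halfq)
    if p_lo == 1.0:
        return n_lo, float(n_obs)
    # p_lo so small that the bound exceeds any meaningful richness: report
    # it as unbounded rather than overflowing the log-gamma evaluation
    if p_lo == 0.0 or n_obs / p_lo > 1e15:
        return n_lo, math.inf
    _, n_hi = _richness_profile_bounds(n_obs, p_lo, halfq)
    return n_lo, float(n_hi)


# ---------------------------------------------------------------------------
# per-stage chaining and replicate aggregation


def trips_stage(
    counts: Sequence[int],
    d: float,
    stage: str = "",
    conf: float = 0.95,
) -> tuple[SamplingEstimate, RichnessEstimate]:
    """Run the full TRiPS chain on one stage's observation counts.

    ``counts`` holds one positive entry per observed taxon. An empty column
    or all-singleton data is flagged non-estimable: the richness estimate
    then falls back to the observed count with an unbounded upper limit.
    """
    counts = np.asarray(counts)
    n_obs = int(counts.size)
    if n_obs == 0:
        samp = SamplingEstimate(
            stage, d, 0, math.nan, math.nan, math.nan, math.nan, math.nan, math.nan, False
        )
        return samp, RichnessEstimate(stage, 0, 0, 0, 0)
    lam, lam_lo, lam_hi = estimate_lambda(counts, d, conf=conf)
    p = sampling_probability(lam, d)
    p_lo = sampling_probability(lam_lo, d)
    p_hi = sampling_probability(lam_hi, d)
    estimable = lam > 0.0
    samp = SamplingEstimate(
        stage, d, n_obs, lam, lam_lo, lam_hi, p, p_lo, p_hi, estimable
    )
    if not estimable:
        rich = RichnessEstimate(stage, n_obs, n_obs, n_obs, math.inf)
    else:
        n_true = estimate_richness(n_obs, p)
        n_lo, n_hi = richness_interval(n_obs, p_lo, p_hi, conf=conf)
        rich = RichnessEstimate(stage, n_obs, n_true, n_lo, n_hi)
    return samp, rich


def trips_replicated(replicates, ts, rank: str | None = None, conf: float = 0.95):
    """TRiPS over replicate count matrices, aggregated by per-stage medians.

    For each stage, the sampling rate and its CI bounds are the medians of
    the per-replicate values, the observed richness is the median of the
    per-replicate observed richness (rounded half up), and richness is
    re-estimated from those medians. Returns
    ``(sampling_estimates, richness_estimates, per_replicate_frame)`` with
    one entry per stage of ``ts``.

    A stage is estimable when its median rate is positive; replicates where
    the rate could not be estimated (no data or all singletons) enter the
    median as 0.
    """
    import pandas as pd

    replicates = list(replicates)
    if not replicates:
        raise ValueError("need at least one replicate")
    rows = []
    for r, mat in enumerate(replicates):
        for stage in ts:
            col = mat.stage_counts(stage.name)
            samp, rich = trips_stage(col, stage.duration, stage.name, conf=conf)
            rows.append(
                {
                    "replicate": r,
                    "stage": stage.name,
                    "duration": stage.duration,
                    "n_observed": samp.n_observed,
                    "lambda_hat": samp.lambda_hat if samp.n_observed else 0.0,
                    "lambda_lo": samp.lambda_lo if samp.n_observed else 0.0,
                    "lambda_hi": samp.lambda_hi if samp.n_observed else 0.0,
                    "estimable": samp.estimable,
                    "n_true": rich.n_true,
                }
            )
    table = pd.DataFrame(rows)
    samp_out, rich_out = [], []
    for stage in ts:
        sub = table[table["stage"] == stage.name]
        d = stage.duration
        lam = float(sub["lambda_hat"].median())
        lam_lo = float(sub["lambda_lo"].median())
        lam_hi = float(sub["lambda_hi"].median())
        n_obs = int(math.floor(sub["n_observed"].median() + 0.5))
        estimable = lam > 0.0 and n_obs > 0
        p = sampling_probability(lam, d) if n_obs else math.nan
        p_lo = sampling_probability(lam_lo, d) if n_obs else math.nan
        p_hi = sampling_probability(lam_hi, d) if n_obs else math.nan
        samp_out.append(
            SamplingEstimate(
                stage.name, d, n_obs, lam, lam_lo, lam_hi, p, p_lo, p_hi, estimable
            )
        )
        if not estimable:
            hi = math.inf if n_obs else 0
            rich_out.append(RichnessEstimate(stage.name, n_obs, n_obs, n_obs, hi))
        else:
            n_true = estimate_richness(n_obs, p)
            n_lo, n_hi = richness_interval(n_obs, p_lo, p_hi, conf=conf)
            rich_out.append(RichnessEstimate(stage.name, n_obs, n_true, n_lo, n_hi))
    return samp_out, rich_out, table


def estimates_to_frame(sampling, richness):
    """Join per-stage sampling and richness estimates into one DataFrame."""
    import pandas as pd

    srows = [s.to_dict() for s in sampling]
    rrows = [r.to_dict() for r in richness]
    sf = pd.DataFrame(srows)
    rf = pd.DataFrame(rrows).drop(columns=["n_observed"])
    return sf.merge(rf, on="stage")
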