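"""Simulation study: coverage, bias and accuracy of the richness estimator.

For each simulated clade the estimator sees only the fossil counts of the
observed lineages and the window duration, exactly as it would see one
stage of an occurrence count matrix. Three metrics summarise performance:

* success rate -- the fraction of simulations whose 95% confidence
  interval contains the true value (richness, or the clade-mean sampling
  rate);
* mean scaled error -- the signed mean of (estimate - truth) / truth, a
  relative-bias measure;
* Pearson's product-moment correlation between true and estimated
  richness.

Simulations where the rate is not estimable (nothing sampled, or every
observed lineage a singleton) have no richness estimate; per the headline
convention they count as coverage failures, and rates over the estimable
subset are reported alongside.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from . import core
from .simulator import ParamSpace, SimResult, counts_from_sim, draw_params, simulate_clade

__all__ = [
    "EvalSummary",
    "run_study",
    "coverage",
    "mean_scaled_error",
    "success_surface",
]


@dataclass
class EvalSummary:
    """Headline metrics of one simulation study."""

    n_sims: int
    n_estimable: int
    n_zero_observed: int
    success_rate_richness: float
    success_rate_lambda: float
    success_rate_richness_estimable: float
    success_rate_lambda_estimable: float
    mean_scaled_error: float
    mean_scaled_error_magnitude: float
    pearson_rho: float
    pearson_rho_with_fallback: float

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def coverage(flags) -> float:
    """Fraction of simulations whose CI contained the true value."""
    flags = np.asarray(flags, dtype=bool)
    if flags.size == 0:
        raise ValueError("no simulations to summarise")
    return float(flags.mean())


def mean_scaled_error(estimates, truths) -> float:
    """Signed mean of (estimate - truth)/truth; zero truths are excluded."""
    estimates = np.asarray(estimates, dtype=float)
    truths = np.asarray(truths, dtype=float)
    if estimates.shape != truths.shape:
        raise ValueError("estimates and truths must have equal length")
    keep = truths > 0
    if not keep.all():
        warnings.warn(f"excluding {int((~keep).sum())} pair(s) with zero truth")
    if not keep.any():
        raise ValueError("no pairs with positive truth")
    return float(((estimates[keep] - truths[keep]) / truths[keep]).mean())


def _evaluate_sim(result: SimResult, conf: float) -> dict:
    """TRiPS on one realisation, with truth comparisons."""
    p = result.params
    row = result.to_row()
    counts = counts_from_sim(result)
    samp, rich = core.trips_stage(counts, p.duration, conf=conf)
    estimable = samp.estimable
    row.update(
        estimable=estimable,
        lambda_hat=samp.lambda_hat,
        lambda_lo=samp.lambda_lo,
        lambda_hi=samp.lambda_hi,
        p_hat=samp.p_hat,
        n_true_hat=rich.n_true if estimable else np.nan,
        n_lo=rich.n_lo,
        n_hi=rich.n_hi,
        frac_observed=row["n_observed"] / row["true_richness"],
    )
    if estimable:
        row["covered_richness"] = rich.n_lo <= result.true_richness <= rich.n_hi
        row["covered_lambda"] = samp.lambda_lo <= p.mean_sampling <= samp.lambda_hi
    else:
        row["covered_richness"] = False
        row["covered_lambda"] = False
    return row


def run_study(
    space: ParamSpace | None = None,
    n_sims: int = 10_000,
    seed: int | None = None,
    conf: float = 0.95,
) -> tuple[EvalSummary, pd.DataFrame]:
    """Draw parameters, simulate, estimate and score ``n_sims`` clades.

    Fully reproducible from ``seed``: a master seed spawns one child
    stream per simulation.
    """
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    space = space or ParamSpace()
    children = np.random.SeedSequence(seed).spawn(n_sims)
    rows = []
    for child in children:
        rng = np.random.default_rng(child)
        params = draw_params(space, rng)
        result = simulate_clade(params, rng)
        rows.append(_evaluate_sim(result, conf))
    table = pd.DataFrame(rows)
    return summarise(table), table


def summarise(table: pd.DataFrame) -> EvalSummary:
    """Aggregate a per-simulation table into the headline metrics."""
    est = table[table["estimable"]]
    n_est = len(est)
    if n_est >= 2:
        mse = mean_scaled_error(est["n_true_hat"], est["true_richness"])
        mse_mag = float(
            np.abs(
                (est["n_true_hat"] - est["true_richness"]) / est["true_richness"]
            ).mean()
        )
        rho = float(pearsonr(est["true_richness"], est["n_true_hat"])[0])
        # fallback: non-estimable sims contribute their observed richness
        fallback = table["n_true_hat"].fillna(table["n_observed"])
        rho_all = float(pearsonr(table["true_richness"], fallback)[0])
    else:
        mse = mse_mag = rho = rho_all = math.nan
    return EvalSummary(
        n_sims=len(table),
        n_estimable=n_est,
        n_zero_observed=int((table["n_observed"] == 0).sum()),
        success_rate_richness=coverage(table["covered_richness"]),
        success_rate_lambda=coverage(table["covered_lambda"]),
        success_rate_richness_estimable=(
            coverage(est["covered_richness"]) if n_est else math.nan
        ),
        success_rate_lambda_estimable=(
            coverage(est["covered_lambda"]) if n_est else math.nan
        ),
        mean_scaled_error=mse,
        mean_scaled_error_magnitude=mse_mag,
        pearson_rho=rho,
        pearson_rho_with_fallback=rho_all,
    )


def success_surface(
    table: pd.DataFrame,
    duration_bins=None,
    rate_bins=None,
    which: str = "covered_richness",
) -> pd.DataFrame:
    """Mean coverage per (duration x clade-mean sampling rate) bin.

    Returns a long-format frame with bin edges, per-bin simulation counts
    and success rates; empty bins carry ``NaN`` and ``n = 0``.
    """
    duration_bins = np.asarray(
        duration_bins if duration_bins is not None else np.linspace(2, 20, 7)
    )
    rate_bins = np.asarray(
        rate_bins if rate_bins is not None else np.linspace(0, 1.5, 7)
    )
    d_idx = pd.cut(table["duration"], duration_bins, include_lowest=True)
    r_idx = pd.cut(table["mean_sampling"], rate_bins, include_lowest=True)
    grouped = table.groupby([d_idx, r_idx], observed=False)[which]
    out = grouped.agg(success_rate="mean", n="size").reset_index()
    out.loc[out["n"] == 0, "success_rate"] = np.nan
    return out
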