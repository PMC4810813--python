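"""Estimator unit tests, checked against independent brute-force oracles.

The rate MLE is checked against a dense grid search over the truncated
Poisson likelihood; the integer richness MLE against exhaustive evaluation
of the binomial likelihood. Frozen expected values below were produced by
those oracles.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import gammaln
from scipy.stats import poisson

from conftest import make_matrix
from trips import core
from trips.timescale import Stage, Timescale


# ---------------------------------------------------------------------------
# independent oracles


def grid_lambda_mle(counts, d, lam_max=10.0, step=1e-4):
    """Grid-search maximiser of the truncated-Poisson likelihood product."""
    lams = np.arange(step, lam_max, step)
    x = lams[:, None] * d
    counts = np.asarray(counts)
    ll = (counts * np.log(x) - x - np.log1p(-np.exp(-x))).sum(axis=1)
    return lams[np.argmax(ll)]


def brute_richness_mle(n_obs, p, n_max=None):
    """Exhaustive binomial-likelihood maximiser.

    Exact ties (n_obs/p integral) have probability zero for continuously
    drawn p; the documented tie-to-larger rule is asserted separately on a
    constructed tie.
    """
    n_max = n_max or int(np.ceil(n_obs / p)) + 50
    Ns = np.arange(n_obs, n_max + 1)
    ll = gammaln(Ns + 1) - gammaln(Ns - n_obs + 1) + (Ns - n_obs) * np.log1p(-p)
    return int(Ns[np.argmax(ll)])


# ---------------------------------------------------------------------------
# truncated-Poisson log-likelihood


class TestLoglikLambda:
    def test_matches_truncated_poisson_pmf(self):
        # log[ P(O=1 | lam*d=1, O>0) ] = log[ e^-1 / (1 - e^-1) ]
        expected = math.log(poisson.pmf(1, 1.0) / (1 - poisson.pmf(0, 1.0)))
        assert core.loglik_lambda([1], 1.0, 1.0) == pytest.approx(expected)
        assert expected == pytest.approx(-0.541324854612918)

    def test_additive_over_lineages(self):
        one = core.loglik_lambda([2], 1.0, 2.0)
        assert core.loglik_lambda([2, 2], 1.0, 2.0) == pytest.approx(2 * one)

    def test_diverges_to_minus_infinity_in_lambda(self):
        vals = [core.loglik_lambda([2, 3], 1.0, lam) for lam in (5, 50, 500)]
        assert vals[0] > vals[1] > vals[2]
        assert vals[2] < -900

    def test_zero_rate_is_minus_infinity(self):
        assert core.loglik_lambda([1, 2], 1.0, 0.0) == -math.inf

    def test_zero_count_rejected(self):
        with pytest.raises(ValueError, match="zero-truncated"):
            core.loglik_lambda([0, 2], 1.0, 1.0)


class TestEstimateLambda:
    def test_all_singletons_give_zero(self):
        lam, lo, _ = core.estimate_lambda([1, 1, 1], 4.0)
        assert lam == 0.0 and lo == 0.0

    def test_mean_two_counts(self):
        # lam solves lam/(1-e^-lam) = 2; grid-search oracle gives 1.5936
        lam, _, _ = core.estimate_lambda([1, 2, 3], 1.0)
        assert lam == pytest.approx(1.5936, abs=2e-4)

    def test_duration_scaling(self):
        # same mean count, d=5: the rate scales down by 5
        lam, _, _ = core.estimate_lambda([2], 5.0)
        assert lam == pytest.approx(1.5936 / 5, abs=1e-4)

    def test_matches_grid_search_on_random_vectors(self, rng):
        for _ in range(50):
            counts = rng.integers(1, 7, size=rng.integers(1, 11))
            if counts.mean() <= 1.0:
                continue
            lam, _, _ = core.estimate_lambda(counts, 1.0)
            assert lam == pytest.approx(grid_lambda_mle(counts, 1.0), abs=1.5e-4)

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.integers(1, 6), min_size=1, max_size=10),
           st.floats(0.5, 20.0))
    def test_moment_identity(self, counts, d):
        """x/(1 - e^-x) at the MLE equals the sample mean of the counts."""
        lam, _, _ = core.estimate_lambda(counts, d)
        if lam == 0.0:
            assert np.mean(counts) == 1.0
        else:
            x = lam * d
            assert x / -math.expm1(-x) == pytest.approx(np.mean(counts), abs=1e-6)

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.integers(1, 6), min_size=2, max_size=12),
           st.floats(0.5, 20.0))
    def test_profile_ci_drops_half_chi2(self, counts, d):
        """Log-likelihood at both CI bounds sits 1.9207 below the maximum."""
        lam, lo, hi = core.estimate_lambda(counts, d)
        if lam == 0.0:
            return
        llmax = core.loglik_lambda(counts, d, lam)
        drop = core.CHI2_95_1 / 2
        assert core.loglik_lambda(counts, d, lo) - llmax == pytest.approx(-drop, abs=1e-4)
        assert core.loglik_lambda(counts, d, hi) - llmax == pytest.approx(-drop, abs=1e-4)
        assert 0 <= lo <= lam <= hi


class TestSamplingProbability:
    def test_closed_form(self):
        assert core.sampling_probability(0.0, 3.0) == 0.0
        assert core.sampling_probability(math.log(2), 1.0) == pytest.approx(0.5)
        assert core.sampling_probability(0.2, 5.0) == pytest.approx(1 - math.exp(-1))

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            core.sampling_probability(-0.1, 1.0)


class TestEstimateRichness:
    @pytest.mark.parametrize(
        "n_obs,p,expected",
        [
            (10, 1.0, 10),    # perfect sampling
            (10, 0.3, 33),    # brute-force oracle
            (10, 0.5, 20),    # tie L(19)=L(20), broken to larger
            (0, 0.5, 0),
        ],
    )
    def test_known_values(self, n_obs, p, expected):
        assert core.estimate_richness(n_obs, p) == expected

    def test_tie_is_exact(self):
        ll = lambda N: gammaln(N + 1) - gammaln(N - 10 + 1) + (N - 10) * np.log1p(-0.5)
        assert ll(19) == pytest.approx(ll(20))

    def test_matches_exhaustive_search(self, rng):
        for _ in range(200):
            n = int(rng.integers(1, 51))
            p = float(rng.uniform(0.05, 1.0))
            assert core.estimate_richness(n, p) == brute_richness_mle(n, p)

    def test_zero_probability_rejected(self):
        with pytest.raises(ValueError, match="not estimable"):
            core.estimate_richness(10, 0.0)

    @settings(deadline=None, max_examples=60)
    @given(st.integers(1, 200), st.floats(0.01, 0.99), st.floats(0.01, 0.99))
    def test_monotone_in_p(self, n, p1, p2):
        lo, hi = sorted([p1, p2])
        assert core.estimate_richness(n, lo) >= core.estimate_richness(n, hi)

    @settings(deadline=None, max_examples=60)
    @given(st.integers(0, 200), st.integers(0, 200), st.floats(0.01, 0.99))
    def test_monotone_in_n_obs(self, n1, n2, p):
        lo, hi = sorted([n1, n2])
        assert core.estimate_richness(lo, p) <= core.estimate_richness(hi, p)


class TestRichnessInterval:
    def test_certain_detection_collapses_interval(self):
        assert core.richness_interval(10, 1.0, 1.0) == (10, 10.0)

    def test_nothing_observed(self):
        assert core.richness_interval(0, 0.2, 0.8) == (0, 0.0)

    def test_ordering_and_containment(self):
        lo, hi = core.richness_interval(40, 0.3, 0.7)
        n_hat = core.estimate_richness(40, 0.5)
        assert lo <= n_hat <= hi

    def test_unbounded_at_zero_lower_probability(self):
        lo, hi = core.richness_interval(10, 0.0, 0.8)
        assert hi == math.inf and lo >= 10 // 1

    def test_bounds_sit_at_profile_cutoff(self):
        """Each bound is the extreme N whose binomial log-likelihood is
        within half the chi-square cutoff of the maximum at that p."""
        n, p_lo, p_hi = 60, 0.3, 0.6

        def ll(N, p):
            return gammaln(N + 1) - gammaln(N - n + 1) + (N - n) * np.log1p(-p)

        lo, hi = core.richness_interval(n, p_lo, p_hi)
        hi = int(hi)
        cut = core.CHI2_95_1 / 2
        assert ll(lo, p_hi) >= ll(core.estimate_richness(n, p_hi), p_hi) - cut
        assert ll(lo - 1, p_hi) < ll(core.estimate_richness(n, p_hi), p_hi) - cut
        assert ll(hi, p_lo) >= ll(core.estimate_richness(n, p_lo), p_lo) - cut
        assert ll(hi + 1, p_lo) < ll(core.estimate_richness(n, p_lo), p_lo) - cut


class TestTripsStage:
    def test_all_singletons_not_estimable(self):
        samp, rich = core.trips_stage([1, 1, 1], 2.0, "S")
        assert not samp.estimable
        assert samp.lambda_hat == 0.0
        assert rich.n_true == rich.n_observed == 3
        assert rich.n_hi == math.inf

    def test_empty_column_flagged(self):
        samp, rich = core.trips_stage([], 2.0, "S")
        assert not samp.estimable and samp.n_observed == 0
        assert rich.n_true == 0

    def test_chain_matches_direct_calls(self):
        # grid-search oracle: 2*lam/(1 - e^-2lam) = 3
        counts, d = [3, 3, 3], 2.0
        samp, rich = core.trips_stage(counts, d, "S")
        lam, lam_lo, lam_hi = core.estimate_lambda(counts, d)
        assert samp.lambda_hat == pytest.approx(lam)
        assert samp.lambda_hat == pytest.approx(grid_lambda_mle(counts, d), abs=1e-4)
        p = core.sampling_probability(lam, d)
        assert samp.p_hat == pytest.approx(p)
        assert rich.n_true == core.estimate_richness(3, p)
        assert (rich.n_lo, rich.n_hi) == core.richness_interval(
            3,
            core.sampling_probability(lam_lo, d),
            core.sampling_probability(lam_hi, d),
        )

    def test_p_bounds_are_monotone_transforms(self):
        samp, _ = core.trips_stage([2, 4, 1, 3], 3.0, "S")
        for lam, p in [(samp.lambda_hat, samp.p_hat), (samp.lambda_lo, samp.p_lo),
                       (samp.lambda_hi, samp.p_hi)]:
            assert p == pytest.approx(core.sampling_probability(lam, 3.0))
        assert samp.p_lo <= samp.p_hat <= samp.p_hi


class TestTripsReplicated:
    ts = Timescale([Stage("A", 10.0, 6.0), Stage("B", 6.0, 2.0)])

    def test_single_replicate_equals_trips_stage(self):
        mat = make_matrix({"t1": [3, 0], "t2": [2, 1], "t3": [0, 1]}, ["A", "B"])
        samp, rich, _ = core.trips_replicated([mat], self.ts)
        direct = core.trips_stage(mat.stage_counts("A"), 4.0, "A")
        assert samp[0].lambda_hat == pytest.approx(direct[0].lambda_hat)
        assert rich[0].n_true == direct[1].n_true

    def test_identical_replicates_reproduce_common_value(self):
        mat = make_matrix({"t1": [3, 0], "t2": [2, 2]}, ["A", "B"])
        samp1, rich1, _ = core.trips_replicated([mat] * 3, self.ts)
        samp2, rich2, _ = core.trips_replicated([mat], self.ts)
        assert samp1[0].lambda_hat == pytest.approx(samp2[0].lambda_hat)
        assert rich1[0].n_true == rich2[0].n_true

    def test_median_rate_used_downstream(self):
        # three replicates with different stage-A counts -> median lambda
        mats = [
            make_matrix({"t1": [c, 0], "t2": [c, 0]}, ["A", "B"])
            for c in (2, 3, 5)
        ]
        samp, _, table = core.trips_replicated(mats, self.ts)
        lams = sorted(
            core.estimate_lambda([c, c], 4.0)[0] for c in (2, 3, 5)
        )
        assert samp[0].lambda_hat == pytest.approx(lams[1])
        assert len(table) == 6  # 3 replicates x 2 stages

    def test_empty_replicate_list_rejected(self):
        with pytest.raises(ValueError):
            core.trips_replicated([], self.ts)
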