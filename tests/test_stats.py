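"""Exact multinomial test, KS machinery, likelihood and posterior density."""

import itertools
import math

import numpy as np
import pytest
from scipy.special import kolmogorov
from scipy.stats import ks_2samp

from stabflex.params import FittedParams, Priors, reference_subject
from stabflex.stats import (
    SummaryStats,
    exact_multinomial_p,
    ks2_probability,
    ks2_statistic,
    log_likelihood,
    log_posterior,
    simulate_summary,
    summarize,
)
from stabflex.task import simulate_dataset


def brute_force_multinomial_p(observed, probs):
    """Direct enumeration oracle for small N."""
    N = sum(observed)
    probs = np.asarray(probs, dtype=float)
    probs = probs / probs.sum()

    def pmf(x):
        p = math.factorial(N)
        for xi, pi in zip(x, probs):
            p /= math.factorial(xi)
            p *= pi**xi
        return p

    p0 = pmf(observed)
    total = 0.0
    for x in itertools.product(range(N + 1), repeat=4):
        if sum(x) != N:
            continue
        px = pmf(x)
        if px <= p0 * (1 + 1e-12):
            total += px
    return min(total, 1.0)


class TestExactMultinomial:
    def test_uniform_modal_outcome_has_p_one(self):
        assert exact_multinomial_p([1, 1, 1, 1], [0.25] * 4) == pytest.approx(1.0)

    def test_observation_in_zero_probability_category(self):
        assert exact_multinomial_p([3, 0, 0, 1], [0.5, 0.3, 0.2, 0.0]) == 0.0

    def test_empty_sample_convention(self):
        assert exact_multinomial_p([0, 0, 0, 0], [0.25] * 4) == 1.0

    @pytest.mark.parametrize(
        "observed,probs",
        [
            ([4, 1, 2, 1], [0.4, 0.2, 0.25, 0.15]),
            ([8, 0, 0, 0], [0.7, 0.1, 0.1, 0.1]),
            ([2, 2, 2, 2], [0.25, 0.25, 0.25, 0.25]),
            ([0, 3, 0, 3], [0.05, 0.45, 0.05, 0.45]),
            ([5, 1, 0, 0], [0.5, 0.5, 0.0, 0.0]),
        ],
    )
    def test_matches_brute_force_enumeration(self, observed, probs):
        assert exact_multinomial_p(observed, probs) == pytest.approx(
            brute_force_multinomial_p(observed, probs), rel=1e-10
        )

    def test_agrees_with_binomial_on_two_categories(self):
        """Reduces to the two-sided exact binomial when two cells are empty."""
        from scipy.stats import binom

        obs = [14, 6, 0, 0]
        q = 0.45
        got = exact_multinomial_p(obs, [q, 1 - q, 0, 0])
        # two-sided binomial by summation of outcomes no more likely
        n = 20
        p0 = binom.pmf(obs[0], n, q)
        want = sum(
            binom.pmf(k, n, q) for k in range(n + 1) if binom.pmf(k, n, q) <= p0 * (1 + 1e-12)
        )
        assert got == pytest.approx(want, rel=1e-10)

    def test_category_permutation_invariance(self):
        obs = [10, 4, 3, 3]
        probs = [0.5, 0.2, 0.2, 0.1]
        p = exact_multinomial_p(obs, probs)
        for perm in ((1, 0, 3, 2), (3, 2, 1, 0), (2, 0, 1, 3)):
            assert exact_multinomial_p(
                [obs[i] for i in perm], [probs[i] for i in perm]
            ) == pytest.approx(p, rel=1e-10)

    def test_large_count_runs(self):
        p = exact_multinomial_p([120, 110, 5, 5], [0.48, 0.48, 0.02, 0.02])
        assert 0.0 <= p <= 1.0


class TestKS2:
    def test_identical_samples_give_zero(self):
        x = [1.0, 2.0, 5.0]
        assert ks2_statistic(x, x) == 0.0

    def test_separated_samples_closed_form(self):
        n = 8
        a = np.arange(n, dtype=float)
        b = a + 100
        assert ks2_statistic(a, b) == pytest.approx(math.sqrt(n / 2), rel=1e-12)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            ks2_statistic([], [1.0])

    def test_statistic_matches_reference(self, rng):
        for _ in range(100):
            n, m = rng.integers(5, 200, 2)
            a = rng.normal(0, 1, n)
            b = rng.normal(0.3, 1.2, m)
            ref = ks_2samp(a, b, method="asymp")
            assert ks2_statistic(a, b) == pytest.approx(
                ref.statistic * math.sqrt(n * m / (n + m)), rel=1e-9
            )

    def test_probability_matches_reference_series(self):
        for D in np.linspace(0.3, 3.0, 28):
            assert ks2_probability(float(D)) == pytest.approx(kolmogorov(D), abs=1e-3)

    def test_probability_limits_and_monotonicity(self):
        assert ks2_probability(0.0) == 1.0
        assert ks2_probability(50.0) == pytest.approx(0.0, abs=1e-12)
        grid = np.linspace(0.0, 4.0, 200)
        vals = [ks2_probability(float(d)) for d in grid]
        assert all(b <= a + 1e-12 for a, b in zip(vals, vals[1:]))

    def test_pvalue_on_samples_matches_kolmogorov_limit(self, rng):
        """Sample-level p-values equal the Kolmogorov survival function of
        the scaled statistic (scipy's ks_2samp additionally applies a
        finite-sample correction, so the statistic -- not its p -- is the
        shared reference)."""
        for _ in range(50):
            n, m = rng.integers(20, 150, 2)
            a = rng.normal(0, 1, n)
            b = rng.normal(0.2, 1, m)
            D = ks_2samp(a, b).statistic * math.sqrt(n * m / (n + m))
            got = ks2_probability(ks2_statistic(a, b))
            assert got == pytest.approx(kolmogorov(D), abs=1e-9)


def _stats_from(counts, rts, n_total=None):
    st = SummaryStats()
    for cond, c in counts.items():
        st.counts[cond] = np.asarray(c)
        st.n_total[cond] = n_total or int(np.sum(c))
        st.n_none[cond] = st.n_total[cond] - int(np.sum(c))
    for key, v in rts.items():
        st.rts[key] = np.sort(np.asarray(v, dtype=float))
    return st


class TestLogLikelihood:
    def test_identical_rt_samples_contribute_nothing(self):
        """Matching counts and identical RT cells leave only the multinomial."""
        rt = np.array([400.0, 450.0, 520.0, 610.0])
        sim = _stats_from(
            {"baseline": [60, 60, 4, 4]}, {("baseline", "odd"): rt}, n_total=128
        )
        sub_counts = [15, 15, 1, 1]
        sub = _stats_from({"baseline": sub_counts}, {("baseline", "odd"): rt})
        got = log_likelihood(sub, sim)
        from scipy.special import gammaln

        p = np.array([60, 60, 4, 4]) / 128
        p = np.maximum(p, 1 / 256)
        p /= p.sum()
        want = float(
            gammaln(33) - gammaln(np.array(sub_counts) + 1.0).sum()
            + np.sum(np.array(sub_counts) * np.log(p))
        )
        assert got == pytest.approx(want, rel=1e-12)

    def test_removing_condition_removes_its_terms(self):
        rt = np.array([400.0, 450.0, 520.0])
        sim = _stats_from(
            {"baseline": [50, 50, 0, 0], "switch": [0, 0, 50, 50]},
            {("baseline", "odd"): rt, ("switch", "gt5"): rt},
            n_total=100,
        )
        sub_full = _stats_from(
            {"baseline": [10, 10, 0, 0], "switch": [0, 0, 10, 10]},
            {("baseline", "odd"): rt, ("switch", "gt5"): rt},
        )
        sub_base = _stats_from(
            {"baseline": [10, 10, 0, 0]}, {("baseline", "odd"): rt}
        )
        full = log_likelihood(sub_full, sim)
        base_only = log_likelihood(sub_base, sim)
        sub_sw = _stats_from({"switch": [0, 0, 10, 10]}, {("switch", "gt5"): rt})
        assert full == pytest.approx(base_only + log_likelihood(sub_sw, sim), rel=1e-12)

    def test_missing_condition_raises(self):
        sim = _stats_from({"baseline": [10, 10, 0, 0]}, {})
        sub = _stats_from({"switch": [1, 1, 1, 1]}, {})
        with pytest.raises(ValueError, match="missing"):
            log_likelihood(sub, sim)

    def test_small_rt_cells_are_skipped(self):
        sim = _stats_from(
            {"baseline": [50, 50, 0, 0]},
            {("baseline", "odd"): [400.0, 410.0]},  # below the 3-sample minimum
            n_total=100,
        )
        sub = _stats_from(
            {"baseline": [10, 10, 0, 0]}, {("baseline", "odd"): [900.0, 950.0]}
        )
        with_cell = log_likelihood(sub, sim)
        sim2 = _stats_from({"baseline": [50, 50, 0, 0]}, {}, n_total=100)
        assert with_cell == pytest.approx(log_likelihood(sub, sim2), rel=1e-12)

    def test_self_consistency_favors_generating_parameters(self, ref_summary):
        """Data scored against its own parameters beats mismatched drifts."""
        theta = reference_subject()
        theta2 = theta.replace(D11=2 * theta.D11, D12=2 * theta.D12, c_plus=2 * theta.c_plus)
        diffs = []
        for rep in range(25):
            ll1 = log_likelihood(ref_summary, simulate_summary(theta, 256, rng_seed=rep, dt=2.0))
            ll2 = log_likelihood(
                ref_summary, simulate_summary(theta2, 256, rng_seed=rep, dt=2.0)
            )
            diffs.append(ll1 - ll2)
        assert np.mean(diffs) > 0


class TestLogPosterior:
    def test_prior_mode_at_prior_mean(self):
        pri = Priors()
        base = pri.log_density(pri.mu)
        for j in range(13):
            theta = pri.mu.copy()
            theta[j] += 0.03
            assert pri.log_density(theta) < base

    def test_three_sigma_shift_costs_four_and_a_half(self):
        pri = Priors()
        theta = pri.mu.copy()
        theta[0] = 1.21  # 3 prior standard deviations on s_NMDA
        assert pri.log_density(pri.mu) - pri.log_density(theta) == pytest.approx(4.5)

    def test_deterministic_under_seed(self, ref_summary):
        theta = reference_subject()
        a = log_posterior(theta, ref_summary, n_sim=64, rng_seed=5, dt=2.0)
        b = log_posterior(theta, ref_summary, n_sim=64, rng_seed=5, dt=2.0)
        assert a == b

    def test_simulate_summary_matches_dataset_summaries(self, ref_params):
        """The fast summary path agrees statistically with the dataset path."""
        fast = simulate_summary(ref_params, 4000, rng_seed=1)
        slow = summarize(simulate_dataset(ref_params, 4000, rng_seed=2))
        for cond in ("baseline", "switch"):
            pf = fast.counts[cond] / fast.counts[cond].sum()
            ps = slow.counts[cond] / slow.counts[cond].sum()
            assert np.allclose(pf, ps, atol=0.04)
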