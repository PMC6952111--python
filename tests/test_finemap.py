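"""Fine-mapping core: MVN configuration likelihood, posterior enumeration,
PIPs and greedy rho-causal sets, checked against brute-force oracles."""

from itertools import combinations

import numpy as np
import pytest
from scipy.stats import multivariate_normal, norm, spearmanr

from aimfine import (
    BudgetExceededError,
    CausalConfig,
    CausalPrior,
    SummaryStatVector,
    config_log_likelihood,
    dense_config_log_likelihood,
    enumerate_posteriors,
    finemap,
    finemap_meta,
    joint_log_likelihood,
    pip,
    rho_causal_set,
)

from conftest import random_psd_correlation


def brute_force_posterior(s, sigma, prior):
    """Independent oracle: dense scipy MVN density for every configuration."""
    m = s.size
    k_min = 0 if prior.include_null else 1
    masks, posts = [], []
    logs = []
    for k in range(k_min, min(prior.k_max, m) + 1):
        for idx in combinations(range(m), k):
            c = np.zeros(m)
            c[list(idx)] = 1.0
            cov = sigma + prior.sigma**2 * sigma @ np.diag(c) @ sigma
            ll = multivariate_normal(np.zeros(m), cov, allow_singular=False).logpdf(s)
            logs.append(ll + prior.log_prior(k, m))
            masks.append(sum(1 << i for i in idx))
    logs = np.array(logs)
    post = np.exp(logs - logs.max())
    post /= post.sum()
    return dict(zip(masks, post))


class TestConfigLikelihood:
    def test_univariate_null(self):
        ll = config_log_likelihood(np.array([0.0]), np.eye(1), CausalConfig((), 1))
        assert ll == pytest.approx(-0.918939, abs=1e-6)

    def test_univariate_causal(self):
        # variance 1 + 5.2^2 = 28.04
        ll = config_log_likelihood(np.array([2.0]), np.eye(1), CausalConfig((0,), 1))
        assert ll == pytest.approx(norm.logpdf(2.0, 0.0, np.sqrt(28.04)), abs=1e-10)
        assert ll == pytest.approx(-2.65708, abs=1e-5)

    def test_null_config_is_plain_mvn(self, rng):
        sigma = random_psd_correlation(rng, 6, 100)
        s = rng.standard_normal(6)
        ll = config_log_likelihood(s, sigma, CausalConfig((), 6))
        assert ll == pytest.approx(multivariate_normal(np.zeros(6), sigma).logpdf(s), abs=1e-8)

    def test_low_rank_equals_dense(self, rng):
        """Woodbury evaluation agrees with the dense-Cholesky form on
        random m=50, k<=3 instances."""
        for _ in range(100):
            sigma = random_psd_correlation(rng, 50, 70)
            sigma = (sigma + 1e-3 * np.eye(50)) / (1 + 1e-3)
            s = rng.standard_normal(50) * 3
            k = int(rng.integers(1, 4))
            idx = tuple(sorted(rng.choice(50, k, replace=False).tolist()))
            cfg = CausalConfig(idx, 50)
            assert config_log_likelihood(s, sigma, cfg) == pytest.approx(
                dense_config_log_likelihood(s, sigma, cfg), abs=1e-8
            )


class TestEnumeration:
    @pytest.mark.parametrize("include_null", [False, True])
    @pytest.mark.parametrize("m", [5, 8])
    def test_matches_brute_force_oracle(self, rng, m, include_null):
        prior = CausalPrior(k_max=3, include_null=include_null)
        sigma = random_psd_correlation(rng, m, 100)
        sigma = (sigma + 1e-3 * np.eye(m)) / (1 + 1e-3)
        s = rng.standard_normal(m)
        s[m // 2] = 5.0
        table = enumerate_posteriors(s, sigma, prior)
        oracle = brute_force_posterior(s, sigma, prior)
        ours = dict(zip((int(x) for x in table.masks), table.posterior))
        assert set(ours) == set(oracle)
        assert max(abs(ours[k] - oracle[k]) for k in oracle) < 1e-10

    def test_posterior_sums_to_one(self, rng):
        sigma = random_psd_correlation(rng, 10, 100)
        sigma = (sigma + 1e-3 * np.eye(10)) / (1 + 1e-3)
        table = enumerate_posteriors(rng.standard_normal(10), sigma, CausalPrior(k_max=3))
        assert table.posterior.sum() == pytest.approx(1.0, abs=1e-10)

    def test_null_config_dominates_null_data_when_allowed(self):
        """m=1 with the null configuration in the model space: s=0 puts most
        posterior mass on 'no causal variant'."""
        prior = CausalPrior(include_null=True, k_max=1)
        table = enumerate_posteriors(np.array([0.0]), np.eye(1), prior)
        null_mass = table.posterior[table.k == 0][0]
        assert null_mass > 0.5

    def test_clear_signal_gets_all_pip(self):
        prior = CausalPrior(k_max=2)
        table = enumerate_posteriors(np.array([6.0, 0.0]), np.eye(2), prior)
        pips = pip(table)
        assert pips[0] > 0.99 and pips[1] < 0.05

    def test_pip_matches_brute_force_summation(self, rng):
        m = 6
        sigma = random_psd_correlation(rng, m, 80)
        sigma = (sigma + 1e-3 * np.eye(m)) / (1 + 1e-3)
        s = rng.standard_normal(m) * 2
        prior = CausalPrior(k_max=3)
        table = enumerate_posteriors(s, sigma, prior)
        oracle = brute_force_posterior(s, sigma, prior)
        for j in range(m):
            expected = sum(p for mask, p in oracle.items() if mask >> j & 1)
            assert pip(table)[j] == pytest.approx(expected, abs=1e-10)

    def test_exchangeable_variants_get_equal_pips(self):
        sigma = np.array([[1.0, 0.999], [0.999, 1.0]])
        sigma = (sigma + 1e-3 * np.eye(2)) / (1 + 1e-3)
        table = enumerate_posteriors(np.array([4.0, 4.0]), sigma, CausalPrior(k_max=2))
        pips = pip(table)
        assert pips[0] == pytest.approx(pips[1], abs=1e-6)

    def test_budget_guard(self):
        with pytest.raises(BudgetExceededError):
            enumerate_posteriors(
                np.zeros(50), np.eye(50), CausalPrior(k_max=6), config_budget=10_000
            )


class TestRhoCausalSet:
    def _random_table(self, rng, m=8):
        sigma = random_psd_correlation(rng, m, 60)
        sigma = (sigma + 1e-3 * np.eye(m)) / (1 + 1e-3)
        s = rng.standard_normal(m) * rng.uniform(0.5, 3.0)
        return enumerate_posteriors(s, sigma, CausalPrior(k_max=3))

    def test_greedy_vs_exhaustive_minimal_set(self, rng):
        """Greedy always reaches rho; its size is never below the exhaustive
        minimum and matches it in the vast majority of random tables."""
        rho = 0.95
        equal = 0
        n_tables = 200
        for _ in range(n_tables):
            table = self._random_table(rng)
            greedy = rho_causal_set(table, rho)
            assert greedy.mass >= rho
            post, masks = table.posterior, table.masks
            best = None
            for size in range(table.m + 1):
                for K in combinations(range(table.m), size):
                    kmask = np.uint64(sum(1 << i for i in K))
                    if post[(masks & ~kmask) == 0].sum() >= rho:
                        best = size
                        break
                if best is not None:
                    break
            assert greedy.size >= best
            equal += greedy.size == best
        assert equal / n_tables >= 0.90

    def test_monotone_in_rho(self, rng):
        table = self._random_table(rng)
        sizes = [rho_causal_set(table, r).size for r in (0.5, 0.8, 0.95, 0.99)]
        assert sizes == sorted(sizes)

    def test_dominant_singleton(self):
        table = enumerate_posteriors(
            np.array([8.0, 0.1, -0.2, 0.0]), np.eye(4), CausalPrior(k_max=2)
        )
        cset = rho_causal_set(table, 0.95)
        assert cset.variants == [0]
        assert cset.mass >= 0.95

    def test_split_mass_needs_both(self):
        sigma = np.array([[1.0, 0.999], [0.999, 1.0]])
        sigma = (sigma + 1e-3 * np.eye(2)) / (1 + 1e-3)
        table = enumerate_posteriors(np.array([5.0, 5.0]), sigma, CausalPrior(k_max=1))
        cset = rho_causal_set(table, 0.95)
        assert cset.variants == [0, 1]


class TestJointModel:
    def test_null_config_decomposes(self, rng):
        m = 4
        A = random_psd_correlation(rng, m, 100)
        E = random_psd_correlation(rng, m, 100)
        sa, se = rng.standard_normal(m), rng.standard_normal(m)
        cfg = CausalConfig((), m)
        expected = multivariate_normal(np.zeros(m), A).logpdf(sa) + multivariate_normal(
            np.zeros(m), E
        ).logpdf(se)
        assert joint_log_likelihood(sa, se, A, E, cfg) == pytest.approx(expected, abs=1e-8)

    def test_univariate_null_is_twice_standard_normal(self):
        ll = joint_log_likelihood(
            np.array([0.0]), np.array([0.0]), np.eye(1), np.eye(1), CausalConfig((), 1)
        )
        assert ll == pytest.approx(2 * -0.918939, abs=1e-5)

    def test_meta_posterior_approximates_joint_ranking(self, rng):
        """Config ranking under the meta statistic tracks the exact joint
        model (the square-vs-circle approximation)."""
        m = 5
        agreements = []
        for _ in range(10):
            E = random_psd_correlation(rng, m, 300)
            A = random_psd_correlation(rng, m, 300)
            E = (E + 1e-3 * np.eye(m)) / (1 + 1e-3)
            A = (A + 1e-3 * np.eye(m)) / (1 + 1e-3)
            causal = int(rng.integers(m))
            c = np.zeros(m)
            c[causal] = 1.0
            se = rng.multivariate_normal(5.2 * E @ c, E)
            sa = rng.multivariate_normal(5.2 * A @ c, A)
            sm1 = (sa + se) / np.sqrt(2)
            M = 0.5 * (E + A)
            prior = CausalPrior(k_max=2)
            table = enumerate_posteriors(sm1, M, prior)
            joint = np.array(
                [
                    joint_log_likelihood(sa, se, A, E, table.config_at(i), prior)
                    + table.log_prior[i]
                    for i in range(table.masks.size)
                ]
            )
            agreements.append(spearmanr(table.log_post, joint).statistic)
        assert np.mean(agreements) > 0.8


class TestFinemapMeta:
    def test_smaller_set_wins(self, rng):
        m = 6
        sigma = (np.eye(m) + 1e-3 * np.eye(m)) / (1 + 1e-3)
        sm1 = SummaryStatVector(z=np.array([7.0, 0, 0, 0, 0, 0]), kind="meta1")
        sm2 = SummaryStatVector(z=np.zeros(m), kind="meta2")
        cset = finemap_meta(sm1, sm2, sigma, CausalPrior(k_max=2))
        assert cset.kind == "meta1"
        assert cset.variants == [0]

    def test_tie_prefers_m1(self):
        m = 3
        sigma = np.eye(m)
        z = np.array([6.0, 0.0, 0.0])
        sm1 = SummaryStatVector(z=z, kind="meta1")
        sm2 = SummaryStatVector(z=z, kind="meta2")
        cset = finemap_meta(sm1, sm2, sigma, CausalPrior(k_max=2))
        assert cset.kind == "meta1"

    def test_finemap_returns_consistent_table_and_set(self, rng):
        sigma = random_psd_correlation(rng, 10, 200)
        sigma = (sigma + 1e-3 * np.eye(10)) / (1 + 1e-3)
        s = rng.standard_normal(10)
        s[3] = 6.0
        cset, table = finemap(s, sigma, CausalPrior(k_max=3))
        assert cset.mass >= 0.95
        assert 3 in cset.variants
        assert pip(table)[3] > 0.5
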