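"""Association statistics: OLS eQTL z-scores, the two-proportion AIM
z-score, correlation matrices and top-k selection."""

import numpy as np
import pytest
from scipy import stats as sps

from aimfine import (
    AIMContingency,
    DegenerateStatisticError,
    InputError,
    NoAIMIndividualsError,
    SummaryStatVector,
    aim_zscore,
    aim_zscores,
    eqtl_zscores,
    genotype_correlation,
    heterozygosity_correlation,
    regularize,
    select_top_variants,
)
from aimfine.core import CorrelationMatrix
from aimfine.stats import ExpressionPhenotype

from conftest import random_psd_correlation


def _ols_oracle(y, x):
    """Independent normal-equations oracle for one variant:
    standardize x, fit with intercept, z = beta/sigma * sqrt(n)."""
    n = y.size
    xs = (x - x.mean()) / x.std()
    X = np.column_stack([np.ones(n), xs])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    sigma = np.sqrt(resid @ resid / (n - 2))
    return coef[1] / sigma * np.sqrt(n)


class TestEqtlZscores:
    def test_matches_normal_equations_oracle(self, rng):
        y = rng.standard_normal(6)
        X = rng.integers(0, 3, size=(6, 4)).astype(float)
        X[:, 0] = [0, 1, 2, 0, 1, 2]  # ensure non-constant
        stat = eqtl_zscores(y, X)
        for j, vid in enumerate(stat.variant_ids):
            col = int(vid[1:])
            assert stat.z[j] == pytest.approx(_ols_oracle(y, X[:, col]), abs=1e-10)

    def test_orthogonal_phenotype_gives_zero(self):
        x = np.array([1.0, -1.0, 1.0, -1.0, 1.0, -1.0])
        y = np.array([1.0, 1.0, -2.0, -2.0, 1.0, 1.0])  # x @ y = 0, mean(y) = 0
        stat = eqtl_zscores(y, x[:, None])
        assert stat.z[0] == pytest.approx(0.0, abs=1e-12)

    def test_perfect_fit_raises(self):
        x = np.array([0.0, 1.0, 2.0, 0.0, 1.0, 2.0])
        with pytest.raises(DegenerateStatisticError):
            eqtl_zscores(x.copy(), x[:, None])

    def test_constant_column_dropped_with_warning(self, rng):
        y = rng.standard_normal(10)
        X = rng.integers(0, 3, size=(10, 3)).astype(float)
        X[:, 1] = 2.0
        with pytest.warns(UserWarning):
            stat = eqtl_zscores(y, X)
        assert len(stat) == 2 and "v1" not in stat.variant_ids

    def test_covariates_residualized(self, rng):
        n = 50
        z_cov = rng.standard_normal(n)
        x = rng.integers(0, 3, size=n).astype(float)
        y = 0.5 * z_cov + rng.standard_normal(n)
        direct = eqtl_zscores(ExpressionPhenotype(Y=y, Z=z_cov[:, None]), x[:, None])
        # manual residualization oracle
        D = np.column_stack([np.ones(n), z_cov])
        y_res = y - D @ np.linalg.lstsq(D, y, rcond=None)[0]
        manual = eqtl_zscores(y_res, x[:, None])
        assert direct.z[0] == pytest.approx(manual.z[0], abs=1e-10)

    def test_null_distribution_standard_normal(self, rng):
        """Under the null, z-scores across many independent variants are
        standard normal (KS sanity check)."""
        n, m = 500, 1000
        y = rng.standard_normal(n)
        X = rng.binomial(2, 0.3, size=(n, m)).astype(float)
        stat = eqtl_zscores(y, X)
        p = sps.kstest(stat.z, "norm").pvalue
        assert p > 1e-3


class TestAimZscore:
    def test_null_is_zero(self):
        cont = AIMContingency(n1=10, n2=20, p1_hat=0.4, p2_hat=0.4)
        assert aim_zscore(cont) == pytest.approx(0.0)

    def test_fully_separated_groups(self):
        # 1 / sqrt(0.5*0.5 * 10/25) = sqrt(10) = 3.16228
        cont = AIMContingency(n1=5, n2=5, p1_hat=1.0, p2_hat=0.0)
        assert aim_zscore(cont) == pytest.approx(3.16228, abs=1e-5)

    def test_antisymmetry(self):
        a = AIMContingency(n1=7, n2=13, p1_hat=0.8, p2_hat=0.3)
        b = AIMContingency(n1=13, n2=7, p1_hat=0.3, p2_hat=0.8)
        assert aim_zscore(a) == pytest.approx(-aim_zscore(b))

    def test_matches_textbook_pooled_z(self, rng):
        """Agreement with statsmodels' pooled two-proportion z-test on random
        contingency tables."""
        from statsmodels.stats.proportion import proportions_ztest

        for _ in range(200):
            n1, n2 = int(rng.integers(2, 80)), int(rng.integers(2, 80))
            k1, k2 = int(rng.integers(1, n1)), int(rng.integers(1, n2))
            cont = AIMContingency(n1=n1, n2=n2, p1_hat=k1 / n1, p2_hat=k2 / n2)
            z_ref, _ = proportions_ztest([k1, k2], [n1, n2])
            assert aim_zscore(cont) == pytest.approx(z_ref, rel=1e-9)

    def test_no_aim_individuals_raises(self):
        with pytest.raises(NoAIMIndividualsError):
            aim_zscore(AIMContingency(n1=0, n2=10, p1_hat=np.nan, p2_hat=0.5))

    def test_degenerate_het_fraction_raises(self):
        with pytest.raises(DegenerateStatisticError):
            aim_zscore(AIMContingency(n1=5, n2=5, p1_hat=1.0, p2_hat=1.0))

    def test_vectorized_flags_undefined_variants(self):
        het = np.array([[1, 1], [0, 1], [1, 1], [0, 1]])
        status = np.array([1.0, 1.0, 0.0, 0.0])
        vec, undefined = aim_zscores(het, status)
        assert undefined == [1]  # all-het column carries no information
        assert len(vec) == 1


class TestCorrelationMatrices:
    def test_duplicated_column_fully_correlated(self, rng):
        g = rng.binomial(2, 0.4, size=(100, 2)).astype(float)
        g = np.column_stack([g, g[:, 0]])
        C = genotype_correlation(g)
        assert C.values[0, 2] == pytest.approx(1.0)

    def test_complement_anticorrelated(self, rng):
        x = rng.binomial(2, 0.4, size=100).astype(float)
        C = genotype_correlation(np.column_stack([x, 2 - x]))
        assert C.values[0, 1] == pytest.approx(-1.0)

    def test_independent_variants_near_zero(self, rng):
        g = rng.binomial(2, 0.3, size=(10_000, 5)).astype(float)
        C = genotype_correlation(g)
        off = C.values[~np.eye(5, dtype=bool)]
        assert np.abs(off).max() < 0.05

    def test_het_identical_and_complementary_patterns(self, rng):
        h = rng.integers(0, 2, size=(60, 1)).astype(float)
        C = heterozygosity_correlation(np.column_stack([h, h, 1 - h]))
        assert C.values[0, 1] == pytest.approx(1.0)
        assert C.values[0, 2] == pytest.approx(-1.0)

    def test_constant_column_rejected(self):
        with pytest.raises(DegenerateStatisticError):
            genotype_correlation(np.column_stack([np.ones(10), np.arange(10.0)]))

    def test_bounds_and_symmetry(self, small_panel):
        for C in (
            genotype_correlation(small_panel.genotypes),
            heterozygosity_correlation(small_panel.het),
        ):
            assert np.abs(C.values).max() <= 1 + 1e-12
            assert np.abs(C.values - C.values.T).max() < 1e-12
            assert np.allclose(np.diag(C.values), 1.0)


class TestTopVariants:
    def test_fewer_than_k_returns_all(self):
        assert set(select_top_variants(np.array([1.0, 2.0, 3.0]), 50)) == {0, 1, 2}

    def test_magnitude_ranking(self):
        idx = select_top_variants(np.array([1.0, -9.0, 2.0]), 2)
        assert list(idx) == [1, 2]  # |-9| then |2|, brute-force sorted order

    def test_ties_broken_by_lower_index(self):
        idx = select_top_variants(np.array([2.0, -2.0, 1.0]), 1)
        assert list(idx) == [0]


class TestRegularize:
    def test_small_perturbation_when_well_conditioned(self, rng):
        C = CorrelationMatrix(random_psd_correlation(rng, 5, 50))
        R = regularize(C, ridge=1e-3)
        assert np.abs(R.values - C.values).max() <= 1e-3 + 1e-12
        assert np.allclose(np.diag(R.values), 1.0)

    def test_rank_one_all_ones_becomes_pd(self):
        C = CorrelationMatrix(np.ones((3, 3)))
        R = regularize(C)
        assert np.linalg.eigvalsh(R.values).min() > 0

    def test_cholesky_always_succeeds_on_rank_deficient_inputs(self, rng):
        for _ in range(100):
            m = int(rng.integers(3, 12))
            # rank-deficient: fewer rows than variants
            A = rng.standard_normal((max(2, m - 2), m))
            A = A - A.mean(axis=0)
            sd = A.std(axis=0)
            sd[sd == 0] = 1.0
            C = np.corrcoef((A / sd).T)
            C = np.nan_to_num((C + C.T) / 2, nan=0.0)
            np.fill_diagonal(C, 1.0)
            R = regularize(CorrelationMatrix(C))
            np.linalg.cholesky(R.values)  # must not raise


def test_summary_stat_vector_validation():
    with pytest.raises(InputError):
        SummaryStatVector(z=np.array([1.0, np.inf]), kind="eqtl")
    with pytest.raises(InputError):
        SummaryStatVector(z=np.array([1.0]), kind="bogus")
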