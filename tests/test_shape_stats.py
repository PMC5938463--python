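"""Allometry, ordination, permutation distance tests and Goodall's F."""

import numpy as np
import pytest
from scipy import stats

from snailmorph.procrustes import gpa, tangent_project
from snailmorph.shape_stats import (AllometricRegression, ShapeCVA, ShapePCA,
                                    cva, goodall_f, pairwise_group_distances, pca)
from snailmorph.synthetic import shell_template
from .conftest import random_configs


class TestAllometry:
    def test_null_data_r2_near_zero(self, rng):
        flat = rng.normal(size=(300, 40))
        cs = rng.uniform(1, 3, 300)
        fit = AllometricRegression(n_permutations=199, random_state=0).fit(
            flat, centroid_sizes=cs)
        assert fit.r_squared_ < 0.02

    def test_slope_recovery_synthetic_field(self, rng):
        """shapes = consensus + beta*CS + noise recovers beta at n = 500."""
        n = 500
        beta = rng.normal(size=40)
        beta /= np.linalg.norm(beta)
        cs = rng.uniform(1, 3, n)
        signal = np.outer(cs, beta)
        noise_sd = 0.1 * signal.std()
        flat = 5.0 + signal + rng.normal(0, noise_sd, (n, 40))
        fit = AllometricRegression(n_permutations=0).fit(flat, centroid_sizes=cs)
        corr = np.corrcoef(fit.slope_vector_, beta)[0, 1]
        assert corr > 0.99

    def test_residuals_orthogonal_to_cs(self, rng):
        flat = rng.normal(size=(100, 40))
        cs = rng.uniform(1, 3, 100)
        fit = AllometricRegression(n_permutations=0).fit(flat, centroid_sizes=cs)
        csc = cs - cs.mean()
        corr = np.abs(csc @ fit.residuals_) / (
            np.linalg.norm(csc) * np.linalg.norm(fit.residuals_, axis=0))
        assert corr.max() < 1e-10
        refit = AllometricRegression(n_permutations=0).fit(
            fit.residuals_, centroid_sizes=cs)
        assert refit.r_squared_ < 1e-20

    def test_constant_cs_error(self, rng):
        with pytest.raises(ValueError, match="constant"):
            AllometricRegression(n_permutations=0).fit(
                rng.normal(size=(10, 4)), centroid_sizes=np.ones(10))


class TestPCA:
    def test_single_direction(self, rng):
        direction = rng.normal(size=40)
        flat = np.outer(rng.normal(size=50), direction)
        space = pca(flat)
        assert space.pct_variance[0] == pytest.approx(100.0)

    def test_variance_sums_to_100_and_orthonormal(self, rng):
        space = ShapePCA().fit(rng.normal(size=(30, 10)))
        assert space.pct_variance_.sum() == pytest.approx(100.0, abs=1e-6)
        assert np.all(np.diff(space.eigenvalues_) <= 1e-12)
        np.testing.assert_allclose(space.components_.T @ space.components_,
                                   np.eye(10), atol=1e-10)

    def test_back_projection_reconstructs(self, rng):
        flat = rng.normal(size=(40, 12))
        est = ShapePCA().fit(flat)
        np.testing.assert_allclose(est.inverse_transform(est.scores_), flat, atol=1e-9)

    def test_sign_convention(self, rng):
        est = ShapePCA().fit(rng.normal(size=(30, 8)))
        for j in range(8):
            col = est.components_[:, j]
            assert col[np.argmax(np.abs(col))] > 0


class TestCVA:
    def test_two_separated_groups(self, rng):
        a = rng.normal(0, 0.1, (30, 10))
        b = rng.normal(0, 0.1, (30, 10)) + np.r_[5.0, np.zeros(9)]
        labels = ["a"] * 30 + ["b"] * 30
        space = cva(np.vstack([a, b]), labels)
        assert space.pct_variance[0] == pytest.approx(100.0)
        assert space.scores.shape[1] == 1

    def test_permuted_labels_shrink_eigenvalues(self, rng):
        x = np.vstack([rng.normal(0, 1, (40, 6)),
                       rng.normal(3, 1, (40, 6))])
        labels = np.array(["a"] * 40 + ["b"] * 40)
        lam_true = ShapeCVA().fit(x, labels).eigenvalues_[0]
        lam_perm = np.median([
            ShapeCVA().fit(x, rng.permutation(labels)).eigenvalues_[0]
            for _ in range(20)
        ])
        assert lam_perm < lam_true / 5

    def test_invariance_to_linear_transform(self, rng):
        """CVA scores are invariant (up to sign) to invertible linear maps."""
        x = np.vstack([rng.normal(0, 1, (25, 5)),
                       rng.normal(2, 1, (25, 5)),
                       rng.normal(-2, 1.5, (25, 5))])
        labels = np.repeat(["a", "b", "c"], 25)
        m = rng.normal(size=(5, 5)) + 3 * np.eye(5)
        s1 = ShapeCVA().fit(x, labels).scores_
        s2 = ShapeCVA().fit(x @ m, labels).scores_
        for j in range(s1.shape[1]):
            r = np.corrcoef(s1[:, j], s2[:, j])[0, 1]
            assert abs(r) > 1 - 1e-8

    def test_small_group_error(self, rng):
        with pytest.raises(ValueError, match="fewer than 2"):
            cva(rng.normal(size=(5, 4)), ["a", "a", "a", "a", "b"])

    def test_rank_bound(self, rng):
        space = cva(rng.normal(size=(40, 36)),
                    np.repeat(["a", "b", "c", "d"], 10))
        assert space.scores.shape[1] <= 3


class TestGroupDistances:
    def test_symmetry_zero_diagonal(self, rng):
        x = rng.normal(size=(30, 8))
        labels = np.repeat(["a", "b", "c"], 10)
        table = pairwise_group_distances(x, labels, n_perm=99, seed=0)
        np.testing.assert_allclose(table.distances, table.distances.T)
        assert np.all(np.diag(table.distances) == 0)
        assert np.all((table.p_values > 0) & (table.p_values <= 1))
        assert table.bonferroni_alpha == pytest.approx(0.05 / 3)

    def test_strong_separation_attains_min_p(self, rng):
        a = rng.normal(0, 0.1, (15, 6))
        b = rng.normal(0, 0.1, (15, 6)) + 0.5 * 5
        labels = ["a"] * 15 + ["b"] * 15
        table = pairwise_group_distances(np.vstack([a, b]), labels,
                                         n_perm=499, seed=0)
        assert table.p_values[0, 1] == pytest.approx(1 / 500)

    def test_reproducible_under_seed(self, rng):
        x = rng.normal(size=(24, 5))
        labels = np.repeat(["a", "b"], 12)
        t1 = pairwise_group_distances(x, labels, n_perm=200, seed=7)
        t2 = pairwise_group_distances(x, labels, n_perm=200, seed=7)
        np.testing.assert_array_equal(t1.p_values, t2.p_values)

    def test_bad_n_perm(self, rng):
        with pytest.raises(ValueError):
            pairwise_group_distances(rng.normal(size=(8, 3)),
                                     ["a"] * 4 + ["b"] * 4, n_perm=0)


class TestGoodall:
    def test_df_formula(self, rng):
        """k = 20 landmarks and two groups of 19 give df = (36, 1296)."""
        a = random_configs(rng, 19, noise=0.01)
        b = random_configs(rng, 19, noise=0.01)
        res = goodall_f(a, b)
        assert (res.df_num, res.df_den) == (36, 1296)

    def test_identical_groups(self, rng):
        a = random_configs(rng, 5, noise=0.02)
        res = goodall_f(a, [x.copy() for x in a])
        assert res.f_value == pytest.approx(0.0, abs=1e-16)
        assert res.p_value == 1.0

    def test_null_distribution_is_f(self, rng):
        """Equal-mean groups: Goodall's F follows F(q, q(n1+n2-2))."""
        k, n1, n2 = 5, 5, 5
        q = 2 * k - 4
        base = shell_template()[:k]
        fs = []
        for _ in range(400):
            a = [base + rng.normal(0, 0.01, (k, 2)) for _ in range(n1)]
            b = [base + rng.normal(0, 0.01, (k, 2)) for _ in range(n2)]
            fs.append(goodall_f(a, b).f_value)
        ks = stats.kstest(fs, stats.f(q, q * (n1 + n2 - 2)).cdf)
        assert ks.pvalue > 0.01

    def test_insufficient_replication(self, rng):
        with pytest.raises(ValueError):
            goodall_f(random_configs(rng, 1), random_configs(rng, 3))
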