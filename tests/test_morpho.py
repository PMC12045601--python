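from itertools import permutations

import numpy as np
import pytest

from prolifatlas.morpho import (
    GeneralizedProcrustes,
    ShapePCA,
    TwoBlockPLS,
    gpa,
    pca,
    residualize_on_stage,
    split_by_somites,
    svm_genotype,
    two_block_pls,
)


def _rot(rng):
    q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q


class TestGPA:
    def test_identical_configurations_zero_distance(self, rng):
        A = rng.uniform(0, 10, (6, 3))
        model = gpa(np.stack([A, A]))
        assert np.abs(model.coords_[0] - model.coords_[1]).max() < 1e-12

    def test_invariance_to_rigid_scale_pretransforms(self, rng):
        A = rng.uniform(0, 10, (8, 3))
        B = 2.5 * A @ _rot(rng).T + np.array([5.0, -3.0, 1.0])
        model = gpa(np.stack([A, B]))
        assert np.abs(model.coords_[0] - model.coords_[1]).max() < 1e-8

    def test_unit_centroid_size_after_alignment(self, rng):
        X = rng.uniform(0, 5, (4, 7, 3))
        model = gpa(X)
        sizes = np.sqrt((model.coords_ ** 2).sum(axis=(1, 2)))
        assert np.allclose(sizes, 1.0, atol=1e-9)

    def test_mean_shape_recovery_from_noisy_copies(self, rng):
        tetra = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], float)
        sd = 0.02
        noisy = np.stack([tetra + rng.normal(0, sd, tetra.shape) for _ in range(3)])
        model = gpa(noisy)
        ref = tetra - tetra.mean(0)
        ref = ref / np.sqrt((ref**2).sum())
        from prolifatlas.morpho import _procrustes_rotate

        aligned_ref = _procrustes_rotate(ref, model.mean_shape_)
        assert np.abs(model.mean_shape_ - aligned_ref).max() < sd / np.sqrt(3)

    def test_degenerate_configuration_rejected(self):
        X = np.zeros((2, 5, 3))
        with pytest.raises(ValueError):
            gpa(X)


class TestPCA:
    def test_rank_one_data(self, rng):
        X = np.outer(rng.normal(size=9), rng.normal(size=6))
        model = pca(X)
        assert model.explained_variance_ratio_[0] == pytest.approx(1.0)

    def test_isotropic_two_feature_split(self, rng):
        X = rng.normal(size=(1000, 2))
        model = pca(X)
        assert model.explained_variance_ratio_[0] == pytest.approx(0.5, abs=0.05)

    def test_scores_reproduce_projection(self, rng):
        X = rng.normal(size=(3, 3))
        model = pca(X)
        assert np.allclose(model.scores_, (X - model.mean_) @ model.components_.T)

    def test_sign_convention_deterministic(self, rng):
        X = rng.normal(size=(10, 4))
        m1, m2 = pca(X), pca(X.copy())
        assert np.array_equal(m1.components_, m2.components_)
        for row in m1.components_:
            assert row[np.argmax(np.abs(row))] > 0

    def test_variance_fractions_sorted_and_bounded(self, rng):
        model = pca(rng.normal(size=(12, 6)))
        ratio = model.explained_variance_ratio_
        assert np.all(np.diff(ratio) <= 1e-12)
        assert ratio.sum() <= 1.0 + 1e-9

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pca(np.ones((5, 3)))


class TestTwoBlockPLS:
    def test_identical_blocks_r_one(self, rng):
        X = rng.normal(size=(10, 4))
        res = two_block_pls(X, X, n_perm=49, seed=0)
        assert res.r == pytest.approx(1.0)

    @pytest.mark.parametrize("stat", ["covariance", "correlation"])
    def test_exhaustive_p_matches_bruteforce_enumeration(self, rng, stat):
        n = 5
        X = rng.normal(size=(n, 3))
        Y = 0.5 * X + rng.normal(0, 0.5, size=(n, 3))
        res = two_block_pls(X, Y, exhaustive=True, perm_stat=stat)

        # independent oracle: direct enumeration with raw numpy SVD
        Xc, Yc = X - X.mean(0), Y - Y.mean(0)
        def first_stat(Xp):
            U, S, Vt = np.linalg.svd(Xp.T @ Yc / (n - 1), full_matrices=False)
            if stat == "covariance":
                return S[0]
            a, b = Xp @ U[:, 0], Yc @ Vt[0]
            return np.corrcoef(a, b)[0, 1]
        obs = first_stat(Xc)
        vals = [first_stat(Xc[list(p)]) for p in permutations(range(n))]
        p_oracle = np.mean([v >= obs - 1e-12 for v in vals])
        assert res.n_perm == 120
        assert res.p_value == pytest.approx(p_oracle)

    def test_matches_sklearn_plssvd_latent_correlation(self, rng):
        from sklearn.cross_decomposition import PLSSVD

        X = rng.normal(size=(15, 6))
        Y = rng.normal(size=(15, 4)) + X[:, :4]
        res = two_block_pls(X, Y, n_perm=9, seed=0)
        sk = PLSSVD(n_components=1, scale=False).fit(X, Y)
        xs, ys = sk.transform(X, Y)
        assert abs(res.r) == pytest.approx(abs(np.corrcoef(xs[:, 0], ys[:, 0])[0, 1]),
                                           abs=1e-8)

    def test_rotation_of_shape_block_preserves_r(self, rng):
        X = rng.normal(size=(12, 5))
        k = 7
        Y = rng.normal(size=(12, 3 * k))
        res1 = two_block_pls(X, Y, n_perm=9, seed=0)
        R = _rot(rng)
        Yrot = (Y.reshape(12, k, 3) @ R.T).reshape(12, 3 * k)
        res2 = two_block_pls(X, Yrot, n_perm=9, seed=0)
        assert res1.r == pytest.approx(res2.r, abs=1e-10)

    def test_row_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            two_block_pls(rng.normal(size=(5, 3)), rng.normal(size=(6, 3)))

    def test_p_lower_bound(self, rng):
        X = rng.normal(size=(20, 3))
        Y = X + rng.normal(0, 0.01, size=(20, 3))
        res = two_block_pls(X, Y, n_perm=99, seed=0)
        assert res.p_value >= 1 / 100
        assert res.p_value == pytest.approx(1 / 100)


class TestResidualize:
    def test_orthogonal_block_unchanged(self):
        somites = np.array([8.0, 10.0, 12.0, 14.0])
        col = np.array([1.0, -1.0, -1.0, 1.0])  # orthogonal to [1, somites]
        out = residualize_on_stage(col[:, None], somites)
        assert np.allclose(out.ravel(), col)

    def test_exact_linear_function_zeroed(self):
        somites = np.array([8.0, 10, 12, 14, 16])
        block = np.column_stack([2 * somites + 1, -somites])
        out = residualize_on_stage(block, somites)
        assert np.abs(out).max() < 1e-10

    def test_hand_computed_single_column(self):
        somites = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([2.0, 3.0, 5.0, 4.0])
        # closed-form OLS: slope = cov/var = 0.8, intercept = 3.5 - 0.8*2.5 = 1.5
        expected = y - (1.5 + 0.8 * somites)
        out = residualize_on_stage(y[:, None], somites)
        assert np.allclose(out.ravel(), expected)

    def test_residuals_uncorrelated_with_stage(self, rng):
        somites = rng.integers(8, 21, 12).astype(float)
        block = rng.normal(size=(12, 5)) + somites[:, None]
        out = residualize_on_stage(block, somites)
        for col in out.T:
            assert abs(np.corrcoef(col, somites)[0, 1]) < 1e-10

    def test_constant_stage_rejected(self):
        with pytest.raises(ValueError):
            residualize_on_stage(np.ones((4, 2)), np.full(4, 10.0))


class TestSomiteSplit:
    def test_threshold_partition(self):
        class S:
            def __init__(self, n):
                self.somites = n

        younger, older = split_by_somites([S(8), S(13), S(14), S(15), S(20)])
        assert [s.somites for s in younger] == [8, 13, 14]
        assert [s.somites for s in older] == [15, 20]

    def test_empty_side_warns(self):
        class S:
            def __init__(self, n):
                self.somites = n

        with pytest.warns(RuntimeWarning):
            younger, older = split_by_somites([S(8), S(10)])
        assert not older


class TestSVM:
    def _separable(self, rng, n_per=7):
        X = np.vstack([rng.normal(0, 0.2, (n_per, 5)) + 2,
                       rng.normal(0, 0.2, (n_per, 5)) - 2])
        y = np.array(["WT"] * n_per + ["MUT"] * n_per)
        return X, y

    def test_separable_toy_perfect_scores(self, rng):
        X, y = self._separable(rng)
        res = svm_genotype(X, y, n_perm=99, seed=0)
        assert res.accuracy == 1.0
        assert res.f1 == 1.0

    def test_p_attains_lower_bound_when_null_never_matches(self, rng):
        X, y = self._separable(rng)
        res = svm_genotype(X, y, n_perm=99, seed=0)
        if res.perm_f1.max() < res.f1:
            assert res.p_value == pytest.approx(1 / 100)
        assert res.p_value >= 1 / 100

    def test_single_class_rejected(self, rng):
        X = rng.normal(size=(6, 3))
        with pytest.raises(ValueError):
            svm_genotype(X, np.array(["WT"] * 6))

    def test_null_labels_give_uninformative_p(self, rng):
        # median permutation p over independent relabelings should sit near 0.5
        ps = []
        for rep in range(60):
            X = rng.normal(size=(14, 5))
            y = np.array(["WT"] * 7 + ["MUT"] * 7)
            y = rng.permutation(y)
            res = svm_genotype(X, y, n_perm=39, seed=rep)
            ps.append(res.p_value)
        assert 0.3 <= np.median(ps) <= 0.7
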