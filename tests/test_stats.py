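import numpy as np
import pytest

from prolifatlas.stats import (
    NullDistribution,
    change_proportions,
    dice,
    differential_volume,
    percent_increase,
    random_mask_null,
    shape_prolif_correlation,
    significance_mask,
    t_critical,
    vbm_tmap,
)
from prolifatlas.register import JacobianField
from prolifatlas.volio import LabeledVolume, ProliferationMap

SP = (4.0, 4.0, 4.0)


def lab(data):
    return LabeledVolume(np.asarray(data, np.int16), SP)


class TestDifferentialVolume:
    def test_equal_inputs_all_zero(self, rng):
        v = lab(rng.integers(0, 2, (8, 8, 8)))
        assert np.all(differential_volume(v, v).values == 0)

    def test_dilated_sample_gives_outward_shell(self):
        from scipy.ndimage import binary_dilation

        core = np.zeros((12, 12, 12), bool)
        core[4:8, 4:8, 4:8] = True
        grown = binary_dilation(core)
        d = differential_volume(lab(grown), lab(core))
        assert (d.values == -1).sum() == 0
        assert (d.values == 1).sum() == grown.sum() - core.sum()

    def test_proportions_hand_count(self):
        vals = np.zeros((10, 1, 1), np.int8)
        vals[:3] = 1
        vals[3:5] = -1
        from prolifatlas.stats import DifferentialVolume

        dv = DifferentialVolume(vals, SP)
        out, inn = change_proportions(dv, np.ones((10, 1, 1), bool))
        assert (out, inn) == (0.3, 0.2)

    def test_empty_mask_rejected(self):
        from prolifatlas.stats import DifferentialVolume

        dv = DifferentialVolume(np.zeros((4, 4, 4), np.int8), SP)
        with pytest.raises(ValueError):
            change_proportions(dv, np.zeros((4, 4, 4), bool))


class TestShapeProlifCorrelation:
    def test_perfect_linear_relation(self, rng):
        from prolifatlas.stats import DifferentialVolume

        vals = rng.integers(-1, 2, (10, 10, 10)).astype(np.int8)
        dv = DifferentialVolume(vals, SP)
        p = ProliferationMap(0.5 * (vals + 1.0), SP)
        mask = np.ones(vals.shape, bool)
        assert shape_prolif_correlation(dv, p, mask) == pytest.approx(1.0)

    def test_hand_computed_five_voxel_fixture(self):
        from prolifatlas.stats import DifferentialVolume

        d_vals = np.array([1, -1, 0, 1, 0], np.int8).reshape(5, 1, 1)
        p_vals = np.array([0.8, 0.1, 0.4, 0.9, 0.3]).reshape(5, 1, 1)
        dv = DifferentialVolume(d_vals, SP)
        pm = ProliferationMap(p_vals, SP)
        r = shape_prolif_correlation(dv, pm, np.ones((5, 1, 1), bool))
        # closed-form Pearson on the listed values
        x, y = d_vals.ravel().astype(float), p_vals.ravel()
        expected = ((x - x.mean()) @ (y - y.mean())) / (
            np.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()))
        assert r == pytest.approx(expected)

    def test_affine_rescale_invariance(self, rng):
        from prolifatlas.stats import DifferentialVolume

        vals = rng.integers(-1, 2, (8, 8, 8)).astype(np.int8)
        noise = rng.random((8, 8, 8))
        dv = DifferentialVolume(vals, SP)
        mask = np.ones(vals.shape, bool)
        r1 = shape_prolif_correlation(dv, ProliferationMap(noise, SP), mask)
        r2 = shape_prolif_correlation(dv, ProliferationMap(5 * noise + 2, SP), mask)
        assert r1 == pytest.approx(r2)

    def test_zero_variance_rejected(self):
        from prolifatlas.stats import DifferentialVolume

        dv = DifferentialVolume(np.zeros((4, 4, 4), np.int8), SP)
        pm = ProliferationMap(np.random.default_rng(0).random((4, 4, 4)), SP)
        with pytest.raises(ValueError, match="variance"):
            shape_prolif_correlation(dv, pm, np.ones((4, 4, 4), bool))


class TestVBM:
    def test_unit_jacobians_are_masked_out(self):
        jacs = [JacobianField(np.ones((6, 6, 6)), SP) for _ in range(4)]
        tmap = vbm_tmap(jacs, np.ones((6, 6, 6), bool))
        assert not tmap.valid.any()

    def test_t_statistic_arithmetic(self, rng):
        # log J ~ N(0.3, 0.1), n=5: noncentrality δ = 0.3/(0.1/√5) ≈ 6.7, and the
        # mean of t is δ·√((n−1)/2)·Γ((n−2)/2)/Γ((n−1)/2) (small-n bias of 1/s)
        from scipy.special import gamma

        n, shape = 5, (12, 12, 12)
        jacs = [JacobianField(np.exp(rng.normal(0.3, 0.1, shape)), SP)
                for _ in range(n)]
        tmap = vbm_tmap(jacs, np.ones(shape, bool))
        assert tmap.df == n - 1
        delta = 0.3 / (0.1 / np.sqrt(n))
        expected = delta * np.sqrt((n - 1) / 2) * gamma((n - 2) / 2) / gamma((n - 1) / 2)
        assert np.mean(tmap.t[tmap.valid]) == pytest.approx(expected, abs=1.0)

    def test_expansion_sign_convention(self, rng):
        shrink = [JacobianField(np.exp(rng.normal(-0.2, 0.05, (6, 6, 6))), SP)
                  for _ in range(4)]
        tmap = vbm_tmap(shrink, np.ones((6, 6, 6), bool))
        assert np.mean(tmap.t[tmap.valid]) < 0

    def test_significance_mask_threshold(self):
        t_vals = np.array([0.5, 3.0, 3.5, 4.0, -2.0, 3.23, 5.1, 0.0, 2.9, 3.24])
        from prolifatlas.stats import TMap

        tmap = TMap(t_vals.reshape(10, 1, 1), 4, np.ones((10, 1, 1), bool), SP)
        mask = significance_mask(tmap, 3.23)
        assert list(np.flatnonzero(mask.voxels.ravel())) == [2, 3, 6, 9]

    def test_empty_mask_warns(self):
        from prolifatlas.stats import TMap

        tmap = TMap(np.zeros((4, 4, 4)), 4, np.ones((4, 4, 4), bool), SP)
        with pytest.warns(RuntimeWarning):
            mask = significance_mask(tmap, 10.0)
        assert mask.voxels.sum() == 0

    def test_default_threshold_is_student_quantile(self):
        from scipy import stats as sps

        assert t_critical(4, 0.05) == pytest.approx(sps.t.ppf(0.95, 4))


class TestRandomMaskNull:
    def _prolif(self, rng, shape=(16, 16, 16)):
        return ProliferationMap(rng.random(shape), SP)

    def test_constant_map_gives_p_one(self, rng):
        p = ProliferationMap(np.full((10, 10, 10), 0.4), SP)
        sig = np.zeros((10, 10, 10), bool)
        sig[:3] = True
        nd = random_mask_null(p, sig, np.ones((10, 10, 10), bool), n_masks=50, seed=0)
        assert nd.p_value == 1.0
        assert not nd.outside_range

    def test_mask_equal_to_universe_degenerate(self, rng):
        p = self._prolif(rng)
        uni = np.ones((16, 16, 16), bool)
        nd = random_mask_null(p, uni, uni, n_masks=20, seed=0)
        assert np.allclose(nd.null_means, nd.observed)

    def test_p_lower_bound(self, rng):
        p = self._prolif(rng)
        sig = np.zeros((16, 16, 16), bool)
        sig[:2] = True
        nd = random_mask_null(p, sig, np.ones((16, 16, 16), bool), n_masks=100, seed=1)
        assert nd.p_value >= 1 / 101

    def test_universe_smaller_than_mask_rejected(self, rng):
        p = self._prolif(rng)
        sig = np.ones((16, 16, 16), bool)
        uni = np.zeros((16, 16, 16), bool)
        uni[0, 0, :5] = True
        with pytest.raises(ValueError):
            random_mask_null(p, sig, uni)

    def test_enriched_mask_detected(self, rng):
        vals = rng.random((16, 16, 16)) * 0.2
        sig = np.zeros((16, 16, 16), bool)
        sig[5:8, 5:8, 5:8] = True
        vals[sig] += 0.5
        nd = random_mask_null(ProliferationMap(vals, SP), sig,
                              np.ones((16, 16, 16), bool), n_masks=100, seed=2)
        assert nd.outside_range
        assert nd.p_value == pytest.approx(1 / 101)


class TestSummaries:
    @pytest.mark.parametrize(
        "sig, rand, expected",
        [(70.14, 57.26, 22.5), (84.64, 63.23, 33.9), (5.0, 5.0, 0.0)],
    )
    def test_percent_increase(self, sig, rand, expected):
        assert percent_increase(sig, rand) == expected

    def test_percent_increase_needs_positive_baseline(self):
        with pytest.raises(ValueError):
            percent_increase(1.0, 0.0)

    def test_dice_cases(self):
        a = np.zeros((4, 4, 4), bool)
        a[:2] = True
        assert dice(a, a) == 1.0
        assert dice(a, ~a) == 0.0
        assert dice(np.zeros((2, 2, 2), bool), np.zeros((2, 2, 2), bool)) == 1.0

    def test_dice_set_arithmetic(self):
        a = np.zeros((6, 1, 1), bool)
        b = np.zeros((6, 1, 1), bool)
        a[:3] = True  # |A| = 3
        b[1:4] = True  # |B| = 3, |A∩B| = 2
        assert dice(a, b) == pytest.approx(2 * 2 / 6)

    def test_dice_symmetric(self, rng):
        a = rng.random((5, 5, 5)) > 0.5
        b = rng.random((5, 5, 5)) > 0.5
        assert dice(a, b) == dice(b, a)


class TestTwoGroupVBM:
    def test_welch_t_between_stages(self, rng):
        shape = (8, 8, 8)
        expand = [JacobianField(np.exp(rng.normal(0.3, 0.05, shape)), SP)
                  for _ in range(5)]
        stable = [JacobianField(np.exp(rng.normal(0.0, 0.05, shape)), SP)
                  for _ in range(5)]
        tmap = vbm_tmap(expand, np.ones(shape, bool), group_b=stable)
        assert np.mean(tmap.t[tmap.valid]) > 3
        assert 2 <= tmap.df <= 8
        flipped = vbm_tmap(stable, np.ones(shape, bool), group_b=expand)
        assert np.mean(flipped.t[flipped.valid]) < -3
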