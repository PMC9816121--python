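"""Oracle tests for the embedding-loss suite and its differential operators."""

import numpy as np
import pytest

from pqctseg import autodiff as ad
from pqctseg.losses import (
    LossWeights,
    ProbabilisticSegmentation,
    cross_entropy,
    curvature,
    curvature_loss,
    gradient_magnitude,
    gradient_magnitude_loss,
    heaviside,
    normalize_probs,
    probabilistic_segmentation,
    spatial_gradient,
    total_loss,
    total_loss_fields,
    zero_crossing_mask,
)
from pqctseg.unet import EmbeddingFieldPair


def circle_sdf(n: int, radius: float) -> np.ndarray:
    c = (n - 1) / 2.0
    yy, xx = np.meshgrid(np.arange(n) - c, np.arange(n) - c, indexing="ij")
    return np.hypot(yy, xx) - radius


class TestHeaviside:
    def test_at_zero(self):
        assert heaviside(0.0) == pytest.approx(0.5)

    def test_at_epsilon(self):
        # atan(1) = pi/4  ->  1/2 + 1/4
        assert heaviside(2.5, epsilon=2.5) == pytest.approx(0.75)

    def test_odd_symmetry(self, rng):
        x = rng.normal(scale=10, size=200)
        np.testing.assert_allclose(heaviside(x) + heaviside(-x), 1.0)

    def test_range_open_interval(self, rng):
        x = rng.normal(scale=1e6, size=100)
        h = heaviside(x)
        assert np.all((h > 0) & (h < 1))

    def test_nonpositive_epsilon_rejected(self):
        with pytest.raises(ValueError):
            heaviside(1.0, epsilon=0.0)


class TestProbabilisticSegmentation:
    def test_saturated_trabecular_limit(self):
        f = EmbeddingFieldPair(np.full((4, 4), -1e9), np.full((4, 4), -1e9))
        p = probabilistic_segmentation(f)
        assert p.p_trab[0, 0] == pytest.approx(1.0, abs=1e-6)
        assert p.p_cort[0, 0] == pytest.approx(0.0, abs=1e-6)
        assert p.p_back[0, 0] == pytest.approx(0.0, abs=1e-6)

    def test_endo_zero_peri_deep_negative(self):
        f = EmbeddingFieldPair(np.zeros((4, 4)), np.full((4, 4), -1e9))
        p = probabilistic_segmentation(f)
        assert p.p_trab[0, 0] == pytest.approx(0.5, abs=1e-6)
        assert p.p_cort[0, 0] == pytest.approx(0.5, abs=1e-6)
        assert p.p_back[0, 0] == pytest.approx(0.0, abs=1e-6)

    def test_both_fields_zero(self):
        f = EmbeddingFieldPair(np.zeros((2, 2)), np.zeros((2, 2)))
        p = probabilistic_segmentation(f)
        assert (p.p_trab[0, 0], p.p_cort[0, 0], p.p_back[0, 0]) == (0.5, 0.25, 0.5)

    def test_normalization(self):
        p = ProbabilisticSegmentation(
            np.full((2, 2), 0.5), np.full((2, 2), 0.25), np.full((2, 2), 0.5)
        )
        pn = normalize_probs(p)
        assert pn.p_trab[0, 0] == pytest.approx(0.4)
        assert pn.p_cort[0, 0] == pytest.approx(0.2)
        assert pn.p_back[0, 0] == pytest.approx(0.4)
        assert pn.normalized

    def test_normalize_idempotent_and_preserves_one_hot(self):
        one_hot = ProbabilisticSegmentation(
            np.ones((2, 2)), np.zeros((2, 2)), np.zeros((2, 2))
        )
        pn = normalize_probs(one_hot)
        np.testing.assert_allclose(pn.p_trab, 1.0)
        pn2 = normalize_probs(pn)
        np.testing.assert_allclose(pn2.p_trab, pn.p_trab)

    def test_normalized_sums_to_one(self, rng):
        f = EmbeddingFieldPair(rng.normal(size=(8, 8)), rng.normal(size=(8, 8)))
        pn = normalize_probs(probabilistic_segmentation(f))
        np.testing.assert_allclose(pn.p_trab + pn.p_cort + pn.p_back, 1.0, atol=1e-6)


class TestCrossEntropy:
    def test_perfect_prediction_near_zero(self):
        cort = np.zeros((4, 4), bool)
        cort[1:3, 1:3] = True
        trab = np.zeros((4, 4), bool)
        p = ProbabilisticSegmentation(
            trab.astype(float),
            cort.astype(float),
            (~cort & ~trab).astype(float),
            normalized=True,
        )
        assert cross_entropy(p, cort, trab) < 1e-9

    def test_uniform_probabilities_give_ln3(self, rng):
        u = np.full((6, 6), 1 / 3)
        p = ProbabilisticSegmentation(u, u, u, normalized=True)
        cort = rng.random((6, 6)) > 0.5
        trab = ~cort & (rng.random((6, 6)) > 0.5)
        assert cross_entropy(p, cort, trab) == pytest.approx(np.log(3))

    def test_single_voxel_hand_value(self):
        p = ProbabilisticSegmentation(
            np.full((1, 1), 0.25),
            np.full((1, 1), 0.5),
            np.full((1, 1), 0.25),
            normalized=True,
        )
        cort = np.ones((1, 1), bool)
        trab = np.zeros((1, 1), bool)
        assert cross_entropy(p, cort, trab) == pytest.approx(-np.log(0.5))

    def test_decreases_as_true_class_probability_rises(self):
        cort = np.ones((1, 1), bool)
        trab = np.zeros((1, 1), bool)
        values = []
        for pc in (0.3, 0.5, 0.7, 0.9):
            rest = (1 - pc) / 2
            p = ProbabilisticSegmentation(
                np.full((1, 1), rest),
                np.full((1, 1), pc),
                np.full((1, 1), rest),
                normalized=True,
            )
            values.append(cross_entropy(p, cort, trab))
        assert values == sorted(values, reverse=True)


class TestDifferentialOperators:
    def test_gradient_of_linear_field(self):
        yy, xx = np.meshgrid(np.arange(9.0), np.arange(9.0), indexing="ij")
        gr, gc = spatial_gradient(xx)
        np.testing.assert_allclose(gr, 0.0, atol=1e-12)
        np.testing.assert_allclose(gc, 1.0)
        np.testing.assert_allclose(gradient_magnitude(2 * xx + yy), np.sqrt(5.0))

    def test_gradient_of_constant_field(self):
        np.testing.assert_allclose(gradient_magnitude(np.ones((6, 6))), 0.0)

    def test_too_small_field_raises(self):
        with pytest.raises(ValueError):
            spatial_gradient(np.ones((2, 5)))

    def test_zero_crossing_band_1d_profile(self):
        profile = np.tile(np.array([-1.5, -0.5, 0.5, 1.5]), (4, 1))
        band = zero_crossing_mask(profile).mask
        np.testing.assert_array_equal(band[0], [False, True, True, False])

    def test_all_positive_field_has_empty_band(self):
        assert not zero_crossing_mask(np.ones((5, 5))).mask.any()

    def test_exact_zero_voxel_flagged(self):
        f = np.ones((5, 5))
        f[2, 2] = 0.0
        assert zero_crossing_mask(f).mask[2, 2]

    def test_circle_curvature_matches_inverse_radius(self):
        for radius in (10.0, 20.0):
            phi = circle_sdf(101, radius)
            band = zero_crossing_mask(phi).mask
            kappa = curvature(phi)[band]
            assert np.mean(kappa) == pytest.approx(1 / radius, rel=0.10)

    def test_planar_sdf_curvature_near_zero(self):
        yy, xx = np.meshgrid(np.arange(20.0), np.arange(20.0), indexing="ij")
        kappa = curvature(xx - 9.5)
        assert np.abs(kappa[5:-5, 5:-5]).max() < 1e-6

    def test_sign_flip_flips_curvature(self):
        phi = circle_sdf(61, 15.0)
        k1 = curvature(phi)
        k2 = curvature(-phi)
        np.testing.assert_allclose(k1[10:-10, 10:-10], -k2[10:-10, 10:-10], atol=1e-9)


class TestRegularizers:
    def test_curvature_loss_zero_below_threshold(self):
        # kappa = 1/20 voxel^-1 well below the 0.3035 voxel^-1 threshold
        assert curvature_loss(circle_sdf(101, 20.0)) == 0.0

    def test_curvature_loss_zero_on_empty_band(self):
        assert curvature_loss(np.ones((16, 16)) * 3.0) == 0.0

    def test_curvature_loss_near_zero_at_exact_threshold(self):
        # circle with kappa = kappa_thresh: analytically zero; discretization
        # of kappa leaves only a tiny residual
        w = LossWeights()
        phi = circle_sdf(41, 1.0 / w.kappa_thresh_voxel)
        assert curvature_loss(phi, w) < 5e-3

    def test_curvature_loss_band_contribution_at_double_threshold(self):
        # kappa / kappa_thresh = 2  =>  ReLU(4 - 1) = 3 per band voxel
        radius = 12.0
        phi = circle_sdf(65, radius)
        w = LossWeights(kappa_thresh_um=1.0, voxel_size_mm=1.0 / (2 * radius) / 1000)
        assert w.kappa_thresh_voxel == pytest.approx(1 / (2 * radius))
        band = zero_crossing_mask(phi).mask
        loss = curvature_loss(phi, w)
        expected = 3.0 * band.sum() / phi.size
        assert loss == pytest.approx(expected, rel=0.15)

    def test_gradient_magnitude_loss_zero_for_planar_sdf(self):
        yy, xx = np.meshgrid(np.arange(24.0), np.arange(24.0), indexing="ij")
        assert gradient_magnitude_loss(xx - 11.5) == pytest.approx(0.0, abs=1e-12)

    def test_gradient_magnitude_loss_scaled_field(self):
        # |grad| = e off the band  =>  contribution log^2 e = 1 per off-band voxel
        yy, xx = np.meshgrid(np.arange(24.0), np.arange(24.0), indexing="ij")
        phi = np.e * (xx - 11.5)
        band = zero_crossing_mask(phi).mask
        loss = gradient_magnitude_loss(phi)
        assert loss == pytest.approx((~band).sum() / phi.size, rel=1e-6)


class TestTotalLoss:
    @staticmethod
    def _phantom_slice(small_phantom, k=6):
        cort = small_phantom.truth.cortical.voxels[k]
        trab = small_phantom.truth.trabecular.voxels[k]
        fields = EmbeddingFieldPair(
            small_phantom.endo_sdf[k], small_phantom.peri_sdf[k]
        )
        return fields, cort, trab

    def test_zero_lambdas_reduce_to_cross_entropy(self, small_phantom):
        fields, cort, trab = self._phantom_slice(small_phantom)
        w = LossWeights(lambda_kappa=0.0, lambda_grad=0.0)
        bd = total_loss(fields, cort, trab, w)
        assert bd.l_total == pytest.approx(bd.l_ce)

    def test_ground_truth_sdf_scores_small_everywhere(self, small_phantom):
        fields, cort, trab = self._phantom_slice(small_phantom)
        bd = total_loss(fields, cort, trab)
        assert bd.l_ce < 0.15  # saturating Heaviside keeps a small residual
        assert bd.l_grad_endo < 0.05 and bd.l_grad_peri < 0.05
        assert bd.l_kappa_endo < 0.05 and bd.l_kappa_peri < 0.05
        assert bd.l_total == pytest.approx(bd.l_ce, abs=0.01)

    def test_lambda_weighting_arithmetic(self, small_phantom, rng):
        fields, cort, trab = self._phantom_slice(small_phantom)
        noisy = EmbeddingFieldPair(
            fields.endo + rng.normal(scale=2.0, size=fields.endo.shape),
            fields.peri + rng.normal(scale=2.0, size=fields.peri.shape),
        )
        w = LossWeights()
        bd = total_loss(noisy, cort, trab, w)
        expected = (
            bd.l_ce
            + 1e-4 * (bd.l_kappa_endo + bd.l_kappa_peri)
            + 1e-4 * (bd.l_grad_endo + bd.l_grad_peri)
        )
        assert bd.l_total == pytest.approx(expected, rel=1e-12)

    def test_differentiable_with_finite_gradients(self, rng):
        endo = ad.Tensor(rng.normal(size=(16, 16)), requires_grad=True)
        peri = ad.Tensor(rng.normal(size=(16, 16)), requires_grad=True)
        cort = rng.random((16, 16)) > 0.7
        trab = ~cort & (rng.random((16, 16)) > 0.5)
        bd = total_loss_fields(endo, peri, cort, trab)
        bd.l_total.backward()
        assert np.all(np.isfinite(endo.grad))
        assert np.all(np.isfinite(peri.grad))
        assert np.any(endo.grad != 0)

    def test_invariant_under_consistent_flips(self, small_phantom):
        fields, cort, trab = self._phantom_slice(small_phantom)
        bd = total_loss(fields, cort, trab)
        flipped = EmbeddingFieldPair(fields.endo[::-1, ::-1], fields.peri[::-1, ::-1])
        bd_f = total_loss(flipped, cort[::-1, ::-1], trab[::-1, ::-1])
        assert bd_f.l_total == pytest.approx(bd.l_total, rel=1e-12)

    def test_shape_mismatch_rejected(self, rng):
        fields = EmbeddingFieldPair(np.zeros((8, 8)), np.zeros((8, 8)))
        with pytest.raises(ValueError):
            total_loss(fields, np.zeros((6, 6), bool), np.zeros((6, 6), bool))
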