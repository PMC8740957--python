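"""Dice / GDSC / smoothness loss formulas against independent oracles.

The per-scale arithmetic is checked against hand-counted sums, the
Gaussian kernel against direct evaluation of the sampled-and-normalized
exponential, autodiff against the closed-form Dice gradient, and the
gradient-stability claim (smoothing bounds the Dice gradient on sparse
labels) at the level where it is literally testable.
"""

import numpy as np
import pytest

import siamreg as sr
from siamreg import autodiff as ad
from siamreg.core_volumes import ValidationError
from siamreg.losses import smoothed_label_pyramid


class TestGaussianKernel:
    def test_sigma_zero_is_identity_marker(self):
        k = sr.gaussian_kernel(0)
        assert k.identity
        lab = sr.LabelMap(np.zeros((4, 4, 4)), np.full(3, 0.6))
        assert sr.smooth_label(lab, k) is lab

    def test_sigma_one_matches_direct_evaluation(self):
        """7 taps at x = -3..3, proportional to exp(-x^2/2), unit sum."""
        k = sr.gaussian_kernel(1)
        x = np.arange(-3, 4, dtype=float)
        expected = np.exp(-(x**2) / 2.0)
        expected /= expected.sum()
        assert k.taps.shape == (7,)
        assert np.abs(k.taps - expected).max() < 1e-15
        assert abs(k.taps.sum() - 1.0) <= 1e-12

    @pytest.mark.parametrize("sigma", [1, 2, 4, 8])
    def test_taps_sum_to_one_and_are_even(self, sigma):
        k = sr.gaussian_kernel(sigma)
        assert k.taps.shape == (6 * sigma + 1,)
        assert abs(k.taps.sum() - 1.0) <= 1e-12
        assert np.array_equal(k.taps, k.taps[::-1])

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValidationError):
            sr.gaussian_kernel(-1)


class TestSmoothLabel:
    def test_interior_of_solid_block_stays_one(self):
        lab = np.zeros((20, 20, 20))
        lab[4:16, 4:16, 4:16] = 1.0
        out = sr.smooth_label(
            sr.LabelMap(lab, np.full(3, 0.6)), sr.gaussian_kernel(1)
        )
        assert abs(out.data[10, 10, 10] - 1.0) <= 1e-9

    def test_single_voxel_center_value_is_product_of_axis_center_taps(self):
        lab = np.zeros((9, 9, 9))
        lab[4, 4, 4] = 1.0
        k = sr.gaussian_kernel(1)
        out = sr.smooth_label(sr.LabelMap(lab, np.full(3, 0.6)), k)
        center_tap = k.taps[len(k.taps) // 2]
        assert abs(out.data[4, 4, 4] - center_tap**3) < 1e-12

    def test_mass_conserved_away_from_boundary(self):
        lab = np.zeros((16, 16, 16))
        lab[7:9, 7:9, 7:9] = 1.0  # >= 3 sigma from every face for sigma = 2
        out = sr.smooth_label(sr.LabelMap(lab, np.full(3, 0.6)), sr.gaussian_kernel(2))
        assert abs(out.data.sum() - lab.sum()) < 1e-9


def _random_labels(rng, shape=(8, 8, 8), p=0.2):
    return (rng.random(shape) < p).astype(float), (rng.random(shape) < p).astype(float)


class TestDiceLoss:
    def test_perfect_overlap_is_zero(self, rng):
        p, _ = _random_labels(rng)
        p[0, 0, 0] = 1.0
        assert sr.dsc_loss(p, p) < 1e-4

    def test_disjoint_labels_give_one(self):
        p = np.zeros((4, 4, 4))
        g = np.zeros((4, 4, 4))
        p[0, 0, 0] = 1.0
        g[3, 3, 3] = 1.0
        assert abs(sr.dsc_loss(p, g) - 1.0) < 1e-6

    def test_hand_counted_example(self):
        """3 foreground voxels vs 3 with overlap 2: 1 - 4/6 = 1/3."""
        p = np.zeros((4, 4, 4))
        g = np.zeros((4, 4, 4))
        p[0, 0, :3] = 1.0
        g[0, 0, 1:4] = 1.0
        assert abs(sr.dsc_loss(p, g) - (1.0 - 4.0 / 6.0)) < 1e-6

    def test_extent_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            sr.dsc_loss(np.zeros((4, 4, 4)), np.zeros((4, 4, 5)))

    def test_bounded_between_zero_and_one(self, rng):
        for _ in range(20):
            p, g = _random_labels(rng)
            loss = sr.dsc_loss(p, g)
            assert -1e-9 <= loss <= 1.0 + 1e-9


class TestDiceGradientOracle:
    @pytest.mark.parametrize(
        "p,g,expected",
        [
            (1.0, 1.0, 0.5),
            (0.5, 0.0, 0.0),
            (0.01, 1.0, 2.0 / 1.01**2),
        ],
    )
    def test_closed_form_values(self, p, g, expected):
        assert abs(sr.dice_gradient_oracle(p, g) - expected) < 1e-12

    def test_blows_up_as_denominator_shrinks(self):
        grads = [sr.dice_gradient_oracle(p, 0.05) for p in (1.0, 0.5, 0.1, 0.01)]
        assert all(a < b for a, b in zip(grads, grads[1:]))

    def test_degenerate_input_rejected(self):
        with pytest.raises(ValidationError):
            sr.dice_gradient_oracle(0.0, 0.0)

    def test_autodiff_gradient_matches_closed_form(self):
        """On a single-entry label pair (where the per-element form is
        exact), the autodiff gradient of the soft Dice loss equals
        2 g^2 / (p + g)^2 in magnitude."""
        for p_val, g_val in [(1.0, 1.0), (0.3, 0.9), (0.01, 1.0), (0.7, 0.2)]:
            p = ad.Tensor(np.full((1, 1, 1), p_val), requires_grad=True)
            loss = sr.dsc_loss(p, np.full((1, 1, 1), g_val), epsilon=0.0)
            loss.backward()
            expected = sr.dice_gradient_oracle(p_val, g_val)
            assert abs(abs(float(p.grad[0, 0, 0])) - expected) <= 1e-5 * expected + 1e-12


class TestGDSC:
    def test_single_zero_scale_reduces_to_dice(self, rng):
        cfg = sr.LossConfig(sigma_set=(0,))
        for _ in range(10):
            p, g = _random_labels(rng)
            assert abs(sr.gdsc_loss(p, g, cfg) - sr.dsc_loss(p, g)) <= 1e-9

    def test_identical_labels_give_zero_at_zero_scale(self, rng):
        p, _ = _random_labels(rng, (12, 12, 12))
        p[5, 5, 5] = 1.0
        assert sr.gdsc_loss(p, p.copy(), sr.LossConfig(sigma_set=(0,))) < 1e-4

    def test_alignment_minimizes_the_multi_scale_loss(self):
        """Smoothed scales have a nonzero loss floor (smoothed labels are
        soft, so the overlap ratio sits below one even at p == g), but
        perfect alignment still beats any shifted copy."""
        cfg = sr.LossConfig(sigma_set=(0, 1, 2, 4))
        p = np.zeros((16, 16, 16))
        p[6:10, 6:10, 6:10] = 1.0
        aligned = sr.gdsc_loss(p, p.copy(), cfg)
        for shift in (1, 2, 4):
            shifted = np.roll(p, shift, axis=0)
            assert aligned < sr.gdsc_loss(p, shifted, cfg)

    def test_smoothing_makes_nearby_disjoint_labels_overlap(self):
        """Single voxels two apart: plain Dice saturates at 1, the smoothed
        scale sees the overlapping tails, so the multi-scale loss < 1."""
        p = np.zeros((12, 12, 12))
        g = np.zeros((12, 12, 12))
        p[5, 5, 4] = 1.0
        g[5, 5, 6] = 1.0
        loss_multi = sr.gdsc_loss(p, g, sr.LossConfig(sigma_set=(0, 1)))
        assert loss_multi < 1.0 - 1e-4
        # oracle: compute the sigma=1 overlap by separable convolution
        (p0, g0), (p1, g1) = smoothed_label_pyramid(
            p, g, sr.LossConfig(sigma_set=(0, 1))
        )
        ov1 = 2 * (p1 * g1).sum() / (p1.sum() + g1.sum() + 1e-6)
        expected = 1.0 - 0.5 * (0.0 + ov1)
        assert abs(loss_multi - expected) < 1e-9

    def test_pyramid_zero_scale_entry_is_unsmoothed(self, rng):
        p, g = _random_labels(rng)
        pairs = smoothed_label_pyramid(p, g, sr.LossConfig(sigma_set=(0, 2)))
        assert pairs[0][0] is p and pairs[0][1] is g
        assert len(pairs) == 2

    def test_empty_sigma_set_rejected(self):
        with pytest.raises(ValidationError):
            sr.LossConfig(sigma_set=())

    def test_gradient_stability_on_sparse_disjoint_labels(self):
        """The motivating property: for sparse disjoint labels the maximum
        per-voxel gradient under the multi-scale smoothed loss is strictly
        smaller than under plain Dice."""
        cfg = sr.LossConfig(sigma_set=(0, 1, 2, 4, 8))
        for seed in range(5):
            rng = np.random.default_rng(seed)
            p = np.zeros((64, 64, 64))
            g = np.zeros((64, 64, 64))
            idx = rng.choice(64**3, size=10, replace=False)
            p.ravel()[idx[:5]] = 1.0
            g.ravel()[idx[5:]] = 1.0

            pt = ad.Tensor(p.copy(), requires_grad=True)
            sr.dsc_loss(pt, g).backward()
            max_dsc = np.abs(pt.grad).max()

            pt2 = ad.Tensor(p.copy(), requires_grad=True)
            sr.gdsc_loss(pt2, g, cfg).backward()
            max_gdsc = np.abs(pt2.grad).max()
            assert max_gdsc < max_dsc


class TestSmoothness:
    def test_constant_translation_has_zero_gradient_penalty(self):
        dvf = np.tile(np.array([1.5, -2.0, 0.25])[:, None, None, None], (1, 6, 6, 6))
        assert sr.smoothness_loss(dvf, "gradient") == 0.0

    def test_linear_field_has_zero_bending_but_positive_gradient(self):
        x = np.arange(8, dtype=float)
        dvf = np.zeros((3, 8, 8, 8))
        dvf[0] = 0.3 * x[:, None, None]
        assert sr.smoothness_loss(dvf, "bending") <= 1e-12
        assert sr.smoothness_loss(dvf, "gradient") > 0.0

    def test_single_spike_matches_finite_difference_oracle(self):
        """Hand-computed: a spike of magnitude m in component 0 creates
        forward differences +-m along each axis; summing the per-voxel
        Jacobian norms gives m*(3 + sqrt(3)) before averaging."""
        m = 2.0
        n = 5
        dvf = np.zeros((3, n, n, n))
        dvf[0, 2, 2, 2] = m
        # voxels (1,2,2),(2,1,2),(2,2,1): one incoming diff of size m each;
        # voxel (2,2,2): three outgoing diffs -> norm m*sqrt(3)
        expected = (3 * m + m * np.sqrt(3)) / n**3
        assert abs(sr.smoothness_loss(dvf, "gradient") - expected) < 1e-12

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValidationError):
            sr.smoothness_loss(np.zeros((3, 4, 4, 4)), "banana")


class TestTotalLoss:
    def test_alpha_zero_equals_gdsc(self, rng):
        p, g = _random_labels(rng)
        dvf = rng.normal(size=(3, 8, 8, 8))
        cfg = sr.LossConfig(sigma_set=(0, 1), alpha=0.0)
        assert abs(sr.total_loss(p, g, dvf, cfg) - sr.gdsc_loss(p, g, cfg)) < 1e-12

    def test_perfect_alignment_and_zero_field_give_zero(self, rng):
        p, _ = _random_labels(rng)
        p[2, 2, 2] = 1.0
        dvf = np.zeros((3, 8, 8, 8))
        assert sr.total_loss(p, p.copy(), dvf, sr.LossConfig(sigma_set=(0,))) < 1e-4

    def test_linear_combination_arithmetic(self, monkeypatch):
        """gdsc = 0.4, smooth = 0.2, alpha = 0.5 -> 0.5."""
        import siamreg.losses as losses_mod

        monkeypatch.setattr(losses_mod, "gdsc_loss", lambda p, g, cfg: 0.4)
        monkeypatch.setattr(losses_mod, "smoothness_loss", lambda d, v: 0.2)
        out = losses_mod.total_loss(None, None, None, sr.LossConfig(alpha=0.5))
        assert abs(out - 0.5) < 1e-12
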