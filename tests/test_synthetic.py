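"""Vessel-phantom generator, elastic deformation fields, augmentations."""

import numpy as np
import pytest

import siamreg as sr
from siamreg.core_volumes import ValidationError


class TestPhantom:
    def test_same_seed_is_bit_identical(self):
        cfg = sr.PhantomConfig(extents=(24, 24, 24), seed=5)
        a = sr.make_phantom(cfg)
        b = sr.make_phantom(cfg)
        assert np.array_equal(a.fixed.data, b.fixed.data)
        assert np.array_equal(a.moving.data, b.moving.data)
        assert np.array_equal(a.fixed_label.data, b.fixed_label.data)

    def test_label_foreground_fraction_sane(self, tiny_phantom):
        frac = tiny_phantom.fixed_label.data.mean()
        assert 0.0 < frac < 0.5

    def test_bifurcation_landmark_inside_lumen(self, tiny_phantom):
        lm = tiny_phantom.fixed_landmarks["bifurcation"]
        vox = np.round(
            tiny_phantom.fixed_label.world_to_voxel(np.array(lm.position_mm))[0]
        ).astype(int)
        assert tiny_phantom.fixed_label.data[tuple(vox)] == 1.0

    def test_modalities_share_geometry_but_invert_contrast(self, tiny_phantom):
        inside = tiny_phantom.fixed_label.data == 1.0
        f, m = tiny_phantom.fixed.data, tiny_phantom.moving.data
        assert f[inside].mean() > f[~inside].mean()
        assert m[inside].mean() < m[~inside].mean()

    def test_oversized_radius_rejected(self):
        with pytest.raises(ValidationError):
            sr.PhantomConfig(extents=(24, 24, 24), radius_range=(2.0, 10.0))


class TestElasticDvf:
    def test_zero_amplitude_gives_identity_field(self):
        dvf = sr.random_elastic_dvf((16, 16, 16), sr.DeformConfig(amplitude=0.0, seed=1))
        assert np.abs(dvf.vectors).max() == 0.0

    @pytest.mark.parametrize("amplitude", [0.5, 2.0, 3.0])
    def test_max_displacement_equals_amplitude(self, amplitude):
        dvf = sr.random_elastic_dvf(
            (20, 20, 20), sr.DeformConfig(amplitude=amplitude, seed=2)
        )
        maxnorm = np.sqrt((dvf.vectors**2).sum(axis=0)).max()
        assert abs(maxnorm - amplitude) <= 1e-6

    def test_smoothing_reduces_field_roughness(self):
        """With a fixed seed the smoothness penalty decreases monotonically
        as the Gaussian smoothing of the generator grows."""
        losses = [
            sr.smoothness_loss(
                sr.random_elastic_dvf(
                    (24, 24, 24),
                    sr.DeformConfig(amplitude=3.0, smooth_sigma=s, seed=3),
                )
            )
            for s in (1.0, 2.0, 4.0)
        ]
        assert losses[0] > losses[1] > losses[2]


class TestDeformedPair:
    def test_zero_amplitude_pair_is_perfectly_aligned(self, tiny_phantom):
        pair = sr.make_deformed_pair(tiny_phantom, sr.DeformConfig(amplitude=0.0, seed=4))
        assert np.array_equal(pair.moving.data, tiny_phantom.moving.data)
        ident = sr.identity_dvf(pair.fixed.extents, pair.fixed.spacing)
        assert sr.dsc(sr.warp(pair.moving_label, ident, interp="nearest"), pair.fixed_label) == 1.0

    def test_deformation_breaks_overlap(self, tiny_pair):
        ident = sr.identity_dvf(tiny_pair.fixed.extents, tiny_pair.fixed.spacing)
        pre = sr.dsc(
            sr.warp(tiny_pair.moving_label, ident, interp="nearest"),
            tiny_pair.fixed_label,
        )
        assert pre < 1.0

    def test_ground_truth_field_aligns_moving_onto_fixed(self, tiny_pair):
        warped = sr.warp(tiny_pair.moving_label, tiny_pair.gt_dvf, interp="nearest")
        assert sr.dsc(warped, tiny_pair.fixed_label) >= 0.95

    def test_ground_truth_alignment_at_default_scale_and_full_amplitude(self):
        """At the generator's default grid and the 3-voxel peak amplitude,
        warping the moving label with the stored field recovers the fixed
        lumen with Dice >= 0.95."""
        ph = sr.make_phantom(sr.PhantomConfig(seed=21))
        pair = sr.make_deformed_pair(ph, sr.DeformConfig(amplitude=3.0, seed=22))
        warped = sr.warp(pair.moving_label, pair.gt_dvf, interp="nearest")
        assert sr.dsc(warped, pair.fixed_label) >= 0.95

    def test_identity_tre_equals_mean_field_magnitude(self, tiny_pair):
        ident = sr.identity_dvf(tiny_pair.fixed.extents, tiny_pair.fixed.spacing)
        expected = tiny_pair.gt_dvf.magnitude_mm().mean()
        assert abs(sr.tre(ident, tiny_pair.gt_dvf) - expected) < 1e-12

    def test_landmarks_consistent_with_ground_truth(self, tiny_pair):
        d = sr.landmark_distance(
            tiny_pair.fixed_landmarks,
            tiny_pair.moving_landmarks,
            tiny_pair.gt_dvf,
            moving_origin=tiny_pair.moving.origin,
        )
        assert d < 1e-9

    def test_centered_crop_emulates_cross_scale_regime(self, tiny_phantom):
        pair = sr.make_deformed_pair(
            tiny_phantom,
            sr.DeformConfig(amplitude=2.0, seed=6),
            crop_to=(24, 28, 32),
            divisible_by=4,
        )
        assert pair.moving.extents == (24, 28, 32)
        assert pair.fixed.extents == (32, 32, 32)
        warped = sr.warp(pair.moving_label, pair.gt_dvf, interp="nearest")
        assert sr.dsc(warped, pair.fixed_label) >= 0.95

    def test_crop_violating_divisibility_rejected(self, tiny_phantom):
        with pytest.raises(ValidationError, match="divisib"):
            sr.make_deformed_pair(
                tiny_phantom,
                sr.DeformConfig(amplitude=1.0, seed=6),
                crop_to=(23, 28, 32),
                divisible_by=4,
            )

    def test_round_trips_through_dataset_io(self, tiny_pair, tmp_path):
        manifest = sr.write_dataset([tiny_pair], tmp_path)
        back = sr.load_dataset(manifest)[0]
        assert np.array_equal(back.fixed.data, tiny_pair.fixed.data)
        assert np.array_equal(back.moving_label.data, tiny_pair.moving_label.data)
        assert np.array_equal(back.gt_dvf.vectors, tiny_pair.gt_dvf.vectors)
        assert back.group_id == tiny_pair.group_id
        assert back.fixed_landmarks.names == tiny_pair.fixed_landmarks.names


class TestAugment:
    def test_double_flip_is_identity(self, tiny_pair):
        twice = sr.augment(sr.augment(tiny_pair, "lr_flip"), "lr_flip")
        assert np.array_equal(twice.fixed.data, tiny_pair.fixed.data)
        assert np.array_equal(twice.moving.data, tiny_pair.moving.data)
        assert np.allclose(twice.gt_dvf.vectors, tiny_pair.gt_dvf.vectors)
        assert np.allclose(
            twice.fixed_landmarks.positions(), tiny_pair.fixed_landmarks.positions()
        )

    def test_flip_preserves_label_overlap(self, tiny_pair):
        ident = sr.identity_dvf(tiny_pair.fixed.extents, tiny_pair.fixed.spacing)
        pre = sr.dsc(
            sr.warp(tiny_pair.moving_label, ident, interp="nearest"),
            tiny_pair.fixed_label,
        )
        flipped = sr.augment(tiny_pair, "lr_flip")
        pre_f = sr.dsc(
            sr.warp(flipped.moving_label, ident, interp="nearest"), flipped.fixed_label
        )
        assert pre_f == pre

    def test_flip_keeps_ground_truth_consistent(self, tiny_pair):
        flipped = sr.augment(tiny_pair, "lr_flip")
        warped = sr.warp(flipped.moving_label, flipped.gt_dvf, interp="nearest")
        assert sr.dsc(warped, flipped.fixed_label) >= 0.95

    def test_identity_affine_returns_pair_unchanged(self, tiny_pair):
        assert sr.apply_affine(tiny_pair) is tiny_pair

    def test_random_affine_keeps_ground_truth_consistent(self, tiny_pair):
        aug = sr.augment(tiny_pair, "affine", seed=9)
        assert not np.array_equal(aug.fixed.data, tiny_pair.fixed.data)
        warped = sr.warp(aug.moving_label, aug.gt_dvf, interp="nearest")
        assert sr.dsc(warped, aug.fixed_label) >= 0.9

    def test_unknown_mode_rejected(self, tiny_pair):
        with pytest.raises(ValidationError):
            sr.augment(tiny_pair, "rot90")
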