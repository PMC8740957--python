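"""Training loop, grouped cross-validation, checkpoint resume, and the
registration/evaluation drivers, exercised at miniature scale."""

import numpy as np
import pytest

import siamreg as sr
from siamreg.core_volumes import ValidationError
from siamreg.train import load_checkpoint


def _mini_pairs(n, seed=0, extent=16):
    pairs = []
    for i in range(n):
        ph = sr.make_phantom(
            sr.PhantomConfig(
                extents=(extent,) * 3, radius_range=(1.5, 3.0), seed=seed * 100 + i
            )
        )
        pairs.append(
            sr.make_deformed_pair(
                ph, sr.DeformConfig(amplitude=2.0, control_spacing=6, seed=seed * 100 + 50 + i)
            )
        )
    return pairs


def _mini_cfg(iterations, **kw):
    base = dict(
        iterations=iterations,
        batch_size=1,
        checkpoint_interval=max(iterations // 2, 1),
        seed=3,
        augment_affine=False,
        loss=sr.LossConfig(sigma_set=(0, 1, 2)),
        network=sr.NetworkConfig(levels=2, base_channels=4),
        learning_rate=1e-3,
    )
    base.update(kw)
    return sr.TrainConfig(**base)


class TestGroupedKFold:
    def _pairs(self, n_groups, per_group=2):
        return [
            {"pair_id": f"g{g}_p{i}", "group_id": f"g{g}"}
            for g in range(n_groups)
            for i in range(per_group)
        ]

    def test_eleven_groups_four_folds_balanced(self):
        splits = sr.grouped_kfold(self._pairs(11), folds=4, seed=0)
        test_group_counts = [
            len({pid.split("_")[0] for pid in test}) for _, test in splits
        ]
        assert sorted(test_group_counts) == [2, 3, 3, 3]

    def test_every_pair_in_exactly_one_test_fold(self):
        pairs = self._pairs(7)
        splits = sr.grouped_kfold(pairs, folds=3, seed=1)
        seen = [pid for _, test in splits for pid in test]
        assert sorted(seen) == sorted(p["pair_id"] for p in pairs)

    def test_left_right_sides_never_straddle_folds(self):
        splits = sr.grouped_kfold(self._pairs(6, per_group=2), folds=3, seed=2)
        for train, test in splits:
            train_groups = {pid.split("_")[0] for pid in train}
            test_groups = {pid.split("_")[0] for pid in test}
            assert not train_groups & test_groups

    def test_same_seed_reproduces_folds(self):
        pairs = self._pairs(8)
        assert sr.grouped_kfold(pairs, 4, seed=9) == sr.grouped_kfold(pairs, 4, seed=9)

    def test_fewer_groups_than_folds_rejected(self):
        with pytest.raises(ValidationError):
            sr.grouped_kfold(self._pairs(3), folds=4)

    def test_missing_group_id_rejected(self):
        with pytest.raises(ValidationError):
            sr.grouped_kfold([{"pair_id": "a", "group_id": ""}], folds=2)


class TestTraining:
    def test_short_run_reduces_loss(self, tmp_path):
        pairs = _mini_pairs(2, seed=1)
        ckpt = sr.train(_mini_cfg(30), pairs, tmp_path)
        assert ckpt is not None and ckpt.exists()
        log = np.genfromtxt(tmp_path / "loss_log.csv", delimiter=",", names=True)
        total = np.atleast_1d(log["total"])
        assert np.all(np.isfinite(total))
        assert total[-10:].mean() < total[:10].mean()

    def test_resume_reproduces_straight_run_bit_for_bit(self, tmp_path):
        pairs = _mini_pairs(2, seed=2)
        straight = sr.train(
            _mini_cfg(10, checkpoint_interval=5), pairs, tmp_path / "straight"
        )
        half = sr.train(_mini_cfg(5, checkpoint_interval=5), pairs, tmp_path / "half")
        resumed = sr.train(
            _mini_cfg(10, checkpoint_interval=5),
            pairs,
            tmp_path / "half",
            resume=half,
        )
        net_a, _, _ = load_checkpoint(straight)
        net_b, _, _ = load_checkpoint(resumed)
        for k in net_a.params:
            assert np.array_equal(net_a.params[k].data, net_b.params[k].data), k

    def test_divisibility_violation_fails_before_training(self, tmp_path):
        ph = sr.make_phantom(
            sr.PhantomConfig(extents=(18, 18, 18), radius_range=(1.5, 3.0), seed=0)
        )
        pair = sr.make_deformed_pair(ph, sr.DeformConfig(amplitude=1.0, seed=1))
        with pytest.raises(ValidationError, match="divisible"):
            sr.train(_mini_cfg(5), [pair], tmp_path)

    def test_bad_config_rejected(self):
        with pytest.raises(ValidationError):
            sr.TrainConfig(iterations=0)
        with pytest.raises(ValidationError):
            sr.TrainConfig(folds=1)


@pytest.fixture(scope="module")
def trained(tmp_path_factory):
    tmp = tmp_path_factory.mktemp("trained")
    pairs = _mini_pairs(2, seed=4)
    ckpt = sr.train(_mini_cfg(6, checkpoint_interval=3), pairs, tmp)
    return ckpt, pairs, tmp


class TestRegisterAndEvaluate:
    def test_register_writes_outputs_with_fixed_extents(self, trained, tmp_path):
        ckpt, pairs, _ = trained
        pair = pairs[0]
        sr.write_volume(pair.fixed, tmp_path / "f.nii.gz")
        sr.write_volume(pair.fixed_label, tmp_path / "fl.nii.gz")
        sr.write_volume(pair.moving, tmp_path / "m.nii.gz")
        sr.write_volume(pair.moving_label, tmp_path / "ml.nii.gz")
        result = sr.register(
            ckpt,
            tmp_path / "f.nii.gz",
            tmp_path / "m.nii.gz",
            tmp_path / "out",
            fixed_label_path=tmp_path / "fl.nii.gz",
            moving_label_path=tmp_path / "ml.nii.gz",
        )
        dvf = sr.read_dvf(result["dvf"])
        assert dvf.extents == pair.fixed.extents
        warped_label = sr.read_volume(result["warped_label"])
        assert set(np.unique(warped_label.data)) <= {0.0, 1.0}
        assert result["seconds"] > 0

    def test_evaluate_reports_expected_metric_columns(self, trained):
        ckpt, pairs, _ = trained
        rows, agg = sr.evaluate_pairs(ckpt, pairs)
        assert len(rows) == len(pairs)
        for key in ("dsc_pre", "dsc_post", "lm_dist_post", "tre_post", "seconds"):
            assert key in agg
        assert 0.0 <= agg["dsc_pre"] <= 1.0

    def test_select_best_checkpoint_prefers_higher_dice(self, trained, tmp_path):
        ckpt, pairs, tmp = trained
        ckpts = sorted(tmp.glob("ckpt_*.npz"))
        assert len(ckpts) >= 2
        best = sr.select_best_checkpoint(ckpts, pairs[:1])
        assert best in [p for p in ckpts]


class TestCheckpointFormat:
    def test_round_trip_preserves_weights_and_config(self, tmp_path):
        net = sr.build_network(sr.NetworkConfig(levels=2, base_channels=4), seed=5)
        for p in net.parameters():
            p.data += 0.01
        path = tmp_path / "ckpt.npz"
        sr.save_checkpoint(path, net, None, 7, None, None)
        net2, meta, adam_state = load_checkpoint(path)
        assert meta["iteration"] == 7
        assert adam_state is None
        assert net2.cfg == net.cfg
        for k in net.params:
            assert np.array_equal(net.params[k].data, net2.params[k].data)
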