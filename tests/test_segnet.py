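import dataclasses

import numpy as np
import pytest

from renoquant import nn
from renoquant.evaluate import dice_coefficient
from renoquant.grids import LabeledMask, Unit, VolumeGrid
from renoquant.segnet import (
    ParenchymaSegmenter,
    PlateauScheduler,
    SegNetConfig,
    TrainConfig,
    TrainedSegmenter,
    build_network,
    postprocess_probability,
    soft_dice_loss,
    split_train_validation,
    train,
    windows_from_phantom,
)

TINY = SegNetConfig(levels=2, base_channels=4, spatial_dropout_rate=0.0)


class TestArchitecture:
    def test_smallest_legal_config_builds_and_runs(self, rng):
        net = build_network(TINY, seed=0)
        out = net.forward(rng.normal(size=(8, 8, 8)).astype(np.float32))
        assert out.value.shape == (1, 8, 8, 8)
        assert 0.0 < out.value.min() and out.value.max() < 1.0

    def test_output_shape_matches_input_for_three_levels(self, rng):
        cfg = SegNetConfig(levels=3, base_channels=4, spatial_dropout_rate=0.0)
        net = build_network(cfg, seed=0)
        out = net.forward(rng.normal(size=(16, 12, 8)).astype(np.float32))
        assert out.value.shape == (1, 16, 12, 8)

    def test_indivisible_shape_reports_axis(self):
        net = build_network(SegNetConfig(levels=3, base_channels=4))
        with pytest.raises(ValueError, match="axis 1"):
            net.forward(np.zeros((16, 10, 8), dtype=np.float32))

    @pytest.mark.parametrize(
        "flag", ["use_residual_blocks", "use_elementwise_sum", "use_skip_connections"]
    )
    def test_ablation_flags_strictly_reduce_parameters(self, flag):
        full = build_network(SegNetConfig(levels=3, base_channels=4)).n_parameters
        ablated = build_network(
            SegNetConfig(levels=3, base_channels=4, **{flag: False})
        ).n_parameters
        assert ablated < full

    def test_paper_scale_defaults(self):
        cfg = SegNetConfig()
        assert cfg.levels == 5 and cfg.spatial_dropout_rate == 0.3
        tcfg = TrainConfig()
        assert (tcfg.epochs, tcfg.iterations_per_epoch) == (80, 272)
        assert (tcfg.adam_beta1, tcfg.adam_beta2, tcfg.adam_epsilon) == (0.9, 0.999, 0.0)
        assert tcfg.learning_rate == 5e-4 and tcfg.plateau_patience_epochs == 10


class TestSoftDiceLossArrayForm:
    def test_binary_inputs_complement_dice_coefficient(self, rng):
        a = (rng.random((10, 10, 10)) > 0.6).astype(np.uint8)
        b = (rng.random((10, 10, 10)) > 0.6).astype(np.uint8)
        grid = lambda v: LabeledMask.from_binary(
            VolumeGrid(v, (1, 1, 1), unit=Unit.BINARY)
        )
        loss = soft_dice_loss(a, b, eps=0.0)
        assert 1.0 - loss == pytest.approx(dice_coefficient(grid(a), grid(b)), abs=1e-12)


class TestPlateauSchedule:
    def test_constant_loss_halves_every_patience_interval(self):
        sched = PlateauScheduler(lr=1e-3, patience=3, factor=0.5)
        # first update sets the baseline; thereafter the rate halves after
        # every `patience` consecutive non-improving epochs
        lrs = [sched.update(1.0) for _ in range(10)]
        assert lrs == [1e-3, 1e-3, 1e-3, 0.5e-3, 0.5e-3, 0.5e-3, 0.25e-3,
                       0.25e-3, 0.25e-3, 0.125e-3]

    def test_improving_loss_keeps_rate(self):
        sched = PlateauScheduler(lr=1e-3, patience=2)
        losses = [1.0, 0.9, 0.8, 0.7]
        assert all(sched.update(l) == 1e-3 for l in losses)


class TestSplit:
    def test_study_sized_split(self):
        tr, va = split_train_validation(range(393), train=315, seed=0)
        assert (len(tr), len(va)) == (315, 78)
        assert not set(tr) & set(va)
        assert sorted(tr + va) == list(range(393))

    def test_seed_reproducible(self):
        assert split_train_validation(range(50), 0.8, seed=4) == split_train_validation(
            range(50), 0.8, seed=4
        )

    def test_small_fractional_split(self):
        tr, va = split_train_validation(range(10), train=8, seed=1)
        assert (len(tr), len(va)) == (8, 2)

    def test_invalid_count_rejected(self):
        with pytest.raises(ValueError):
            split_train_validation(range(5), train=7, seed=0)


def _prob_grid(vals):
    return VolumeGrid(np.asarray(vals, dtype=np.float32), (1, 1, 1), unit=Unit.PROBABILITY)


class TestPostprocess:
    def test_single_ellipsoid_probability_gets_laterality(self):
        p = np.zeros((20, 10, 10), dtype=np.float32)
        p[13:18, 3:7, 3:7] = 0.9
        mask = postprocess_probability(_prob_grid(p))
        assert mask.sides_present == ["left"]

    def test_three_blobs_keep_two_largest(self):
        p = np.zeros((30, 10, 10), dtype=np.float32)
        p[1:7, 2:8, 2:8] = 0.9  # 216 voxels
        p[12:16, 3:7, 3:7] = 0.9  # 64 voxels
        p[22:24, 4:6, 4:6] = 0.9  # 8 voxels -> dropped
        mask = postprocess_probability(_prob_grid(p))
        assert mask.grid.values.sum() == 216 + 64
        assert not mask.grid.values[22:24].any()

    def test_all_background_returns_empty_with_warning(self):
        with pytest.warns(UserWarning, match="no foreground"):
            mask = postprocess_probability(_prob_grid(np.zeros((8, 8, 8))))
        assert mask.grid.values.sum() == 0


def _tiny_pair(rng, shape=(12, 8, 8)):
    """A trivially learnable pair: bright box on dark background."""
    target = np.zeros(shape, dtype=np.uint8)
    target[3:9, 2:6, 2:6] = 1
    hu = np.where(target, 35.0, 40.0) + rng.normal(0, 5.0, shape)
    ct = VolumeGrid(hu.astype(np.float32), (1, 1, 1), unit=Unit.HU)
    return ct, VolumeGrid(target, (1, 1, 1), unit=Unit.BINARY)


class TestTraining:
    def test_one_adam_step_decreases_loss(self, rng):
        ct, m = _tiny_pair(rng)
        net = build_network(TINY, seed=1)
        from renoquant.segnet import normalize_ct

        x = normalize_ct(ct.values, TINY)
        t = np.asarray(m.values, dtype=np.float32)[None]
        opt = nn.Adam(net.params.values(), lr=1e-4)
        pred = net.forward(x)
        l0 = nn.soft_dice_loss(pred, t)
        l0.backward()
        opt.step()
        l1 = nn.soft_dice_loss(net.forward(x), t)
        assert float(l1.value) < float(l0.value)

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            train(build_network(TINY), [], TrainConfig())
        with pytest.raises(ValueError):
            ParenchymaSegmenter([], TINY, TrainConfig())

    def test_short_fit_logs_and_improves(self, rng):
        ct, m = _tiny_pair(rng)
        tcfg = TrainConfig(epochs=3, iterations_per_epoch=12, seed=0)
        res = ParenchymaSegmenter([(ct, m)], TINY, tcfg).fit()
        log = res.training_log
        assert list(log.columns) == ["epoch", "loss", "lr"]
        assert len(log) == 3
        assert log["loss"].iloc[-1] < log["loss"].iloc[0]
        assert "parameters" in res.summary()

    def test_serialization_roundtrip_is_bit_identical(self, rng, tmp_path):
        ct, m = _tiny_pair(rng)
        tcfg = TrainConfig(epochs=1, iterations_per_epoch=5, seed=2)
        res = ParenchymaSegmenter([(ct, m)], TINY, tcfg).fit()
        path = tmp_path / "model.npz"
        res.save(path)
        back = TrainedSegmenter.load(path)
        p1 = res.predict_proba(ct).values
        p2 = back.predict_proba(ct).values
        np.testing.assert_array_equal(p1, p2)
        assert back.config == res.config
        assert back.training_log.shape == res.training_log.shape

    def test_unknown_checkpoint_schema_rejected(self, tmp_path, rng):
        import json

        path = tmp_path / "bad.npz"
        np.savez(path, __meta__=np.frombuffer(json.dumps({"schema": "x"}).encode(), np.uint8))
        with pytest.raises(ValueError):
            TrainedSegmenter.load(path)


class TestWindows:
    def test_windows_from_phantom_shapes_agree(self, phantom0):
        ct_w, m_w = windows_from_phantom(phantom0, (48, 32, 32))
        assert ct_w.shape == m_w.shape == (48, 32, 32)
        assert ct_w.meta["crop"] == m_w.meta["crop"]
        assert m_w.values.sum() > 0
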