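"""Loss contracts, gradient correctness, training behaviour, tiled inference."""

import numpy as np
import pytest

from bootseg.nets import (
    ModelSpec,
    TrainConfig,
    UNet,
    load_checkpoint,
    masked_mse,
    masked_mse_grad,
    predict_2d_stack,
    predict_3d,
    save_checkpoint,
    tiled_predict,
    train_3d_from_synthetic,
    train_3d_mtlsd,
    train_sparse_2d,
)
from bootseg.synth import (
    DegradeParams,
    SynthParams,
    generate_labels,
    make_training_pair,
    render_raw,
)
from bootseg.volumes import LabelVolume, SparseAnnotation, VolumeGrid

SIGMA = (120.0, 80.0, 80.0)


class TestMaskedMSE:
    def test_perfect_prediction_is_zero(self, rng):
        t = rng.random((3, 4, 4)).astype(np.float32)
        assert masked_mse(t, t, np.ones_like(t)) == 0.0

    def test_all_zero_weights_give_zero_loss(self, rng):
        p = rng.random((2, 4, 4)).astype(np.float32)
        t = rng.random((2, 4, 4)).astype(np.float32)
        assert masked_mse(p, t, np.zeros_like(p)) == 0.0

    def test_hand_computed_value(self):
        pred = np.array([1.0, 0.0])
        target = np.array([0.0, 0.0])
        weights = np.array([1.0, 3.0])
        assert masked_mse(pred, target, weights) == pytest.approx(0.25)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            masked_mse(np.zeros(3), np.zeros(4), np.zeros(3))

    def test_zero_weight_entries_have_exactly_zero_gradient(self, rng):
        """Finite differences confirm masked entries cannot move the loss."""
        pred = rng.random((3, 5, 5))
        target = rng.random((3, 5, 5))
        weights = (rng.random((3, 5, 5)) > 0.4).astype(np.float64)
        grad = masked_mse_grad(pred, target, weights)
        assert np.all(grad[weights == 0] == 0.0)
        base = masked_mse(pred, target, weights)
        for idx in zip(*np.nonzero(weights == 0)):
            bumped = pred.copy()
            bumped[idx] += 0.1
            assert masked_mse(bumped, target, weights) == base


class TestUNetMechanics:
    def test_analytic_gradient_matches_finite_differences(self, rng):
        spec = ModelSpec(dimensionality=2, in_channels=1, out_heads=(("lsd", 2),),
                         depth=1, base_features=3)
        model = UNet(spec, seed=0)
        x = rng.random((1, 8, 8)).astype(np.float32)
        t = rng.random((2, 8, 8)).astype(np.float32)
        w = (rng.random((2, 8, 8)) > 0.3).astype(np.float32)
        pred = model.forward(x)
        model.backward({"lsd": masked_mse_grad(pred["lsd"], t, w)})
        grads = model.gradients()
        params = model.parameters()
        eps = 1e-3
        for name in ("down0_0.weight", "bottom_0.weight", "head_lsd_0.weight"):
            flat_idx = (0,) * params[name].ndim
            orig = params[name][flat_idx]
            params[name][flat_idx] = orig + eps
            lp = masked_mse(model.forward(x)["lsd"], t, w)
            params[name][flat_idx] = orig - eps
            lm = masked_mse(model.forward(x)["lsd"], t, w)
            params[name][flat_idx] = orig
            fd = (lp - lm) / (2 * eps)
            assert abs(fd - grads[name][flat_idx]) < 1e-4

    def test_outputs_live_in_unit_interval(self, rng):
        spec = ModelSpec(dimensionality=3, in_channels=2, out_heads=(("affs", 3),),
                         depth=1, base_features=4)
        model = UNet(spec, seed=1)
        out = model.forward(rng.random((2, 8, 16, 16)).astype(np.float32))
        assert out["affs"].min() >= 0.0 and out["affs"].max() <= 1.0

    def test_checkpoint_roundtrip(self, tmp_path, rng):
        spec = ModelSpec(dimensionality=2, in_channels=1, out_heads=(("lsd", 6),),
                         depth=1, base_features=4)
        model = UNet(spec, seed=2)
        x = rng.random((1, 16, 16)).astype(np.float32)
        want = model.forward(x)["lsd"]
        path = tmp_path / "model.npz"
        save_checkpoint(model, path)
        back = load_checkpoint(path)
        np.testing.assert_array_equal(back.forward(x)["lsd"], want)


class TestTiledInference:
    def test_tiled_equals_untiled_3d(self, rng):
        spec = ModelSpec(dimensionality=3, in_channels=2, out_heads=(("affs", 3),),
                         depth=2, base_features=4)
        model = UNet(spec, seed=0)
        x = rng.random((2, 16, 48, 48)).astype(np.float32)
        full = tiled_predict(model, x)
        tiled = tiled_predict(model, x, tile_shape=(44, 72, 72))
        assert np.abs(full["affs"] - tiled["affs"]).max() < 1e-4

    def test_tiled_equals_untiled_2d(self, rng):
        spec = ModelSpec(dimensionality=2, in_channels=1, out_heads=(("lsd", 6),),
                         depth=2, base_features=6)
        model = UNet(spec, seed=1)
        x = rng.random((1, 96, 96)).astype(np.float32)
        full = tiled_predict(model, x)
        tiled = tiled_predict(model, x, tile_shape=(88, 88))
        assert np.abs(full["lsd"] - tiled["lsd"]).max() < 1e-4

    def test_section_permutation_permutes_outputs(self, rng):
        spec = ModelSpec(dimensionality=2, in_channels=1, out_heads=(("lsd", 6),),
                         depth=1, base_features=4)
        model = UNet(spec, seed=3)
        vol = VolumeGrid(rng.random((5, 32, 32)).astype(np.float32))
        out = predict_2d_stack(model, vol)
        perm = [3, 1, 4, 0, 2]
        vol_p = VolumeGrid(vol.data[perm])
        out_p = predict_2d_stack(model, vol_p)
        np.testing.assert_array_equal(out_p.data, out.data[:, perm])

    def test_mtlsd_heads_contract(self, rng):
        spec = ModelSpec(dimensionality=3, in_channels=1,
                         out_heads=(("affs", 3), ("lsd", 10)), depth=1,
                         base_features=4)
        model = UNet(spec, seed=4)
        vol = VolumeGrid(rng.random((8, 16, 16)).astype(np.float32))
        preds = predict_3d(model, vol)
        assert set(preds) == {"affs", "lsd"}
        assert preds["affs"].data.shape == (3, 8, 16, 16)
        assert preds["lsd"].data.shape == (10, 8, 16, 16)

    def test_channel_mismatch_rejected(self, rng):
        spec = ModelSpec(dimensionality=3, in_channels=6, out_heads=(("affs", 3),),
                         depth=1, base_features=4)
        model = UNet(spec, seed=5)
        bad = VolumeGrid(rng.random((2, 8, 16, 16)).astype(np.float32),
                         semantic="descriptor")
        with pytest.raises(ValueError):
            predict_3d(model, bad)


def _dense_section_annotation(seed=3):
    labels = generate_labels(SynthParams(shape=(8, 64, 64), num_objects=(8, 12),
                                         seed=seed))
    section = LabelVolume(labels.data[:1].copy(), labels.voxel_size)
    raw = render_raw(section, seed=seed + 1)
    ann = SparseAnnotation(section, np.ones(section.data.shape, bool))
    return raw, ann


class TestTraining2D:
    SPEC = ModelSpec(dimensionality=2, in_channels=1, out_heads=(("lsd", 6),),
                     depth=2, base_features=12)

    def test_zero_iterations_returns_initialized_model(self):
        raw, ann = _dense_section_annotation()
        cfg = TrainConfig(iterations=0, patch_shape=(64, 64), sigma=SIGMA)
        report = train_sparse_2d(raw, ann, self.SPEC, cfg)
        assert report.losses == []
        assert report.model is not None

    def test_overfits_single_dense_section(self):
        raw, ann = _dense_section_annotation()
        # augmentations off: this probes pure memorization capacity
        cfg = TrainConfig(iterations=300, patch_shape=(64, 64),
                          learning_rate=2e-3, sigma=SIGMA, master_seed=11,
                          augmentations=())
        report = train_sparse_2d(raw, ann, self.SPEC, cfg)
        assert report.losses[-1] < 0.1 * report.losses[0]

    def test_empty_annotation_rejected(self):
        raw, ann = _dense_section_annotation()
        empty = SparseAnnotation(
            LabelVolume(np.zeros_like(ann.labels.data), ann.labels.voxel_size),
            np.zeros(ann.labels.data.shape, bool))
        with pytest.raises(ValueError):
            train_sparse_2d(raw, empty, self.SPEC,
                            TrainConfig(iterations=1, patch_shape=(64, 64)))

    def test_unmet_labeled_fraction_raises_with_guidance(self):
        raw, ann = _dense_section_annotation()
        tiny = np.zeros_like(ann.labeled_mask)
        tiny[0, :2, :2] = True
        sparse = SparseAnnotation(
            LabelVolume(np.where(tiny, ann.labels.data, 0).astype(np.uint64),
                        ann.labels.voxel_size), tiny)
        cfg = TrainConfig(iterations=1, patch_shape=(64, 64),
                          min_labeled_fraction=0.5)
        with pytest.raises(RuntimeError, match="labeled-fraction"):
            train_sparse_2d(raw, sparse, self.SPEC, cfg)


class TestTraining3D:
    def test_synthetic_training_beats_untrained_model(self):
        spec = ModelSpec(dimensionality=3, in_channels=6, out_heads=(("affs", 3),),
                         depth=2, base_features=8)
        synth = SynthParams(shape=(8, 24, 24), num_objects=(3, 6))
        degrade = DegradeParams()
        cfg = TrainConfig(iterations=120, learning_rate=2e-3, sigma=SIGMA,
                          master_seed=5)
        report = train_3d_from_synthetic(spec, cfg, synth, degrade)
        holdout = make_training_pair(
            SynthParams(shape=(8, 24, 24), num_objects=(3, 6), seed=987654),
            SIGMA, DegradeParams(seed=987655))
        x, t, w = holdout[0].data, holdout[1].data, holdout[2].data
        trained_loss = masked_mse(report.model.forward(x)["affs"], t, w)
        untrained = UNet(spec, seed=123)
        untrained_loss = masked_mse(untrained.forward(x)["affs"], t, w)
        assert trained_loss < untrained_loss

    def test_loss_trace_deterministic_under_master_seed(self):
        spec = ModelSpec(dimensionality=3, in_channels=6, out_heads=(("affs", 3),),
                         depth=1, base_features=4)
        synth = SynthParams(shape=(8, 16, 16), num_objects=(2, 4))
        cfg = TrainConfig(iterations=15, learning_rate=1e-3, sigma=SIGMA,
                          master_seed=9)
        a = train_3d_from_synthetic(spec, cfg, synth, DegradeParams())
        b = train_3d_from_synthetic(spec, cfg, synth, DegradeParams())
        assert a.losses == b.losses

    def test_mtlsd_overfit_and_head_additivity(self):
        labels = generate_labels(SynthParams(shape=(16, 32, 32),
                                             num_objects=(5, 9), seed=31))
        raw = render_raw(labels, seed=32)
        spec = ModelSpec(dimensionality=3, in_channels=1,
                         out_heads=(("affs", 3), ("lsd", 10)), depth=2,
                         base_features=8)
        cfg = TrainConfig(iterations=200, patch_shape=(16, 32, 32),
                          learning_rate=2e-3, sigma=SIGMA, master_seed=13,
                          augmentations=())  # memorization probe
        report = train_3d_mtlsd(raw, labels, spec, cfg)
        assert report.losses[-1] < 0.35 * report.losses[0]

        # auxiliary-head contract: supervising only the affinity head leaves
        # the descriptor head's parameters untouched
        from bootseg.nets.infer import normalize_raw
        from bootseg.targets import compute_affinities

        model = report.model
        x = normalize_raw(raw.data)[None]
        preds = model.forward(x)
        affs = compute_affinities(labels)
        model.zero_grad()
        model.backward({"affs": masked_mse_grad(
            preds["affs"], affs.data, affs.mask.astype(np.float32))})
        grads = model.gradients()
        assert not grads["head_lsd_0.weight"].any()
        assert grads["head_affs_0.weight"].any()

    def test_zero_iterations_3d(self):
        spec = ModelSpec(dimensionality=3, in_channels=6, out_heads=(("affs", 3),),
                         depth=1, base_features=4)
        report = train_3d_from_synthetic(
            spec, TrainConfig(iterations=0, sigma=SIGMA),
            SynthParams(shape=(8, 16, 16)), DegradeParams())
        assert report.losses == []
        assert report.model is not None
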