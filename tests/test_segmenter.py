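"""Model contracts, training determinism, and learning behavior."""

from __future__ import annotations

import numpy as np
import pytest

import patchseg as ps
from patchseg.assembly_eval import integrate, mean_iou
from patchseg.patching import PatchConfig
from patchseg.segmenter import (
    ConfigError,
    ModelConfig,
    TrainConfig,
    UNet,
    build_model,
    predict_patches,
    train_segmenter,
)
from patchseg.selfsup_loss import LossWeights

from conftest import DESK_CHANNELS, DESK_PATCH, train_desk_segmenter


@pytest.fixture(scope="module")
def tiny_scene():
    return ps.generate_scene(
        ps.SceneConfig(field_height=96, field_width=96, n_cells=6,
                       min_center_spacing=18.0, seed=4)
    )


class TestModel:
    def test_output_shape_and_range(self):
        model = build_model(ModelConfig(in_channels=3, depth=2, base_filters=4, seed=0))
        out = model.predict(np.random.default_rng(0).random((2, 3, 32, 32)))
        assert out.shape == (2, 1, 32, 32)
        assert (out > 0).all() and (out < 1).all()

    def test_seeded_init_is_deterministic(self):
        a = build_model(ModelConfig(in_channels=2, depth=2, base_filters=4, seed=7))
        b = build_model(ModelConfig(in_channels=2, depth=2, base_filters=4, seed=7))
        for pa, pb in zip(a.params, b.params):
            assert np.array_equal(pa.data, pb.data)

    def test_depth_divisibility_enforced(self):
        ok = build_model(ModelConfig(in_channels=1, depth=3, base_filters=2, seed=0))
        assert ok.predict(np.zeros((1, 1, 32, 32))).shape == (1, 1, 32, 32)
        deep = build_model(ModelConfig(in_channels=1, depth=6, base_filters=2, seed=0))
        with pytest.raises(ConfigError):
            deep.predict(np.zeros((1, 1, 32, 32)))

    def test_wrong_channel_count_rejected(self):
        model = build_model(ModelConfig(in_channels=2, depth=2, base_filters=2, seed=0))
        with pytest.raises(ConfigError):
            model.predict(np.zeros((1, 5, 32, 32)))

    def test_checkpoint_round_trip(self, tmp_path):
        model = build_model(ModelConfig(in_channels=2, depth=2, base_filters=4, seed=1))
        x = np.random.default_rng(2).random((1, 2, 32, 32))
        ref = model.predict(x)
        path = tmp_path / "m.ckpt.npz"
        model.save(path)
        loaded = UNet.load(path)
        assert np.array_equal(loaded.predict(x), ref)


def _tiny_train(scene, seed=0, epochs=3):
    mask = np.ones(scene.labels.shape, dtype=np.uint8)
    mcfg = ModelConfig(in_channels=2, depth=2, base_filters=4, seed=seed)
    tcfg = TrainConfig(max_epochs=epochs, patience=50, weights=LossWeights(beta=0.0),
                       patch=PatchConfig(k=32, disk_sigma=8.0), seed=seed)
    return train_segmenter(scene.channels, scene.centers, mask, mcfg, tcfg,
                           channel_names=["FL"])


class TestTraining:
    def test_no_markers_rejected(self, tiny_scene):
        from patchseg.markers import MarkerSet

        mask = np.ones(tiny_scene.labels.shape)
        with pytest.raises(ValueError):
            train_segmenter(tiny_scene.channels, MarkerSet(), mask,
                            ModelConfig(in_channels=2, depth=2, base_filters=4),
                            TrainConfig(patch=PatchConfig(k=32, disk_sigma=8.0)),
                            channel_names=["FL"])

    def test_mask_shape_must_match(self, tiny_scene):
        with pytest.raises(ValueError):
            train_segmenter(tiny_scene.channels, tiny_scene.centers, np.ones((10, 10)),
                            ModelConfig(in_channels=2, depth=2, base_filters=4),
                            TrainConfig(patch=PatchConfig(k=32, disk_sigma=8.0)),
                            channel_names=["FL"])

    def test_identical_seeds_identical_histories(self, tiny_scene):
        _, h1 = _tiny_train(tiny_scene, seed=3)
        _, h2 = _tiny_train(tiny_scene, seed=3)
        assert np.allclose(h1.totals(), h2.totals(), rtol=1e-12)

    def test_history_length_bounded(self, tiny_scene):
        _, h = _tiny_train(tiny_scene, epochs=2)
        assert h.stopped_at == len(h.epochs) == 2


class TestPrediction:
    def test_one_prediction_per_marker(self, tiny_scene):
        model, _ = _tiny_train(tiny_scene, epochs=1)
        preds = predict_patches(model, tiny_scene.channels, tiny_scene.centers,
                                PatchConfig(k=32, disk_sigma=8.0), ["FL"], batch_size=100)
        assert len(preds) == len(tiny_scene.centers)
        assert sorted(p.marker_id for p in preds) == list(range(1, len(preds) + 1))
        for p in preds:
            assert (p.y > 0).all() and (p.y < 1).all()

    def test_prediction_invariant_to_marker_order(self, tiny_scene):
        from patchseg.markers import MarkerSet

        model, _ = _tiny_train(tiny_scene, epochs=1)
        pcfg = PatchConfig(k=32, disk_sigma=8.0)
        fwd = predict_patches(model, tiny_scene.channels, tiny_scene.centers, pcfg,
                              ["FL"], batch_size=100)
        perm = MarkerSet(points=tiny_scene.centers.points[::-1].copy(),
                         pixel_size=tiny_scene.centers.pixel_size)
        rev = predict_patches(model, tiny_scene.channels, perm, pcfg, ["FL"], batch_size=100)
        by_origin_fwd = {p.origin: p.y for p in fwd}
        by_origin_rev = {p.origin: p.y for p in rev}
        for origin, y in by_origin_fwd.items():
            assert np.allclose(y, by_origin_rev[origin], atol=1e-12)


class TestLearningBehavior:
    """Slow checks on the session-scoped desk-scale run."""

    def test_accuracy_improves_with_training(self, trained_run):
        assert trained_run["miou"] > trained_run["miou_by_epoch"][0]

    def test_generalizes_to_unseen_scene(self, trained_run):
        scene1 = ps.generate_scene(ps.SceneConfig(seed=11))
        preds = predict_patches(trained_run["model"], scene1.channels, scene1.centers,
                                DESK_PATCH, DESK_CHANNELS, batch_size=10_000)
        lab = integrate(preds, scene1.labels.shape)
        miou = mean_iou(lab, scene1.labels).mean_iou
        assert abs(miou - trained_run["miou"]) <= 0.15
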