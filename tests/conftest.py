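"""Shared fixtures.

The expensive artifacts — trained segmentation models and the translator
cross-validation — are session-scoped so the whole suite trains each model
once. Desk-scale study conditions: 256×256 scenes of 48 touching cells at 50%
coverage, 32×32 patches (σ = 8 positional disk), depth-2 encoder–decoder with
8 base filters, λ = 3.32, β = 15.
"""

from __future__ import annotations

import numpy as np
import pytest

import patchseg as ps
from patchseg.assembly_eval import integrate, mean_iou
from patchseg.patching import PatchConfig
from patchseg.segmenter import ModelConfig, TrainConfig, predict_patches, train_segmenter
from patchseg.selfsup_loss import LossWeights
from patchseg.nucleus_translator import TranslatorConfig, crossval_translate

DESK_PATCH = PatchConfig(k=32, disk_sigma=8.0)
DESK_CHANNELS = ["FL"]
TRAIN_EPOCHS = 200


@pytest.fixture(scope="session")
def scene0():
    return ps.generate_scene(ps.SceneConfig(seed=0))


@pytest.fixture(scope="session")
def scenes3(scene0):
    return [scene0] + [ps.generate_scene(ps.SceneConfig(seed=s)) for s in (1, 2)]


@pytest.fixture(scope="session")
def mask0(scene0):
    return ps.mask_from_fluorescence(scene0.channels.channels["FL"], alpha=0.5, kappa=1.0)


def train_desk_segmenter(scene, mask, markers=None, beta=15.0, seed=0, track=False):
    """One desk-scale self-supervised training run; returns a result record."""
    markers = scene.centers if markers is None else markers
    mcfg = ModelConfig(in_channels=len(DESK_CHANNELS) + 1, depth=2, base_filters=8, seed=seed)
    tcfg = TrainConfig(
        max_epochs=TRAIN_EPOCHS, patience=5, rel_tol=1e-3,
        weights=LossWeights(beta=beta), patch=DESK_PATCH, seed=seed,
    )
    track_miou = {}

    def cb(model, epoch, bd):
        if track and epoch == 0:
            preds = predict_patches(model, scene.channels, markers, DESK_PATCH,
                                    DESK_CHANNELS, batch_size=10_000)
            lab = integrate(preds, scene.labels.shape)
            track_miou[epoch] = mean_iou(lab, scene.labels).mean_iou

    model, history = train_segmenter(
        scene.channels, markers, mask, mcfg, tcfg,
        channel_names=DESK_CHANNELS, epoch_callback=cb if track else None,
    )
    preds = predict_patches(model, scene.channels, markers, DESK_PATCH,
                            DESK_CHANNELS, batch_size=10_000)
    labels = integrate(preds, scene.labels.shape)
    ev = mean_iou(labels, scene.labels)
    return dict(model=model, history=history, labels=labels, eval=ev,
                miou=ev.mean_iou, miou_by_epoch=track_miou)


@pytest.fixture(scope="session")
def trained_run(scene0, mask0):
    """Full-model run: λ = 3.32, β = 15, graph-cut mask, true markers."""
    return train_desk_segmenter(scene0, mask0, track=True)


@pytest.fixture(scope="session")
def ablation_run(scene0):
    """Mask-free ablation: β = 0, all-ones mask."""
    ones = np.ones(scene0.labels.shape, dtype=np.uint8)
    return train_desk_segmenter(scene0, ones, beta=0.0)


@pytest.fixture(scope="session")
def translator_cv(scenes3):
    """3-fold image→nucleus cross-validation on the FL channel."""
    mcfg = ModelConfig(in_channels=1, depth=2, base_filters=8, seed=0)
    return crossval_translate(scenes3, "FL", mcfg, TranslatorConfig(seed=0))


@pytest.fixture(scope="session")
def synthetic_marker_run(scene0, mask0, translator_cv):
    """Segmenter trained with the fold-0 synthetic markers instead of true anchors."""
    markers = translator_cv[0]["markers"]
    return train_desk_segmenter(scene0, mask0, markers=markers)
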