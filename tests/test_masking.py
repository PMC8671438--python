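"""Graph-cut masking: normalization, energies, optimality, classifier path."""

from __future__ import annotations

import numpy as np
import pytest

from patchseg.masking import (
    GraphCutProblem,
    ScribbleSet,
    estimate_alpha,
    graphcut_energy,
    graphcut_mask,
    mask_from_brightfield,
    normalize_intensity,
    pixel_classifier_probability,
)
from patchseg.fixtures import scribbles_from_labels


class TestNormalizeIntensity:
    def test_endpoint_mapping(self):
        img = np.linspace(0.0, 100.0, 101).reshape(1, -1)
        x = normalize_intensity(img, 0.0, 100.0, eps=1e-6)
        assert x.min() == pytest.approx(1e-6)
        assert x.max() == pytest.approx(1.0 - 1e-6)

    def test_constant_image_maps_to_half(self):
        assert (normalize_intensity(np.full((5, 5), 3.7)) == 0.5).all()

    def test_midpoint(self):
        img = np.arange(101.0).reshape(1, -1)
        x = normalize_intensity(img, 1.0, 99.0)
        assert x[0, 50] == pytest.approx(0.5, abs=0.01)

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError):
            normalize_intensity(np.array([[0.0, np.nan]]))


def test_estimate_alpha_clamps():
    assert estimate_alpha(0.5) == 0.5
    assert estimate_alpha(0.99) == 0.95
    assert estimate_alpha(0.7) == pytest.approx(0.7)
    with pytest.raises(ValueError):
        estimate_alpha(1.5)


class TestGraphCut:
    def test_unary_only_map_rule(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(0.05, 0.95, size=(6, 7))
        mask = graphcut_mask(GraphCutProblem(x=x, alpha=0.5, kappa=0.0))
        assert np.array_equal(mask.m, (x > 0.5).astype(np.uint8))

    def test_uniform_bright_image_is_all_foreground(self):
        x = np.full((5, 5), 0.9)
        for kappa in (0.0, 1.0, 10.0):
            mask = graphcut_mask(GraphCutProblem(x=x, alpha=0.5, kappa=kappa))
            assert mask.m.all()

    def test_rejects_unclipped_intensities(self):
        with pytest.raises(ValueError):
            GraphCutProblem(x=np.array([[0.0, 0.5]]), alpha=0.5)

    def test_energy_optimality_against_random_labelings(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(0.05, 0.95, size=(8, 8))
        prob = GraphCutProblem(x=x, alpha=0.4, kappa=0.7)
        got = graphcut_mask(prob)
        e_star = graphcut_energy(prob, got.m)
        for _ in range(100):
            y = rng.integers(0, 2, size=(8, 8))
            assert e_star <= graphcut_energy(prob, y) + 1e-9

    def test_foreground_grows_with_alpha(self):
        rng = np.random.default_rng(2)
        for _ in range(5):
            x = rng.uniform(0.05, 0.95, size=(6, 6))
            prev = None
            for alpha in (0.2, 0.4, 0.6, 0.8):
                m = graphcut_mask(GraphCutProblem(x=x, alpha=alpha, kappa=0.3)).m
                if prev is not None:
                    assert (m >= prev).all()  # never shrinks
                prev = m

    def test_eight_connectivity_supported(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(0.05, 0.95, size=(5, 5))
        m = graphcut_mask(GraphCutProblem(x=x, alpha=0.5, kappa=0.5, connectivity=8))
        assert m.m.shape == (5, 5)


class TestPixelClassifier:
    @staticmethod
    def _two_tone(seed=0):
        rng = np.random.default_rng(seed)
        img = np.full((64, 64), 0.2) + 0.02 * rng.standard_normal((64, 64))
        img[:, 32:] += 0.5
        scr = np.zeros((64, 64), dtype=np.uint8)
        scr[10, 36:62] = 1  # strokes across the bright side = foreground
        scr[40, 38:60] = 1
        scr[10, 2:28] = 2
        scr[45, 4:24] = 2
        return img, ScribbleSet(labels=scr)

    def test_bright_region_probability(self):
        img, scr = self._two_tone()
        prob = pixel_classifier_probability(img, scr)
        assert (prob[:, 36:] > 0.5).mean() >= 0.95
        assert prob.min() >= 0.0 and prob.max() <= 1.0

    def test_single_class_scribbles_rejected(self):
        scr = np.zeros((8, 8), dtype=np.uint8)
        scr[2, 2] = 1
        with pytest.raises(ValueError):
            ScribbleSet(labels=scr)

    def test_blank_image_mask_is_uniform(self):
        img = np.full((32, 32), 0.5)
        scr = np.zeros((32, 32), dtype=np.uint8)
        scr[5, 5:15] = 1
        scr[20, 5:15] = 2
        m = mask_from_brightfield(img, ScribbleSet(labels=scr), alpha=0.6, kappa=1.0)
        assert m.m.all() or not m.m.any()

    def test_huge_kappa_gives_uniform_mask(self):
        img, scr = self._two_tone()
        m = mask_from_brightfield(img, scr, alpha=0.5, kappa=1e4)
        assert m.m.all() or not m.m.any()


def test_brightfield_mask_recovers_fixture_foreground(scene0):
    """Scribble-trained classifier + graph cut segments the low-contrast
    bright-field channel to IOU ≥ 0.8 against the true cell area."""
    scr = ScribbleSet(labels=scribbles_from_labels(scene0.labels, 0))
    m = mask_from_brightfield(scene0.channels.channels["BF"], scr, alpha=0.5, kappa=2.0)
    truth = scene0.labels > 0
    got = m.m.astype(bool)
    iou = (got & truth).sum() / (got | truth).sum()
    assert iou >= 0.8


def test_fluorescence_mask_recovers_fixture_foreground(scene0, mask0):
    truth = scene0.labels > 0
    got = mask0.m.astype(bool)
    iou = (got & truth).sum() / (got | truth).sum()
    assert iou >= 0.9
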