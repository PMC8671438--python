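"""The patch-consistency objective: printed examples, additivity, gradients."""

from __future__ import annotations

import numpy as np
import pytest

from patchseg import nn
from patchseg.patching import PatchPrediction
from patchseg.selfsup_loss import (
    LossWeights,
    balanced_lambda,
    loss_for_tile,
    partition_by_tile,
    total_loss,
    total_loss_autograd,
)

from oracles import brute_force_loss


def const_pred(val, k, origin, marker_id):
    return PatchPrediction(y=np.full((k, k), val), origin=origin, marker_id=marker_id)


class TestTotalLoss:
    def test_near_zero_predictions_give_near_zero_loss(self):
        w = LossWeights()
        preds = [const_pred(w.eps, 8, (0, 0), 1), const_pred(w.eps, 8, (4, 4), 2)]
        bd = total_loss(preds, np.ones((16, 16)), w)
        assert abs(bd.total) < 1e-3

    def test_disjoint_saturated_patches_only_area(self):
        w = LossWeights()
        preds = [const_pred(1 - w.eps, 4, (0, 0), 1), const_pred(1 - w.eps, 4, (8, 8), 2)]
        bd = total_loss(preds, np.ones((16, 16)), w)
        assert bd.consistency_term == 0.0
        assert bd.mask_term == 0.0
        assert bd.total == pytest.approx(-32.0, abs=1e-3)

    def test_balanced_lambda_cancels_area_for_coin_toss(self):
        k = 16
        w = LossWeights(lam=3.32, beta=0.0)
        preds = [const_pred(0.5, k, (0, 0), 1), const_pred(0.5, k, (0, 0), 2)]
        bd = total_loss(preds, np.ones((k, k)), w)
        assert bd.area_term == pytest.approx(-(k**2))
        assert bd.consistency_term == pytest.approx(3.32 * np.log10(2.0) * k**2)
        # residual cancellation error below 0.1% of the area term
        assert abs(bd.total) <= 1e-3 * k**2

    def test_outside_mask_penalty(self):
        w = LossWeights(beta=15.0)
        preds = [const_pred(1 - w.eps, 4, (0, 0), 1)]
        bd = total_loss(preds, np.zeros((8, 8)), w)
        assert bd.total == pytest.approx((15.0 - 1.0) * 16, abs=1e-2)

    def test_breakdown_signs_and_sum(self):
        rng = np.random.default_rng(0)
        preds = [
            PatchPrediction(y=rng.uniform(0.1, 0.9, (6, 6)), origin=(i * 3, i * 2), marker_id=i)
            for i in range(3)
        ]
        bd = total_loss(preds, (rng.random((16, 16)) > 0.5).astype(int), LossWeights())
        assert bd.area_term <= 0.0
        assert bd.consistency_term >= 0.0
        assert bd.mask_term >= 0.0
        assert bd.total == pytest.approx(bd.area_term + bd.consistency_term + bd.mask_term)

    def test_out_of_frame_patch_rejected(self):
        with pytest.raises(ValueError):
            total_loss([const_pred(0.5, 8, (12, 12), 1)], np.ones((16, 16)), LossWeights())


class TestTileLoss:
    def test_single_patch_has_no_consistency(self):
        bd = loss_for_tile([const_pred(0.7, 8, (0, 0), 1)], np.ones((16, 16)), LossWeights())
        assert bd.consistency_term == 0.0

    def test_empty_tile_is_zero(self):
        bd = loss_for_tile([], np.ones((8, 8)), LossWeights())
        assert bd.total == 0.0

    def test_tile_additivity_without_cross_tile_overlap(self):
        """When no window crosses a tile boundary, tile losses sum to the total."""
        rng = np.random.default_rng(1)
        w = LossWeights()
        mask = (rng.random((64, 64)) > 0.4).astype(int)
        preds, points = [], []
        for i, (r0, c0) in enumerate([(2, 2), (10, 12), (40, 8), (44, 40), (8, 44)]):
            preds.append(PatchPrediction(y=rng.uniform(0.2, 0.8, (12, 12)),
                                         origin=(r0, c0), marker_id=i + 1))
            points.append((r0 + 6, c0 + 6))
        tiles = partition_by_tile(np.array(points), 32)
        total_by_tiles = sum(
            loss_for_tile([preds[i] for i in idx], mask, w).total for idx in tiles.values()
        )
        assert total_by_tiles == pytest.approx(total_loss(preds, mask, w).total, abs=1e-9)


class TestAutogradLoss:
    def test_matches_numpy_reference(self):
        rng = np.random.default_rng(2)
        mask = (rng.random((20, 20)) > 0.3).astype(int)
        ys, origins, preds = [], [], []
        for i in range(3):
            y = rng.uniform(0.05, 0.95, (8, 8))
            o = (int(rng.integers(0, 12)), int(rng.integers(0, 12)))
            ys.append(nn.Tensor(y, requires_grad=True))
            origins.append(o)
            preds.append(PatchPrediction(y=y, origin=o, marker_id=i + 1))
        w = LossWeights()
        terms = total_loss_autograd(ys, origins, mask, w)
        ref = total_loss(preds, mask, w)
        assert terms["total"].item() == pytest.approx(ref.total, abs=1e-9)
        assert terms["area"].item() == pytest.approx(ref.area_term, abs=1e-9)
        assert terms["consistency"].item() == pytest.approx(ref.consistency_term, abs=1e-9)
        assert terms["mask"].item() == pytest.approx(ref.mask_term, abs=1e-9)

    def test_contested_pixel_gradient_pushes_claims_apart(self):
        """When the partner's claim is high, the derivative of the loss with
        respect to the own claim is positive (descent reduces the claim)."""
        w = LossWeights()
        for partner in (0.9, 0.95):
            yi = nn.Tensor(np.full((4, 4), 0.6), requires_grad=True)
            yj = nn.Tensor(np.full((4, 4), partner), requires_grad=True)
            terms = total_loss_autograd([yi, yj], [(0, 0), (0, 0)], np.ones((4, 4)), w)
            terms["total"].backward()
            assert (yi.grad > 0).all()
        # against a low partner claim, the area reward dominates
        yi = nn.Tensor(np.full((4, 4), 0.6), requires_grad=True)
        yj = nn.Tensor(np.full((4, 4), 0.05), requires_grad=True)
        terms = total_loss_autograd([yi, yj], [(0, 0), (0, 0)], np.ones((4, 4)), w)
        terms["total"].backward()
        assert (yi.grad < 0).all()


def test_balance_law_across_partner_probabilities():
    """area + consistency vanish exactly at λ = −1/log10(1−q)."""
    for q in (0.3, 0.5, 0.7):
        lam = balanced_lambda(q)
        assert lam == pytest.approx(-1.0 / np.log10(1.0 - q), rel=1e-9)
        k = 8
        w = LossWeights(lam=lam, beta=0.0)
        preds = [const_pred(q, k, (0, 0), 1), const_pred(q, k, (0, 0), 2)]
        bd = total_loss(preds, np.ones((k, k)), w)
        assert abs(bd.area_term + bd.consistency_term) < 1e-9 * k**2 + 1e-9


def test_brute_force_on_random_layouts():
    rng = np.random.default_rng(11)
    for trial in range(3):
        mask = (rng.random((16, 16)) > 0.5).astype(int)
        preds = [
            PatchPrediction(y=rng.uniform(0.05, 0.95, (4, 4)),
                            origin=(int(rng.integers(0, 12)), int(rng.integers(0, 12))),
                            marker_id=i + 1)
            for i in range(3)
        ]
        w = LossWeights(lam=2.0, beta=5.0)
        got = total_loss(preds, mask, w)
        assert got.total == pytest.approx(brute_force_loss(preds, mask, w)[3], abs=1e-9)
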