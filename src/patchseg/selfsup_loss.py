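"""The self-supervised patch-consistency objective.

For patch predictions y¹…yⁿ (each a k×k probability grid, zero by convention
outside its window) and a field-wide binary cell-area mask M, the training
loss is

    L = − Σ_pix Σ_i yⁱ                                   (area reward)
        − λ Σ_pix Σ_{i≠j} yⁱ · log₁₀(1 − yʲ)             (consistency penalty)
        + β Σ_pix Σ_i yⁱ · (1 − M)                        (outside-mask penalty)

The area term pushes every patch to claim as many pixels as possible; the
consistency term is a cross-entropy of each claim against the complement of
every overlapping partner's claim, so two patches cannot both keep a pixel;
the mask term forbids claims outside the total cell area. With base-10 logs,
λ = 1/(−log₁₀ 0.5) ≈ 3.32 makes the first two terms cancel per pixel when the
partner's prediction is a coin toss — the "balanced" default. β defaults to a
stiff 15. The pair sum runs over ordered pairs (both (i,j) and (j,i)) and the
summands vanish identically outside window overlaps.

``total_loss`` is the plain-numpy reference; ``total_loss_autograd`` builds
the identical expression on autograd tensors for training.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .masking import BinaryMask
from .patching import PatchPrediction

LOG10 = np.log(10.0)


@dataclass
class LossWeights:
    lam: float = 3.32
    beta: float = 15.0
    eps: float = 1e-6

    def __post_init__(self) -> None:
        if self.lam < 0 or self.beta < 0:
            raise ValueError("lam and beta must be non-negative")
        if not (0.0 < self.eps < 0.5):
            raise ValueError("eps must lie in (0, 0.5)")


@dataclass
class LossBreakdown:
    area_term: float
    consistency_term: float
    mask_term: float
    total: float


def _overlap_slices(
    oi: tuple[int, int], si: tuple[int, int], oj: tuple[int, int], sj: tuple[int, int]
):
    """Index slices of the overlap rectangle inside patch i and patch j, or None."""
    r0 = max(oi[0], oj[0])
    r1 = min(oi[0] + si[0], oj[0] + sj[0])
    c0 = max(oi[1], oj[1])
    c1 = min(oi[1] + si[1], oj[1] + sj[1])
    if r1 <= r0 or c1 <= c0:
        return None
    in_i = (slice(r0 - oi[0], r1 - oi[0]), slice(c0 - oi[1], c1 - oi[1]))
    in_j = (slice(r0 - oj[0], r1 - oj[0]), slice(c0 - oj[1], c1 - oj[1]))
    return in_i, in_j


def _check_frame(preds: list[PatchPrediction], mask: np.ndarray) -> None:
    h, w = mask.shape
    for p in preds:
        r0, c0 = p.origin
        kr, kc = p.y.shape
        if r0 < 0 or c0 < 0 or r0 + kr > h or c0 + kc > w:
            raise ValueError(f"patch at origin {p.origin} leaves the {mask.shape} field")


def total_loss(
    preds: list[PatchPrediction], mask: BinaryMask | np.ndarray, w: LossWeights
) -> LossBreakdown:
    """Evaluate the objective on numpy probability grids (reference path)."""
    m = mask.m if isinstance(mask, BinaryMask) else np.asarray(mask)
    _check_frame(preds, m)
    ys = [np.clip(p.y, w.eps, 1.0 - w.eps) for p in preds]

    area = -sum(float(y.sum()) for y in ys) if ys else 0.0

    consistency = 0.0
    for i in range(len(preds)):
        for j in range(i + 1, len(preds)):
            ov = _overlap_slices(preds[i].origin, ys[i].shape, preds[j].origin, ys[j].shape)
            if ov is None:
                continue
            in_i, in_j = ov
            yi, yj = ys[i][in_i], ys[j][in_j]
            consistency += float((yi * np.log10(1.0 - yj) + yj * np.log10(1.0 - yi)).sum())
    consistency *= -w.lam

    mask_pen = 0.0
    for p, y in zip(preds, ys):
        r0, c0 = p.origin
        kr, kc = y.shape
        mask_pen += float((y * (1.0 - m[r0 : r0 + kr, c0 : c0 + kc])).sum())
    mask_pen *= w.beta

    return LossBreakdown(
        area_term=area,
        consistency_term=consistency,
        mask_term=mask_pen,
        total=area + consistency + mask_pen,
    )


def loss_for_tile(
    preds: list[PatchPrediction], mask: BinaryMask | np.ndarray, w: LossWeights
) -> LossBreakdown:
    """The identical objective restricted to one tile's patch set.

    The caller restricts ``preds`` to markers inside a single tile (the
    per-batch training unit); an empty tile yields a zero loss.
    """
    return total_loss(preds, mask, w)


def partition_by_tile(points: np.ndarray, tile_size: int) -> dict[tuple[int, int], list[int]]:
    """Group marker indices by the tile (row-major grid of side tile_size) they fall in."""
    tiles: dict[tuple[int, int], list[int]] = {}
    for idx, (r, c) in enumerate(np.asarray(points).reshape(-1, 2)):
        tiles.setdefault((int(r) // tile_size, int(c) // tile_size), []).append(idx)
    return dict(sorted(tiles.items()))


def total_loss_autograd(
    ys: list[nn.Tensor],
    origins: list[tuple[int, int]],
    mask: BinaryMask | np.ndarray,
    w: LossWeights,
) -> dict[str, nn.Tensor]:
    """The same three terms as differentiable scalars on autograd tensors.

    The probability clip is applied only inside the logarithms (the usual
    cross-entropy stabilization); the linear area and mask terms use the raw
    probabilities, so a pixel saturated by an early suppression phase still
    feels the area reward and can recover. For predictions strictly inside
    (eps, 1−eps) the value coincides with :func:`total_loss`.
    """
    m = mask.m if isinstance(mask, BinaryMask) else np.asarray(mask)

    zero = nn.Tensor(0.0)
    area = zero
    for y in ys:
        area = area + y.sum()
    area = -1.0 * area

    consistency = zero
    for i in range(len(ys)):
        for j in range(i + 1, len(ys)):
            ov = _overlap_slices(origins[i], ys[i].shape, origins[j], ys[j].shape)
            if ov is None:
                continue
            in_i, in_j = ov
            yi, yj = ys[i][in_i], ys[j][in_j]
            log_not_j = nn.log(nn.clip(1.0 - yj, w.eps, 1.0)) / LOG10
            log_not_i = nn.log(nn.clip(1.0 - yi, w.eps, 1.0)) / LOG10
            consistency = consistency + (yi * log_not_j).sum() + (yj * log_not_i).sum()
    consistency = (-w.lam) * consistency

    mask_pen = zero
    for y, (r0, c0) in zip(ys, origins):
        kr, kc = y.shape
        outside = 1.0 - m[r0 : r0 + kr, c0 : c0 + kc]
        if outside.any():
            mask_pen = mask_pen + (y * nn.Tensor(outside)).sum()
    mask_pen = w.beta * mask_pen

    total = area + consistency + mask_pen
    return {"area": area, "consistency": consistency, "mask": mask_pen, "total": total}


def balanced_lambda(partner_prob: float = 0.5) -> float:
    """The weight at which consistency exactly cancels area for a fixed partner claim.

    Computed numerically from the loss itself: evaluate the area and
    consistency terms for two fully overlapping patches, one free (any value),
    one fixed at ``partner_prob``, at unit weight, and solve for the weight
    that makes them cancel.
    """
    k = 16
    y = np.full((k, k), partner_prob)
    both = [
        PatchPrediction(y=y, origin=(0, 0), marker_id=1),
        PatchPrediction(y=y.copy(), origin=(0, 0), marker_id=2),
    ]
    unit = LossWeights(lam=1.0, beta=0.0, eps=1e-12)
    bd = total_loss(both, np.ones((k, k)), unit)
    return -bd.area_term / bd.consistency_term
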