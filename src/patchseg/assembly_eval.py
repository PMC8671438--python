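"""Whole-field assembly of patch predictions and segmentation scoring.

Integration rule: each pixel goes to the marker whose patch gives it the
highest probability; pixels where every covering patch predicts below the
background threshold (default 0.5) stay background. Ties break toward the
smallest marker id.

Scoring: for each reference cell, the machine segment with maximal pixel
intersection is its match, and the per-cell score is the intersection over
union of the two pixel sets; ``mean_iou`` averages over the evaluated
reference cells (mIOU).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .patching import PatchPrediction


@dataclass
class SegEval:
    mean_iou: float
    per_cell_iou: list[tuple[int, float]]


def integrate(
    preds: list[PatchPrediction],
    field_shape: tuple[int, int],
    threshold: float = 0.5,
) -> np.ndarray:
    """Assemble per-patch probabilities into an instance label map."""
    ids = [p.marker_id for p in preds]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate marker_ids in predictions")
    h, w = field_shape
    best = np.zeros((h, w))
    labels = np.zeros((h, w), dtype=np.int32)
    for p in sorted(preds, key=lambda p: p.marker_id):
        r0, c0 = p.origin
        kr, kc = p.y.shape
        if r0 < 0 or c0 < 0 or r0 + kr > h or c0 + kc > w:
            raise ValueError(f"prediction at {p.origin} leaves the field {field_shape}")
        win_best = best[r0 : r0 + kr, c0 : c0 + kc]
        win_lab = labels[r0 : r0 + kr, c0 : c0 + kc]
        better = p.y > win_best  # strict: earlier (smaller) id wins ties
        win_best[better] = p.y[better]
        win_lab[better] = p.marker_id
    labels[best < threshold] = 0
    return labels


def per_cell_ious(
    machine: np.ndarray, reference: np.ndarray, reference_ids=None
) -> list[tuple[int, float]]:
    machine = np.asarray(machine)
    reference = np.asarray(reference)
    if machine.shape != reference.shape:
        raise ValueError("machine and reference label maps must share a shape")
    if reference_ids is None:
        reference_ids = np.unique(reference)
        reference_ids = reference_ids[reference_ids > 0]
    reference_ids = np.asarray(reference_ids)
    if reference_ids.size == 0:
        raise ValueError("no reference cells to evaluate")
    ious: list[tuple[int, float]] = []
    for rid in reference_ids:
        ref = reference == rid
        overlap = machine[ref]
        overlap = overlap[overlap > 0]
        if overlap.size == 0:
            ious.append((int(rid), 0.0))
            continue
        match = int(np.bincount(overlap).argmax())
        seg = machine == match
        inter = np.count_nonzero(ref & seg)
        union = np.count_nonzero(ref | seg)
        ious.append((int(rid), inter / union))
    return ious


def mean_iou(
    machine: np.ndarray, reference: np.ndarray, reference_ids=None
) -> SegEval:
    """Mean intersection-over-union over (optionally a subset of) reference cells."""
    ious = per_cell_ious(machine, reference, reference_ids)
    return SegEval(mean_iou=float(np.mean([v for _, v in ious])), per_cell_iou=ious)


def edge_interior_ids(reference: np.ndarray, edge_fraction: float = 0.05) -> tuple[list[int], list[int]]:
    """Split reference cells into clump-edge and clump-interior cells.

    A cell is an edge cell if more than ``edge_fraction`` of its boundary
    pixels touch the background (label 0); otherwise it is interior.
    """
    reference = np.asarray(reference)
    bg_adjacent = ndimage.binary_dilation(reference == 0)
    edge, interior = [], []
    for rid in np.unique(reference):
        if rid == 0:
            continue
        cell = reference == rid
        boundary = cell & ~ndimage.binary_erosion(cell)
        frac = np.count_nonzero(boundary & bg_adjacent) / max(np.count_nonzero(boundary), 1)
        (edge if frac > edge_fraction else interior).append(int(rid))
    return edge, interior
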