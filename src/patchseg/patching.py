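"""Marker-centered patches, the positional disk channel, and dihedral augmentation.

Each model input is a k×k crop of all image channels around one marker, plus
a Gaussian disk channel exp(−‖p−marker‖²/(2σ²)) that tells the network which
cell to segment. Augmentation is the dihedral group generated by row flips,
column flips and transposition, applied identically to all channels, with an
exact geometric inverse for predictions.

Conventions: 0-based row-major coordinates; windows are half-open
[origin, origin + k); the "center" of an even-sized patch is index (k/2, k/2);
windows that would leave the field are shifted minimally to fit, with the disk
drawn at the marker's true in-window offset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import ImageField


@dataclass
class PatchConfig:
    k: int = 64
    disk_sigma: float = 15.0

    def __post_init__(self) -> None:
        if self.k < 16 or self.k % 2:
            raise ValueError("patch side k must be even and at least 16")
        if self.disk_sigma <= 0:
            raise ValueError("disk_sigma must be positive")


@dataclass
class Patch:
    data: np.ndarray  # (C+1, k, k); last channel is the positional disk
    origin: tuple[int, int]
    marker_id: int


@dataclass
class AugmentationRecord:
    flip_rows: bool = False
    flip_cols: bool = False
    transpose: bool = False


@dataclass
class PatchPrediction:
    """A k×k probability grid, zero by convention outside its window."""

    y: np.ndarray
    origin: tuple[int, int]
    marker_id: int


def gaussian_disk(k: int, center: tuple[float, float], sigma: float) -> np.ndarray:
    rr, cc = np.mgrid[0:k, 0:k].astype(np.float64)
    return np.exp(-((rr - center[0]) ** 2 + (cc - center[1]) ** 2) / (2.0 * sigma**2))


def window_origin(marker: tuple[int, int], k: int, field_shape: tuple[int, int]) -> tuple[int, int]:
    """Top-left corner placing the marker at (k/2, k/2), shifted minimally to fit."""
    h, w = field_shape
    if h < k or w < k:
        raise ValueError(f"field {field_shape} smaller than patch size {k}")
    r0 = min(max(marker[0] - k // 2, 0), h - k)
    c0 = min(max(marker[1] - k // 2, 0), w - k)
    return int(r0), int(c0)


def extract_patch(
    field: ImageField,
    marker: tuple[int, int],
    cfg: PatchConfig,
    channel_names: list[str] | None = None,
    marker_id: int = 0,
) -> Patch:
    h, w = field.shape
    r, c = int(marker[0]), int(marker[1])
    if not (0 <= r < h and 0 <= c < w):
        raise ValueError(f"marker {marker} outside field of shape {field.shape}")
    r0, c0 = window_origin((r, c), cfg.k, (h, w))
    stack = field.stack(channel_names)[:, r0 : r0 + cfg.k, c0 : c0 + cfg.k]
    disk = gaussian_disk(cfg.k, (r - r0, c - c0), cfg.disk_sigma)
    data = np.concatenate([stack, disk[None]], axis=0)
    return Patch(data=data, origin=(r0, c0), marker_id=marker_id)


def _apply_geometry(grid: np.ndarray, rec: AugmentationRecord) -> np.ndarray:
    """Forward geometry on the trailing two axes: flips, then transpose."""
    if rec.flip_rows:
        grid = grid[..., ::-1, :]
    if rec.flip_cols:
        grid = grid[..., :, ::-1]
    if rec.transpose:
        grid = np.swapaxes(grid, -2, -1)
    return grid


def _invert_geometry(grid: np.ndarray, rec: AugmentationRecord) -> np.ndarray:
    """Exact inverse: transpose first, then flips."""
    if rec.transpose:
        grid = np.swapaxes(grid, -2, -1)
    if rec.flip_cols:
        grid = grid[..., :, ::-1]
    if rec.flip_rows:
        grid = grid[..., ::-1, :]
    return grid


def augment(patch: Patch, rec: AugmentationRecord) -> Patch:
    """Apply the dihedral geometry to all channels; origin and id are unchanged."""
    return Patch(
        data=np.ascontiguousarray(_apply_geometry(patch.data, rec)),
        origin=patch.origin,
        marker_id=patch.marker_id,
    )


def reverse_augment(pred: PatchPrediction, rec: AugmentationRecord) -> PatchPrediction:
    """Undo the geometry on a prediction before the loss sees it."""
    return PatchPrediction(
        y=np.ascontiguousarray(_invert_geometry(pred.y, rec)),
        origin=pred.origin,
        marker_id=pred.marker_id,
    )


def sample_augmentation(rng: np.random.Generator) -> AugmentationRecord:
    """Each of the three flags independently with probability 1/2."""
    f = rng.integers(0, 2, size=3).astype(bool)
    return AugmentationRecord(flip_rows=bool(f[0]), flip_cols=bool(f[1]), transpose=bool(f[2]))


ALL_AUGMENTATIONS = [
    AugmentationRecord(flip_rows=a, flip_cols=b, transpose=c)
    for a in (False, True)
    for b in (False, True)
    for c in (False, True)
]
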