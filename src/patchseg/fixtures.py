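"""Synthetic multi-cell scenes with ground truth.

The generator emulates the statistical structure the segmentation method
assumes: a confluent monolayer of tightly clumped cells (every cell touches
neighbours), one compact nucleus blob per cell, and modality-dependent
appearance —

``FL``
    fluorescence-like: each cell has its own random base intensity modulated
    by smooth texture, on a dark background; nuclei leave a dimmer imprint,
    the way DNA-dense regions modulate a cytoplasmic stain.
``BF``
    bright-field-like: near-constant background gray, dark intensity ridges
    along cell boundaries, weak interior texture. Foreground and background
    gray values overlap, so intensity thresholding alone cannot mask it.
``NUC``
    a nucleus stain: one elliptical Gaussian blob per cell anchor.

Cell shapes come from competitive multi-source region growing (a priority
flood from the anchors, each cell with a random growth speed), restricted to
a foreground support region so that cells touch and a real background exists.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage.segmentation import find_boundaries

from .io import ImageField, write_channel, write_labels, write_markers
from .markers import MarkerSet


class SceneGenerationError(RuntimeError):
    pass


@dataclass
class SceneConfig:
    field_height: int = 256
    field_width: int = 256
    n_cells: int = 48
    min_center_spacing: float = 20.0
    nucleus_radius_range: tuple[float, float] = (4.0, 8.0)
    pixel_size: float = 1.0  # µm per pixel
    noise_sd: float = 0.03
    coverage: float = 0.50  # target foreground fraction, clipped to [0.5, 0.9]
    seed: int = 0

    def __post_init__(self) -> None:
        if self.field_height < 64 or self.field_width < 64:
            raise ValueError("field dimensions must be at least 64")
        if self.n_cells < 0:
            raise ValueError("n_cells must be non-negative")
        if self.min_center_spacing <= 0:
            raise ValueError("min_center_spacing must be positive")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")


@dataclass
class SyntheticScene:
    labels: np.ndarray  # ground-truth instance map, 0 = background
    centers: MarkerSet  # true cell anchors, one per label id (ordered)
    channels: ImageField  # "FL", "BF", "NUC"


def _sample_centers(cfg: SceneConfig, rng: np.random.Generator) -> np.ndarray:
    margin = max(cfg.nucleus_radius_range) + 2.0
    lo_r, hi_r = margin, cfg.field_height - 1 - margin
    lo_c, hi_c = margin, cfg.field_width - 1 - margin
    centers: list[tuple[float, float]] = []
    attempts = 0
    max_attempts = 500 * max(cfg.n_cells, 1)
    while len(centers) < cfg.n_cells:
        if attempts >= max_attempts:
            raise SceneGenerationError(
                f"could not place {cfg.n_cells} centers with spacing "
                f"{cfg.min_center_spacing} after {max_attempts} attempts"
            )
        attempts += 1
        r = rng.uniform(lo_r, hi_r)
        c = rng.uniform(lo_c, hi_c)
        if all((r - r0) ** 2 + (c - c0) ** 2 >= cfg.min_center_spacing**2 for r0, c0 in centers):
            centers.append((r, c))
    return np.asarray(centers, dtype=np.float64).reshape(-1, 2)


def _foreground_support(cfg: SceneConfig, centers: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Smoothed union of per-cell radius fields, thresholded at the coverage quantile."""
    h, w = cfg.field_height, cfg.field_width
    rr, cc = np.mgrid[0:h, 0:w].astype(np.float64)
    r0 = np.sqrt(cfg.coverage * h * w / (np.pi * max(len(centers), 1)))
    support = np.zeros((h, w))
    widths = rng.uniform(0.85, 1.25, size=len(centers)) * r0
    for (r, c), s in zip(centers, widths):
        support += np.exp(-((rr - r) ** 2 + (cc - c) ** 2) / (2.0 * (0.8 * s) ** 2))
    support += 0.08 * ndimage.gaussian_filter(rng.standard_normal((h, w)), 8)
    cov = float(np.clip(cfg.coverage, 0.5, 0.9))
    fg = support >= np.quantile(support, 1.0 - cov)
    # anchors must sit inside the foreground
    for r, c in centers:
        rr_i, cc_i = int(round(r)), int(round(c))
        fg[max(0, rr_i - 2) : rr_i + 3, max(0, cc_i - 2) : cc_i + 3] = True
    return fg


def _grow_labels(
    fg: np.ndarray, centers: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Competitive priority-flood from the anchors with per-cell random speeds.

    Each region is 4-connected by construction and contains its own anchor.
    """
    h, w = fg.shape
    labels = np.zeros((h, w), dtype=np.int32)
    if len(centers) == 0:
        return labels
    speeds = rng.uniform(0.7, 1.4, size=len(centers))
    # pre-drawn jitter makes growth fronts irregular while staying heap-safe
    jitter = rng.uniform(0.0, 0.6, size=(h, w))
    heap: list[tuple[float, int, int, int, int]] = []
    tie = 0
    for i, (r, c) in enumerate(centers, start=1):
        ri, ci = int(round(r)), int(round(c))
        heapq.heappush(heap, (0.0, tie, ri, ci, i))
        tie += 1
    while heap:
        cost, _, r, c, lab = heapq.heappop(heap)
        if labels[r, c] != 0:
            continue
        labels[r, c] = lab
        step = 1.0 / speeds[lab - 1]
        for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < h and 0 <= c2 < w and fg[r2, c2] and labels[r2, c2] == 0:
                heapq.heappush(heap, (cost + step * (1.0 + jitter[r2, c2]), tie, r2, c2, lab))
                tie += 1
    return labels


def _smooth_texture(shape: tuple[int, int], sigma: float, rng: np.random.Generator) -> np.ndarray:
    t = ndimage.gaussian_filter(rng.standard_normal(shape), sigma)
    sd = t.std()
    return t / sd if sd > 0 else t


def _render_nuclei(
    cfg: SceneConfig, centers: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    h, w = cfg.field_height, cfg.field_width
    nuc = np.zeros((h, w))
    lo, hi = cfg.nucleus_radius_range
    for r, c in centers:
        ra, rb = rng.uniform(lo, hi), rng.uniform(lo, hi)
        theta = rng.uniform(0, np.pi)
        amp = rng.uniform(0.75, 1.0)
        ext = int(np.ceil(3 * max(ra, rb)))
        r0, r1 = max(0, int(r) - ext), min(h, int(r) + ext + 1)
        c0, c1 = max(0, int(c) - ext), min(w, int(c) + ext + 1)
        rr, cc = np.mgrid[r0:r1, c0:c1].astype(np.float64)
        dr, dc = rr - r, cc - c
        u = (dr * np.cos(theta) + dc * np.sin(theta)) / ra
        v = (-dr * np.sin(theta) + dc * np.cos(theta)) / rb
        nuc[r0:r1, c0:c1] += amp * np.exp(-(u**2 + v**2) / 0.9)
    return np.clip(nuc, 0.0, 1.0)


def generate_scene(config: SceneConfig) -> SyntheticScene:
    """Generate one seeded scene: ground-truth labels, anchors, FL/BF/NUC channels."""
    rng = np.random.default_rng(config.seed)
    h, w = config.field_height, config.field_width

    if config.n_cells == 0:
        centers = np.zeros((0, 2))
        labels = np.zeros((h, w), dtype=np.int32)
        nuc_field = np.zeros((h, w))
    else:
        centers = _sample_centers(config, rng)
        fg = _foreground_support(config, centers, rng)
        labels = _grow_labels(fg, centers, rng)
        nuc_field = _render_nuclei(config, centers, rng)

    inside = labels > 0

    # FL: per-cell base intensity × smooth texture, dark background,
    # dimmer nuclear imprint.
    base = np.concatenate([[0.05], rng.uniform(0.35, 0.95, size=config.n_cells)])
    tex = 1.0 + 0.22 * _smooth_texture((h, w), 3.0, rng)
    fl = np.where(inside, base[labels] * tex, 0.05)
    fl = fl * (1.0 - 0.30 * nuc_field)

    # BF: flat gray background, dark ridges along all label boundaries,
    # weak interior texture, faint nuclear imprint.
    # 'inner' keeps the dark edge material inside the cells, as in real
    # bright-field images where the refractile cell rim is part of the cell
    ridges = ndimage.gaussian_filter(
        find_boundaries(labels, mode="inner").astype(np.float64), 1.0
    )
    bf = 0.55 - 0.30 * ridges
    bf += 0.06 * _smooth_texture((h, w), 2.0, rng) * inside
    bf += 0.012 * _smooth_texture((h, w), 2.0, rng)
    bf -= 0.08 * nuc_field

    nuc = nuc_field.copy()

    channels = {}
    for name, img in (("FL", fl), ("BF", bf), ("NUC", nuc)):
        noisy = img + config.noise_sd * rng.standard_normal((h, w))
        channels[name] = np.clip(noisy, 0.0, 1.0)

    center_points = np.round(centers).astype(np.int64)
    return SyntheticScene(
        labels=labels,
        centers=MarkerSet(points=center_points, pixel_size=config.pixel_size),
        channels=ImageField(channels=channels, pixel_size=config.pixel_size),
    )


def scribbles_from_labels(
    labels: np.ndarray,
    rng: np.random.Generator | int = 0,
    n_strokes: int = 12,
    stroke_len: int = 20,
) -> np.ndarray:
    """Short fg/bg scribble strokes derived from a ground-truth label map.

    Emulates the handful of strokes a user would draw on each class:
    returns an image with 0 = unlabeled, 1 = foreground, 2 = background.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    h, w = labels.shape
    fg_core = ndimage.binary_erosion(labels > 0, iterations=3)
    bg_core = ndimage.binary_erosion(labels == 0, iterations=3)
    out = np.zeros((h, w), dtype=np.uint8)
    for cls, core in ((1, fg_core), (2, bg_core)):
        rows, cols = np.nonzero(core)
        if len(rows) == 0:
            raise SceneGenerationError(f"no interior pixels for scribble class {cls}")
        for _ in range(n_strokes):
            k = rng.integers(len(rows))
            r, c = rows[k], cols[k]
            horizontal = bool(rng.integers(2))
            for t in range(stroke_len):
                rr = r if horizontal else min(h - 1, r + t)
                cc = min(w - 1, c + t) if horizontal else c
                if core[rr, cc]:
                    out[rr, cc] = cls
    return out


def write_scene(scene: SyntheticScene, outdir: str | Path) -> dict[str, Path]:
    """Write per-channel TIFFs, a 16-bit ground-truth label TIFF and centers CSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for name, img in scene.channels.channels.items():
        p = outdir / f"{name.lower()}.tif"
        write_channel(p, img)
        paths[name] = p
    paths["labels"] = outdir / "labels.tif"
    write_labels(paths["labels"], scene.labels)
    paths["centers"] = outdir / "centers.csv"
    write_markers(paths["centers"], scene.centers.points)
    return paths
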