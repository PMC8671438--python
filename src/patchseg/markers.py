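"""Per-cell marker locations and marker-set scoring.

Markers are single anchor points, one per cell (nucleus positions in the
intended use). They come either from a labeled nucleus image (centroids) or
from difference-of-Gaussians blob detection on a raw or synthetic nucleus
image. Predicted marker sets are scored against reference sets by greedy
nearest-first pairing with a physical distance cutoff (default 15 µm), giving
false-negative and false-positive rates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu


@dataclass
class MarkerSet:
    points: np.ndarray = field(default_factory=lambda: np.zeros((0, 2), dtype=np.int64))
    pixel_size: float = 1.0  # µm per pixel

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points).reshape(-1, 2)
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class MarkerScore:
    false_negative_rate: float
    false_positive_rate: float
    n_true: int
    n_pred: int
    n_paired: int


def markers_from_labels(nucleus_labels: np.ndarray, pixel_size: float = 1.0) -> MarkerSet:
    """One marker per nonzero label at its centroid, rounded to the nearest pixel."""
    nucleus_labels = np.asarray(nucleus_labels)
    ids = np.unique(nucleus_labels)
    ids = ids[ids > 0]
    if len(ids) == 0:
        return MarkerSet(points=np.zeros((0, 2), dtype=np.int64), pixel_size=pixel_size)
    coms = ndimage.center_of_mass(nucleus_labels > 0, nucleus_labels, ids)
    pts = np.round(np.asarray(coms)).astype(np.int64)
    # centroids of distinct labels may round onto one pixel; nudge duplicates
    seen: set[tuple[int, int]] = set()
    h, w = nucleus_labels.shape
    for i, (r, c) in enumerate(pts):
        rr, cc = int(r), int(c)
        while (rr, cc) in seen:
            cc = min(cc + 1, w - 1)
            if (rr, cc) in seen:
                rr = min(rr + 1, h - 1)
        seen.add((rr, cc))
        pts[i] = (rr, cc)
    return MarkerSet(points=pts, pixel_size=pixel_size)


def markers_from_nucleus_image(image: np.ndarray, pixel_size: float = 1.0) -> MarkerSet:
    """Otsu-threshold a nucleus image, label connected components, take centroids."""
    image = np.asarray(image, dtype=np.float64)
    if image.max() == image.min():
        return MarkerSet(points=np.zeros((0, 2), dtype=np.int64), pixel_size=pixel_size)
    binary = image > threshold_otsu(image)
    labels, _ = ndimage.label(binary)
    return markers_from_labels(labels, pixel_size=pixel_size)


def detect_blobs_dog(
    image: np.ndarray,
    sigma_min: float = 2.0,
    sigma_max: float = 8.0,
    n_scales: int = 6,
    threshold: float = 0.04,
    pixel_size: float = 1.0,
    min_distance: float | None = None,
) -> MarkerSet:
    """Blob detection as local maxima of a difference-of-Gaussians scale space.

    Builds Gaussian blurs at ``n_scales`` geometrically spaced widths, takes
    consecutive differences, and returns the (row, col) of every local maximum
    (over row, col and scale) above ``threshold``. Maxima closer than
    ``min_distance`` pixels (default: ``sigma_min``) are merged, keeping the
    strongest.
    """
    if not sigma_min < sigma_max:
        raise ValueError("need sigma_min < sigma_max")
    if min_distance is None:
        min_distance = sigma_min
    image = np.asarray(image, dtype=np.float64)
    sigmas = np.geomspace(sigma_min, sigma_max, n_scales)
    blurred = [ndimage.gaussian_filter(image, s) for s in sigmas]
    # scale-normalized consecutive differences
    dog = np.stack(
        [(blurred[i] - blurred[i + 1]) / (sigmas[i + 1] / sigmas[i] - 1.0) for i in range(n_scales - 1)]
    )
    local_max = ndimage.maximum_filter(dog, size=(3, 3, 3), mode="nearest")
    peaks = (dog == local_max) & (dog > threshold)
    ss, rr, cc = np.nonzero(peaks)
    if len(rr) == 0:
        return MarkerSet(points=np.zeros((0, 2), dtype=np.int64), pixel_size=pixel_size)
    strength = dog[ss, rr, cc]
    order = np.argsort(strength)[::-1]
    kept: list[tuple[int, int]] = []
    for k in order:
        r, c = int(rr[k]), int(cc[k])
        if all((r - r0) ** 2 + (c - c0) ** 2 >= min_distance**2 for r0, c0 in kept):
            kept.append((r, c))
    return MarkerSet(points=np.asarray(kept, dtype=np.int64), pixel_size=pixel_size)


def pair_markers(pred: MarkerSet, truth: MarkerSet, max_dist_um: float = 15.0) -> MarkerScore:
    """Greedy nearest-first one-to-one pairing with a physical cutoff.

    A predicted marker pairs with a reference marker if the two lie within
    ``max_dist_um``; each marker is used at most once, closest pairs first.
    FN = unmatched reference fraction, FP = unmatched predicted fraction, with
    a rate of 0 whenever its denominator is empty.
    """
    if pred.pixel_size != truth.pixel_size:
        raise ValueError("pred and truth must share pixel_size")
    n_pred, n_true = len(pred), len(truth)
    n_paired = 0
    if n_pred and n_true:
        d = np.linalg.norm(
            pred.points[:, None, :].astype(np.float64) - truth.points[None, :, :], axis=2
        ) * pred.pixel_size
        pairs = [(d[i, j], i, j) for i in range(n_pred) for j in range(n_true) if d[i, j] <= max_dist_um]
        pairs.sort()
        used_p: set[int] = set()
        used_t: set[int] = set()
        for dist, i, j in pairs:
            if i in used_p or j in used_t:
                continue
            assert dist <= max_dist_um
            used_p.add(i)
            used_t.add(j)
            n_paired += 1
    fn = (n_true - n_paired) / n_true if n_true else 0.0
    fp = (n_pred - n_paired) / n_pred if n_pred else 0.0
    return MarkerScore(
        false_negative_rate=fn,
        false_positive_rate=fp,
        n_true=n_true,
        n_pred=n_pred,
        n_paired=n_paired,
    )
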