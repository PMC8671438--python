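"""Image, marker and report I/O.

All images travel as float arrays in [0, 1] inside the package; on disk they
are plain grayscale TIFFs (one per channel), label maps are 16-bit TIFFs,
binary masks 8-bit (0/255) TIFFs, markers CSV (``id,row,col``), reports JSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile


@dataclass
class ImageField:
    """A named-channel 2D image with a physical pixel size (µm/pixel)."""

    channels: dict[str, np.ndarray] = field(default_factory=dict)
    pixel_size: float = 1.0

    def __post_init__(self) -> None:
        shapes = {ch.shape for ch in self.channels.values()}
        if len(shapes) > 1:
            raise ValueError(f"channel shapes differ: {shapes}")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        if not self.channels:
            raise ValueError("empty field")
        return next(iter(self.channels.values())).shape

    def stack(self, names: list[str] | None = None) -> np.ndarray:
        """Channels stacked as (C, H, W) in the given (or insertion) order."""
        names = list(self.channels) if names is None else names
        return np.stack([self.channels[n] for n in names], axis=0)


def _to_unit_float(arr: np.ndarray) -> np.ndarray:
    if np.issubdtype(arr.dtype, np.integer):
        info = np.iinfo(arr.dtype)
        return arr.astype(np.float64) / float(info.max)
    return np.clip(arr.astype(np.float64), 0.0, 1.0)


def read_field(paths: dict[str, str | Path], pixel_size: float = 1.0) -> ImageField:
    """Read one grayscale TIFF per named channel, rescaled to [0, 1] by dtype."""
    channels = {}
    for name, path in paths.items():
        arr = tifffile.imread(str(path))
        if arr.ndim != 2:
            raise ValueError(f"channel {name!r}: expected a 2D image, got shape {arr.shape}")
        channels[name] = _to_unit_float(arr)
    shapes = {c.shape for c in channels.values()}
    if len(shapes) > 1:
        raise ValueError(f"channel shapes differ: {shapes}")
    return ImageField(channels=channels, pixel_size=pixel_size)


def write_channel(path: str | Path, image: np.ndarray) -> None:
    """Write a [0,1] float image as 16-bit grayscale TIFF."""
    arr = np.clip(np.asarray(image, dtype=np.float64), 0.0, 1.0)
    tifffile.imwrite(str(path), (arr * 65535.0 + 0.5).astype(np.uint16))


def write_float_tiff(path: str | Path, image: np.ndarray) -> None:
    tifffile.imwrite(str(path), np.asarray(image, dtype=np.float32))


def write_labels(path: str | Path, labels: np.ndarray) -> None:
    labels = np.asarray(labels)
    if labels.min() < 0 or labels.max() > 65535:
        raise ValueError("label ids must fit in uint16")
    tifffile.imwrite(str(path), labels.astype(np.uint16))


def read_labels(path: str | Path) -> np.ndarray:
    return tifffile.imread(str(path)).astype(np.int32)


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    tifffile.imwrite(str(path), (np.asarray(mask) > 0).astype(np.uint8) * 255)


def read_mask(path: str | Path) -> np.ndarray:
    return (tifffile.imread(str(path)) > 0).astype(np.uint8)


def write_markers(path: str | Path, points: np.ndarray) -> None:
    points = np.asarray(points).reshape(-1, 2)
    df = pd.DataFrame(
        {"id": np.arange(1, len(points) + 1), "row": points[:, 0], "col": points[:, 1]}
    )
    df.to_csv(str(path), index=False)


def read_markers(path: str | Path) -> np.ndarray:
    df = pd.read_csv(str(path))
    return df[["row", "col"]].to_numpy(dtype=np.float64)


def write_json(path: str | Path, obj: dict) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=float) + "\n")
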