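"""Encoder–decoder segmentation model and the self-supervised training loop.

The model is a configurable skip-connected encoder–decoder (UNet family):
``depth`` pooling stages of paired 3×3 conv+relu blocks, a bottleneck, and a
mirrored upsampling path with channel concatenation, ending in a 1×1 conv and
a logistic head. Output spatial size equals input size and the single output
channel is a per-pixel cell probability.

Training: markers are grouped into square tiles (default 640 px); each tile's
marker-centered patches form one batch. Per batch we sample a random dihedral
augmentation per patch, run the augmented patches through the network, apply
the exact inverse geometry to the outputs, evaluate the patch-consistency
objective in field coordinates, and take one ADAM step (constant learning
rate, default 0.005). Training stops when the relative decrease of the
epoch-mean total loss stays below ``rel_tol`` for ``patience`` consecutive
epochs, or at ``max_epochs``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dfield
from pathlib import Path
from typing import Callable

import numpy as np

from . import nn
from .io import ImageField
from .masking import BinaryMask
from .markers import MarkerSet
from .patching import (
    AugmentationRecord,
    PatchConfig,
    PatchPrediction,
    extract_patch,
    sample_augmentation,
)
from .selfsup_loss import LossBreakdown, LossWeights, partition_by_tile, total_loss_autograd


class ConfigError(ValueError):
    pass


@dataclass
class ModelConfig:
    in_channels: int = 2  # image channels + 1 positional disk channel
    depth: int = 3
    base_filters: int = 32
    batchnorm: bool = True
    seed: int = 0


@dataclass
class TrainConfig:
    learning_rate: float = 0.005
    tile_size: int = 640
    max_epochs: int = 60
    patience: int = 5
    rel_tol: float = 1e-3
    weight_decay: float = 1e-4
    weights: LossWeights = dfield(default_factory=LossWeights)
    patch: PatchConfig = dfield(default_factory=PatchConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ConfigError("learning_rate must be positive")
        if self.tile_size < self.patch.k:
            raise ConfigError("tile_size must be at least the patch size")


@dataclass
class TrainHistory:
    epochs: list[LossBreakdown]
    stopped_at: int  # number of epochs actually run
    n_steps: int  # optimizer steps taken

    def totals(self) -> np.ndarray:
        return np.array([e.total for e in self.epochs])


class UNet:
    """Skip-connected encoder–decoder; maps (N, C, k, k) → (N, 1, k, k) probabilities."""

    FORMAT_VERSION = 1

    def __init__(self, cfg: ModelConfig):
        self.cfg = cfg
        self.params: list[nn.Tensor] = []
        self._names: list[str] = []
        rng = np.random.default_rng(cfg.seed)
        f = cfg.base_filters
        self.enc_channels = [cfg.in_channels] + [f * 2**i for i in range(cfg.depth)]
        self.bottleneck_channels = f * 2**cfg.depth
        self._weights = {}
        # encoder blocks
        for i in range(cfg.depth):
            self._add_block(f"enc{i}", self.enc_channels[i], self.enc_channels[i + 1], rng)
        self._add_block(f"bott", self.enc_channels[-1], self.bottleneck_channels, rng)
        # decoder blocks: input = upsampled + skip
        up_in = self.bottleneck_channels
        for i in reversed(range(cfg.depth)):
            skip = self.enc_channels[i + 1]
            self._add_block(f"dec{i}", up_in + skip, skip, rng)
            up_in = skip
        self._add_conv("head", up_in, 1, 1, rng)

    def _add_conv(self, name: str, cin: int, cout: int, ksize: int, rng) -> None:
        std = np.sqrt(2.0 / (cin * ksize * ksize))
        w = nn.Tensor(rng.normal(0.0, std, size=(cout, cin, ksize, ksize)), requires_grad=True)
        b = nn.Tensor(np.zeros(cout), requires_grad=True)
        self._weights[name] = (w, b)
        self.params += [w, b]
        self._names += [f"{name}.w", f"{name}.b"]

    def _add_bn(self, name: str, c: int) -> None:
        gamma = nn.Tensor(np.ones(c), requires_grad=True)
        beta = nn.Tensor(np.zeros(c), requires_grad=True)
        self._weights[name] = (gamma, beta)
        self.params += [gamma, beta]
        self._names += [f"{name}.g", f"{name}.b"]

    def _add_block(self, name: str, cin: int, cout: int, rng) -> None:
        self._add_conv(f"{name}a", cin, cout, 3, rng)
        self._add_conv(f"{name}b", cout, cout, 3, rng)
        if self.cfg.batchnorm:
            self._add_bn(f"{name}a.bn", cout)
            self._add_bn(f"{name}b.bn", cout)

    def _block(self, name: str, x: nn.Tensor) -> nn.Tensor:
        for part in ("a", "b"):
            w, b = self._weights[f"{name}{part}"]
            x = nn.conv2d(x, w, b)
            if self.cfg.batchnorm:
                g, be = self._weights[f"{name}{part}.bn"]
                x = nn.batchnorm2d(x, g, be)
            x = nn.relu(x)
        return x

    def forward(self, x: np.ndarray | nn.Tensor) -> nn.Tensor:
        if not isinstance(x, nn.Tensor):
            x = nn.Tensor(x)
        n, c, h, w = x.shape
        if c != self.cfg.in_channels:
            raise ConfigError(f"expected {self.cfg.in_channels} input channels, got {c}")
        if h % 2**self.cfg.depth or w % 2**self.cfg.depth:
            raise ConfigError(
                f"spatial size {h}×{w} must be divisible by 2^depth = {2**self.cfg.depth}"
            )
        skips = []
        for i in range(self.cfg.depth):
            x = self._block(f"enc{i}", x)
            skips.append(x)
            x = nn.maxpool2(x)
        x = self._block("bott", x)
        for i in reversed(range(self.cfg.depth)):
            x = nn.upsample2(x)
            x = nn.concat([x, skips[i]], axis=1)
            x = self._block(f"dec{i}", x)
        wh, bh = self._weights["head"]
        return nn.sigmoid(nn.conv2d(x, wh, bh))

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Forward pass returning plain probabilities (N, 1, H, W)."""
        return self.forward(x).data

    # ---- checkpointing ----------------------------------------------------
    def save(self, path: str | Path) -> None:
        arrays = {name: p.data for name, p in zip(self._names, self.params)}
        meta = dict(
            format_version=self.FORMAT_VERSION,
            in_channels=self.cfg.in_channels,
            depth=self.cfg.depth,
            base_filters=self.cfg.base_filters,
            batchnorm=self.cfg.batchnorm,
            seed=self.cfg.seed,
        )
        np.savez(str(path), __meta__=json.dumps(meta), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "UNet":
        with np.load(str(path), allow_pickle=False) as data:
            meta = json.loads(str(data["__meta__"]))
            if meta["format_version"] != cls.FORMAT_VERSION:
                raise ConfigError(f"unknown checkpoint version {meta['format_version']}")
            model = cls(ModelConfig(
                in_channels=meta["in_channels"], depth=meta["depth"],
                base_filters=meta["base_filters"], batchnorm=meta.get("batchnorm", True),
                seed=meta["seed"],
            ))
            for name, p in zip(model._names, model.params):
                p.data = data[name].astype(np.float64)
        return model


def build_model(cfg: ModelConfig) -> UNet:
    return UNet(cfg)


def _augment_geometry_np(data: np.ndarray, rec: AugmentationRecord) -> np.ndarray:
    out = data
    if rec.flip_rows:
        out = out[..., ::-1, :]
    if rec.flip_cols:
        out = out[..., :, ::-1]
    if rec.transpose:
        out = np.swapaxes(out, -2, -1)
    return np.ascontiguousarray(out)


def _invert_geometry_tensor(y: nn.Tensor, rec: AugmentationRecord) -> nn.Tensor:
    if rec.transpose:
        y = nn.transpose_last2(y)
    if rec.flip_cols:
        y = nn.flip(y, axis=-1)
    if rec.flip_rows:
        y = nn.flip(y, axis=-2)
    return y


def train_segmenter(
    field: ImageField,
    markers: MarkerSet,
    mask: BinaryMask | np.ndarray,
    mcfg: ModelConfig,
    tcfg: TrainConfig,
    channel_names: list[str] | None = None,
    epoch_callback: Callable[[UNet, int, LossBreakdown], None] | None = None,
) -> tuple[UNet, TrainHistory]:
    """Self-supervised training on one field; returns the model and loss history."""
    if len(markers) == 0:
        raise ValueError("training requires at least one marker")
    m = mask.m if isinstance(mask, BinaryMask) else np.asarray(mask)
    if m.shape != field.shape:
        raise ValueError("mask shape must match the field")

    patches = [
        extract_patch(field, tuple(pt), tcfg.patch, channel_names, marker_id=i + 1)
        for i, pt in enumerate(markers.points)
    ]
    tiles = partition_by_tile(markers.points, tcfg.tile_size)
    model = build_model(mcfg)
    opt = nn.Adam(model.params, lr=tcfg.learning_rate, weight_decay=tcfg.weight_decay)
    rng = np.random.default_rng(tcfg.seed)

    epochs: list[LossBreakdown] = []
    n_steps = 0
    streak = 0
    for epoch in range(tcfg.max_epochs):
        sums = np.zeros(4)
        for tile_idx in tiles.values():
            subset = [patches[i] for i in tile_idx]
            recs = [sample_augmentation(rng) for _ in subset]
            batch = np.stack([_augment_geometry_np(p.data, r) for p, r in zip(subset, recs)])
            out = model.forward(batch)
            ys = [_invert_geometry_tensor(out[i, 0], recs[i]) for i in range(len(subset))]
            origins = [p.origin for p in subset]
            terms = total_loss_autograd(ys, origins, m, tcfg.weights)
            opt.zero_grad()
            terms["total"].backward()
            opt.step()
            n_steps += 1
            sums += [terms[k].item() for k in ("area", "consistency", "mask", "total")]
        n_tiles = len(tiles)
        bd = LossBreakdown(*(sums / n_tiles))
        epochs.append(bd)
        if epoch_callback is not None:
            epoch_callback(model, epoch, bd)
        if epoch > 0:
            prev, cur = epochs[-2].total, bd.total
            rel = (prev - cur) / max(abs(prev), 1e-12)
            streak = streak + 1 if rel < tcfg.rel_tol else 0
            if streak >= tcfg.patience:
                break
    return model, TrainHistory(epochs=epochs, stopped_at=len(epochs), n_steps=n_steps)


def predict_patches(
    model: UNet,
    field: ImageField,
    markers: MarkerSet,
    pcfg: PatchConfig,
    channel_names: list[str] | None = None,
    batch_size: int = 64,
) -> list[PatchPrediction]:
    """One un-augmented prediction per marker."""
    patches = [
        extract_patch(field, tuple(pt), pcfg, channel_names, marker_id=i + 1)
        for i, pt in enumerate(markers.points)
    ]
    preds: list[PatchPrediction] = []
    for start in range(0, len(patches), batch_size):
        chunk = patches[start : start + batch_size]
        out = model.predict(np.stack([p.data for p in chunk]))
        for p, y in zip(chunk, out[:, 0]):
            preds.append(PatchPrediction(y=y, origin=p.origin, marker_id=p.marker_id))
    return preds
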