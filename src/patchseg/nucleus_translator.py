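"""Image→nucleus translation for marker generation without a nucleus channel.

An encoder–decoder (same family as the segmenter) is trained, with per-pixel
binary cross-entropy and ADAM, to map a cell image (fluorescence or
bright-field) to its binarized nucleus image. The goal is not a realistic
nucleus rendering — only that blob detection on the predicted "synthetic
nucleus image" recovers marker positions. Following that intent, training
stops as soon as the epoch-mean cross-entropy (natural log, mean over pixels)
drops to ``stop_loss`` (default 0.15).

Evaluation uses three scenes in a 3-fold cross-validation: train on two
image/nucleus pairs, predict markers on the held-out image, and score them
against the true anchors by distance pairing (15 µm cutoff).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_otsu

from . import nn
from .io import ImageField
from .markers import MarkerScore, MarkerSet, detect_blobs_dog, pair_markers
from .segmenter import ModelConfig, UNet, build_model


@dataclass
class TranslatorConfig:
    learning_rate: float = 0.005
    stop_loss: float = 0.15
    max_epochs: int = 120
    binarize_threshold: str | float = "otsu"
    crop_size: int = 32
    batch_size: int = 8
    steps_per_epoch: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.stop_loss <= 0:
            raise ValueError("stop_loss must be positive")


@dataclass
class TranslationPair:
    source: np.ndarray  # cell-image channel
    target: np.ndarray  # binary nucleus image

    def __post_init__(self) -> None:
        self.source = np.asarray(self.source, dtype=np.float64)
        self.target = np.asarray(self.target, dtype=np.float64)
        if self.source.shape != self.target.shape:
            raise ValueError("source and target must share a shape")
        if not np.isin(self.target, (0.0, 1.0)).all():
            raise ValueError("target must be binary")


def binarize_nucleus(image: np.ndarray, threshold: str | float = "otsu") -> np.ndarray:
    image = np.asarray(image, dtype=np.float64)
    t = threshold_otsu(image) if threshold == "otsu" else float(threshold)
    return (image > t).astype(np.float64)


def _bce(pred: nn.Tensor, target: np.ndarray, eps: float = 1e-7) -> nn.Tensor:
    """Mean per-pixel binary cross-entropy on the natural-log scale."""
    y = nn.clip(pred, eps, 1.0 - eps)
    t = nn.Tensor(target)
    ll = t * nn.log(y) + (1.0 - t) * nn.log(1.0 - y)
    return (-1.0 / target.size) * ll.sum()


def train_translator(
    pairs: list[TranslationPair],
    mcfg: ModelConfig,
    tcfg: TranslatorConfig,
) -> tuple[UNet, list[float]]:
    """Fit the translation model on random crops; returns model and loss history."""
    if not pairs:
        raise ValueError("need at least one training pair")
    if mcfg.in_channels != 1:
        raise ValueError("the translator takes a single source channel")
    k = tcfg.crop_size
    if k % 2**mcfg.depth:
        raise ValueError("crop_size must be divisible by 2^depth")
    model = build_model(mcfg)
    opt = nn.Adam(model.params, lr=tcfg.learning_rate)
    rng = np.random.default_rng(tcfg.seed)
    history: list[float] = []
    for _ in range(tcfg.max_epochs):
        losses = []
        for _ in range(tcfg.steps_per_epoch):
            xs, ts = [], []
            for _ in range(tcfg.batch_size):
                pair = pairs[rng.integers(len(pairs))]
                h, w = pair.source.shape
                r0 = int(rng.integers(h - k + 1))
                c0 = int(rng.integers(w - k + 1))
                xs.append(pair.source[None, r0 : r0 + k, c0 : c0 + k])
                ts.append(pair.target[None, r0 : r0 + k, c0 : c0 + k])
            out = model.forward(np.stack(xs))
            loss = _bce(out, np.stack(ts))
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(loss.item())
        history.append(float(np.mean(losses)))
        if history[-1] <= tcfg.stop_loss:
            break
    return model, history


def predict_full_field(model: UNet, image: np.ndarray, window: int = 64) -> np.ndarray:
    """Tiled full-field inference with 50%-overlapping windows and averaging."""
    image = np.asarray(image, dtype=np.float64)
    h, w = image.shape
    window = min(window, h, w)
    window -= window % 2**model.cfg.depth
    stride = window // 2
    acc = np.zeros((h, w))
    cnt = np.zeros((h, w))
    rows = sorted({min(r, h - window) for r in range(0, h, stride) if r < h})
    cols = sorted({min(c, w - window) for c in range(0, w, stride) if c < w})
    tiles = [(r, c) for r in rows for c in cols]
    for start in range(0, len(tiles), 32):
        chunk = tiles[start : start + 32]
        batch = np.stack([image[None, r : r + window, c : c + window] for r, c in chunk])
        out = model.predict(batch)[:, 0]
        for (r, c), y in zip(chunk, out):
            acc[r : r + window, c : c + window] += y
            cnt[r : r + window, c : c + window] += 1.0
    return acc / cnt


def synth_markers(
    model: UNet,
    image: np.ndarray,
    pixel_size: float = 1.0,
    window: int = 64,
    threshold: float = 0.08,
    min_distance: float = 14.0,
    **dog_kwargs,
) -> tuple[np.ndarray, MarkerSet]:
    """Synthetic nucleus probability image and the markers blob-detected on it.

    Predicted nucleus blobs are blurrier and lumpier than real stains, so the
    detector runs with a higher peak threshold and a merge radius close to a
    nucleus diameter — two maxima that close must belong to one nucleus.
    """
    prob = predict_full_field(model, image, window=window)
    markers = detect_blobs_dog(
        prob, pixel_size=pixel_size, threshold=threshold, min_distance=min_distance, **dog_kwargs
    )
    return prob, markers


def crossval_translate(
    scenes: list,
    channel: str,
    mcfg: ModelConfig,
    tcfg: TranslatorConfig,
    max_dist_um: float = 15.0,
    **dog_kwargs,
) -> list[dict]:
    """3-fold cross-validation of the synthetic-marker path on three scenes.

    Each fold trains the translator on two (image, binarized nucleus) pairs
    and scores blob-detected markers on the held-out scene against its true
    anchors. Returns one record per fold with the trained history, the
    held-out MarkerScore and the predicted markers.
    """
    if len(scenes) != 3:
        raise ValueError("cross-validation requires exactly 3 scenes")
    results = []
    for fold in range(3):
        train_scenes = [s for i, s in enumerate(scenes) if i != fold]
        held = scenes[fold]
        pairs = [
            TranslationPair(
                source=s.channels.channels[channel],
                target=binarize_nucleus(s.channels.channels["NUC"], tcfg.binarize_threshold),
            )
            for s in train_scenes
        ]
        model, history = train_translator(pairs, mcfg, tcfg)
        prob, markers = synth_markers(
            model, held.channels.channels[channel],
            pixel_size=held.channels.pixel_size, **dog_kwargs,
        )
        score: MarkerScore = pair_markers(markers, held.centers, max_dist_um=max_dist_um)
        results.append(
            dict(fold=fold, history=history, score=score, markers=markers, prob=prob)
        )
    return results
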