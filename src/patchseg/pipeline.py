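"""End-to-end pipeline: masking → markers → training → integration → evaluation.

Configured by a TOML file; every stage writes its artifact to the output
directory and logs one line. A single seed in the config drives all
randomness. Setting the mask source to "none" forces β = 0, which is the
mask-free ablation mode: training proceeds with no background constraint.
"""

from __future__ import annotations

import logging
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .assembly_eval import integrate, mean_iou
from .io import (
    ImageField,
    read_field,
    read_labels,
    read_markers,
    read_mask,
    write_json,
    write_labels,
    write_mask,
    write_markers,
)
from .markers import MarkerSet, detect_blobs_dog, markers_from_nucleus_image
from .masking import BinaryMask, ScribbleSet, estimate_alpha, mask_from_brightfield, mask_from_fluorescence
from .patching import PatchConfig
from .segmenter import ModelConfig, TrainConfig, UNet, predict_patches, train_segmenter
from .selfsup_loss import LossWeights
from .nucleus_translator import synth_markers

log = logging.getLogger("patchseg")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    channels: dict[str, str]  # name -> TIFF path
    train_channels: list[str]
    outdir: str = "out"
    pixel_size: float = 1.0
    seed: int = 0
    # markers
    marker_source: str = "labels"  # labels | dog | synthetic | csv
    nucleus_channel: str = "NUC"
    markers_path: str | None = None
    translator_checkpoint: str | None = None
    # mask
    mask_source: str = "graphcut"  # graphcut | classifier | none
    alpha: float = 0.5
    kappa: float = 1.0
    scribbles_path: str | None = None
    mask_channel: str | None = None
    # training
    patch: PatchConfig = field(default_factory=PatchConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    weights: LossWeights = field(default_factory=LossWeights)
    max_epochs: int = 60
    patience: int = 5
    rel_tol: float = 1e-3
    tile_size: int = 640
    learning_rate: float = 0.005
    # evaluation
    truth_labels: str | None = None

    def __post_init__(self) -> None:
        missing = [n for n in self.train_channels if n not in self.channels]
        if missing:
            raise ValueError(f"train_channels not among input channels: {missing}")
        if self.mask_source == "none":
            self.weights.beta = 0.0


def load_config(path: str | Path) -> PipelineConfig:
    raw = tomllib.loads(Path(path).read_text())
    base = Path(path).parent

    def _resolve(p):
        return str((base / p).resolve()) if p is not None else None

    inp = raw.get("input", {})
    markers = raw.get("markers", {})
    mask = raw.get("mask", {})
    patch = raw.get("patch", {})
    model = raw.get("model", {})
    train = raw.get("train", {})
    loss = raw.get("loss", {})
    seed = int(raw.get("seed", 0))
    pcfg = PatchConfig(**patch)
    cfg = PipelineConfig(
        channels={k: _resolve(v) for k, v in inp.get("channels", {}).items()},
        train_channels=list(inp.get("train_channels", [])),
        outdir=_resolve(raw.get("outdir", "out")),
        pixel_size=float(inp.get("pixel_size", 1.0)),
        seed=seed,
        marker_source=markers.get("source", "labels"),
        nucleus_channel=markers.get("nucleus_channel", "NUC"),
        markers_path=_resolve(markers.get("path")),
        translator_checkpoint=_resolve(markers.get("translator_checkpoint")),
        mask_source=mask.get("source", "graphcut"),
        alpha=float(mask.get("alpha", 0.5)),
        kappa=float(mask.get("kappa", 1.0)),
        scribbles_path=_resolve(mask.get("scribbles")),
        mask_channel=mask.get("channel"),
        patch=pcfg,
        model=ModelConfig(seed=seed, **model),
        weights=LossWeights(**loss),
        max_epochs=int(train.get("max_epochs", 60)),
        patience=int(train.get("patience", 5)),
        rel_tol=float(train.get("rel_tol", 1e-3)),
        tile_size=int(train.get("tile_size", 640)),
        learning_rate=float(train.get("learning_rate", 0.005)),
        truth_labels=_resolve(raw.get("truth_labels")),
    )
    return cfg


def _stage_mask(cfg: PipelineConfig, field_img: ImageField) -> BinaryMask:
    if cfg.mask_source == "none":
        return BinaryMask(m=np.ones(field_img.shape, dtype=np.uint8))
    channel = cfg.mask_channel or cfg.train_channels[0]
    image = field_img.channels[channel]
    alpha = estimate_alpha(cfg.alpha)
    if cfg.mask_source == "graphcut":
        return mask_from_fluorescence(image, alpha=alpha, kappa=cfg.kappa)
    if cfg.mask_source == "classifier":
        if cfg.scribbles_path is None:
            raise PipelineError("mask", "classifier mask source requires scribbles")
        scribbles = ScribbleSet(labels=read_mask_scribbles(cfg.scribbles_path))
        return mask_from_brightfield(image, scribbles, alpha=alpha, kappa=cfg.kappa)
    raise PipelineError("mask", f"unknown mask source {cfg.mask_source!r}")


def read_mask_scribbles(path: str | Path) -> np.ndarray:
    import tifffile

    return tifffile.imread(str(path)).astype(np.uint8)


def _stage_markers(cfg: PipelineConfig, field_img: ImageField) -> MarkerSet:
    if cfg.marker_source == "csv":
        if cfg.markers_path is None:
            raise PipelineError("markers", "marker source 'csv' requires a markers path")
        pts = np.round(read_markers(cfg.markers_path)).astype(np.int64)
        return MarkerSet(points=pts, pixel_size=cfg.pixel_size)
    if cfg.marker_source in ("labels", "dog"):
        if cfg.nucleus_channel not in field_img.channels:
            raise PipelineError("markers", f"no nucleus channel {cfg.nucleus_channel!r} for marker source {cfg.marker_source!r}")
        nuc = field_img.channels[cfg.nucleus_channel]
        if cfg.marker_source == "labels":
            return markers_from_nucleus_image(nuc, pixel_size=cfg.pixel_size)
        return detect_blobs_dog(nuc, pixel_size=cfg.pixel_size)
    if cfg.marker_source == "synthetic":
        if cfg.translator_checkpoint is None:
            raise PipelineError("markers", "synthetic markers require a translator checkpoint")
        model = UNet.load(cfg.translator_checkpoint)
        _, markers = synth_markers(
            model, field_img.channels[cfg.train_channels[0]], pixel_size=cfg.pixel_size
        )
        return markers
    raise PipelineError("markers", f"unknown marker source {cfg.marker_source!r}")


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute all stages; returns a dict of artifact paths and summary numbers."""
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict = {}

    log.info("stage=read channels=%s", list(cfg.channels))
    try:
        field_img = read_field(cfg.channels, pixel_size=cfg.pixel_size)
    except Exception as e:  # noqa: BLE001 - stage-tagged rethrow
        raise PipelineError("read", str(e)) from e

    log.info("stage=mask source=%s", cfg.mask_source)
    mask = _stage_mask(cfg, field_img)
    write_mask(out / "mask.tif", mask.m)
    artifacts["mask"] = out / "mask.tif"

    log.info("stage=markers source=%s", cfg.marker_source)
    markers = _stage_markers(cfg, field_img)
    if len(markers) == 0:
        raise PipelineError("markers", "no markers found")
    write_markers(out / "markers.csv", markers.points)
    artifacts["markers"] = out / "markers.csv"

    log.info("stage=train n_markers=%d", len(markers))
    mcfg = cfg.model
    expected_in = len(cfg.train_channels) + 1
    if mcfg.in_channels != expected_in:
        mcfg = ModelConfig(
            in_channels=expected_in, depth=mcfg.depth, base_filters=mcfg.base_filters,
            batchnorm=mcfg.batchnorm, seed=mcfg.seed,
        )
    tcfg = TrainConfig(
        learning_rate=cfg.learning_rate, tile_size=cfg.tile_size,
        max_epochs=cfg.max_epochs, patience=cfg.patience, rel_tol=cfg.rel_tol,
        weights=cfg.weights, patch=cfg.patch, seed=cfg.seed,
    )
    try:
        model, history = train_segmenter(
            field_img, markers, mask, mcfg, tcfg, channel_names=cfg.train_channels
        )
    except Exception as e:  # noqa: BLE001
        raise PipelineError("train", str(e)) from e
    model.save(out / "model.ckpt.npz")
    hist_df = pd.DataFrame(
        [
            dict(step=i, area=b.area_term, consistency=b.consistency_term,
                 mask=b.mask_term, total=b.total)
            for i, b in enumerate(history.epochs)
        ]
    )
    hist_df.to_csv(out / "history.csv", index=False)
    artifacts["model"] = out / "model.ckpt.npz"
    artifacts["history"] = out / "history.csv"
    for i, b in enumerate(history.epochs):
        log.debug("epoch=%d area=%.1f consistency=%.1f mask=%.1f total=%.1f",
                  i, b.area_term, b.consistency_term, b.mask_term, b.total)

    log.info("stage=integrate")
    preds = predict_patches(model, field_img, markers, cfg.patch, cfg.train_channels,
                            batch_size=10_000)
    labels = integrate(preds, field_img.shape)
    write_labels(out / "labels.tif", labels)
    artifacts["labels"] = out / "labels.tif"

    summary = dict(
        n_markers=len(markers), epochs=history.stopped_at,
        final_loss=history.epochs[-1].total,
    )
    if cfg.truth_labels is not None:
        log.info("stage=eval")
        truth = read_labels(cfg.truth_labels)
        ev = mean_iou(labels, truth)
        summary["mean_iou"] = ev.mean_iou
        write_json(out / "eval.json", dict(mean_iou=ev.mean_iou, per_cell_iou=ev.per_cell_iou))
        artifacts["eval"] = out / "eval.json"
    write_json(out / "summary.json", summary)
    artifacts["summary"] = out / "summary.json"
    return {"artifacts": artifacts, "summary": summary}
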