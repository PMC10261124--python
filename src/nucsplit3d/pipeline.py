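"""Config-driven end-to-end runs: synth -> render -> train -> segment -> evaluate.

A run config is a nested mapping (usually loaded from YAML) with one section
per stage plus a global ``seed`` and ``outdir``.  Only the sections present
are executed, in pipeline order; every artifact lands in ``outdir`` and a
run manifest records parameters and seed for provenance.  Unknown keys are
rejected before any stage runs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from typing import Any, Dict, Optional

import numpy as np

from . import synth as synth_mod
from .instseg import SEG_PRESETS, InstanceSegParams, segment_instances
from .metrics import DEFAULT_THRESHOLDS, evaluate
from .nn.losses import LossWeights
from .nn.model import ArchConfig, build_model, load_checkpoint, predict
from .nn.train import TrainConfig, train
from .render import RenderConfig, render
from .synth import SYNTH_PRESETS, SynthConfig, generate_labels
from .tiling import predict_tiled
from .vecfield import generate_vector_field
from .volumes import IntensityVolume, LabelVolume, read_volume, write_volume

__all__ = ["RunConfig", "run_pipeline"]

log = logging.getLogger("nucsplit3d")

_STAGES = ("synth", "render", "train", "segment", "evaluate")
_TOP_KEYS = set(_STAGES) | {"seed", "outdir", "log_level"}


def _build(cls, section: Dict[str, Any], presets: Optional[dict] = None):
    """Instantiate a config dataclass from a mapping, honoring ``preset``."""
    section = dict(section)
    preset = section.pop("preset", None)
    base = presets[preset] if preset is not None else None
    if base is not None:
        kwargs = dataclasses.asdict(base)
    else:
        kwargs = {}
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = set(section) - fields
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    kwargs.update(section)
    kwargs = {k: (tuple(v) if isinstance(v, list) else v) for k, v in kwargs.items()}
    return cls(**{k: v for k, v in kwargs.items() if k in fields})


@dataclasses.dataclass
class RunConfig:
    """Validated run configuration; see :func:`run_pipeline`."""

    seed: int = 0
    outdir: str = "run"
    log_level: str = "INFO"
    synth: Optional[Dict[str, Any]] = None
    render: Optional[Dict[str, Any]] = None
    train: Optional[Dict[str, Any]] = None
    segment: Optional[Dict[str, Any]] = None
    evaluate: Optional[Dict[str, Any]] = None

    @classmethod
    def from_mapping(cls, raw: Dict[str, Any]) -> "RunConfig":
        unknown = set(raw) - _TOP_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def run_pipeline(config: RunConfig) -> Dict[str, Any]:
    """Execute the configured stages in order; returns artifact paths/metrics."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    os.makedirs(config.outdir, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    artifacts: Dict[str, Any] = {}

    manifest = {"seed": config.seed, "stages": [s for s in _STAGES
                                                if getattr(config, s) is not None]}

    labels = None
    intensity = None
    if config.synth is not None:
        cfg = _build(SynthConfig, config.synth, SYNTH_PRESETS)
        log.info("synth: %s", cfg)
        labels = generate_labels(cfg, rng)
        path = os.path.join(config.outdir, "labels.tif")
        write_volume(labels, path)
        artifacts["labels"] = path
        manifest["synth"] = dataclasses.asdict(cfg)

    if config.render is not None:
        section = dict(config.render)
        labels_path = section.pop("labels", None)
        if labels_path:
            labels = read_volume(labels_path, kind="label")
        if labels is None:
            raise ValueError("render stage needs a synth stage or a labels path")
        cfg = _build(RenderConfig, section)
        intensity = render(labels, cfg, rng)
        path = os.path.join(config.outdir, "synth.tif")
        write_volume(intensity, path)
        artifacts["intensity"] = path
        manifest["render"] = dataclasses.asdict(cfg)

    model = None
    if config.train is not None:
        section = dict(config.train)
        n_volumes = int(section.pop("volumes", 4))
        arch = _build(ArchConfig, section.pop("arch", {}))
        synth_cfg = _build(SynthConfig, section.pop("synth", {}), SYNTH_PRESETS)
        render_cfg = _build(RenderConfig, section.pop("render", {}))
        tcfg = _build(TrainConfig, section)
        dataset = []
        for _ in range(n_volumes):
            lab = generate_labels(synth_cfg, rng)
            vol = render(lab, render_cfg, rng)
            dataset.append((vol, lab, generate_vector_field(lab)))
        model = build_model(arch)
        ckpt = os.path.join(config.outdir, "model.npz")
        tcfg.checkpoint = ckpt
        model, history = train(model, dataset, tcfg)
        hist_path = os.path.join(config.outdir, "loss_history.csv")
        with open(hist_path, "w") as f:
            f.write("epoch,loss\n")
            for i, v in enumerate(history):
                f.write(f"{i},{v}\n")
        artifacts["model"] = ckpt
        artifacts["loss_history"] = hist_path
        manifest["train"] = {"volumes": n_volumes, "epochs": tcfg.epochs,
                             "final_loss": history[-1]}

    seg = None
    if config.segment is not None:
        section = dict(config.segment)
        params = _build(InstanceSegParams, section.pop("params", {}), SEG_PRESETS)
        tile = section.pop("tile", None)
        mask_path = section.pop("mask", None)
        vec_path = section.pop("vecfield", None)
        input_path = section.pop("input", None)
        model_path = section.pop("model", None)
        if section:
            raise ValueError(f"unknown segment keys: {sorted(section)}")
        if mask_path and vec_path:
            mask = read_volume(mask_path, kind="label").data
            field = read_volume(vec_path, kind="vector")
        else:
            if input_path:
                intensity = read_volume(input_path, kind="intensity")
            if intensity is None:
                raise ValueError("segment stage needs an input volume or mask+vecfield")
            if model_path:
                model = load_checkpoint(model_path)
            if model is None:
                raise ValueError("segment stage needs a trained model")
            if tile:
                mask, field = predict_tiled(
                    intensity, lambda sub: _model_predictor(model, sub), int(tile)
                )
            else:
                mask, field = predict(model, intensity)
        seg = segment_instances(mask, field, params, intensity)
        path = os.path.join(config.outdir, "seg.tif")
        write_volume(seg, path)
        artifacts["seg"] = path

    if config.evaluate is not None:
        section = dict(config.evaluate)
        pred_path = section.pop("pred", None)
        gt_path = section.pop("gt", None)
        thresholds = section.pop("thresholds", list(DEFAULT_THRESHOLDS))
        if section:
            raise ValueError(f"unknown evaluate keys: {sorted(section)}")
        pred = read_volume(pred_path, kind="label") if pred_path else seg
        gt = read_volume(gt_path, kind="label") if gt_path else labels
        if pred is None or gt is None:
            raise ValueError("evaluate stage needs pred and gt label volumes")
        report = evaluate(gt, pred, thresholds)
        path = os.path.join(config.outdir, "report.json")
        with open(path, "w") as f:
            json.dump(report.as_dict(), f, indent=2)
        artifacts["report"] = path
        artifacts["metrics"] = report.as_dict()

    with open(os.path.join(config.outdir, "manifest.json"), "w") as f:
        json.dump(manifest, f, indent=2, default=str)
    return artifacts


def _model_predictor(model, sub: np.ndarray):
    prob, field = predict(model, IntensityVolume(np.maximum(sub, 0)))
    return prob, field.data
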