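"""End-to-end orchestration: config, seeding, manifests, result tables.

A run chains synthetic corpus generation, regime training and the
evaluation battery (spatial-frequency tuning, shape bias, corruption
robustness) for every (regime, seed) cell, writing one CSV table per stage
plus a JSON manifest keyed by config hash. Completed stages are skipped on
re-run when their output and hash already match, so interrupted runs
resume; failures leave prior outputs untouched.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from PIL import Image

from .behavior import classify_cue_conflict, robustness_curve, shape_bias
from .synthetic import (
    ShapeTexSpec,
    TrainingConfig,
    generate_cue_conflict,
    generate_shapetex,
    train_reference_models,
)
from .tuning import layerwise_tuning_summary, probe_bank

__all__ = ["RunConfig", "run_experiment", "save_corpus_png", "load_run_config"]

_STAGES = ("train", "tuning", "shape_bias", "robustness")


@dataclass(frozen=True)
class RunConfig:
    """One experiment: a corpus spec, regimes, stages and seeds."""

    dataset: ShapeTexSpec = field(default_factory=ShapeTexSpec)
    regimes: tuple = ("clear", "strong_blur")
    stages: tuple = _STAGES
    seeds: tuple = (0,)
    out_dir: str = "runs/default"
    epochs: int = 40
    n_conflict_per_pair: int = 3
    robustness_kinds: tuple = ("gaussian_noise", "defocus_blur", "pixelate")

    def __post_init__(self):
        if not self.seeds:
            raise ValueError("seeds must be nonempty")
        unknown = set(self.stages) - set(_STAGES)
        if unknown:
            raise ValueError(f"unknown stages {sorted(unknown)}; known: {_STAGES}")

    def hash(self) -> str:
        payload = json.dumps(
            {**asdict(self), "dataset": asdict(self.dataset)}, sort_keys=True, default=list
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def load_run_config(path) -> RunConfig:
    """Read a RunConfig from YAML; dataset fields nest under `dataset`."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    ds = ShapeTexSpec(**raw.pop("dataset", {}))
    for key in ("regimes", "stages", "seeds", "robustness_kinds"):
        if key in raw:
            raw[key] = tuple(raw[key])
    return RunConfig(dataset=ds, **raw)


def save_corpus_png(corpus, out_dir) -> Path:
    """Write a corpus as 8-bit PNGs plus a CSV manifest; returns the manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, im in enumerate(corpus):
        name = f"img_{i:05d}_s{im.shape_label}_t{im.texture_label}.png"
        Image.fromarray((np.clip(im.pixels, 0, 1) * 255).astype(np.uint8)).save(out / name)
        rows.append({"filename": name, "shape_label": im.shape_label,
                     "texture_label": im.texture_label})
    manifest = out / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def _noisy_eval_set(spec: ShapeTexSpec, seed_offset: int):
    held = ShapeTexSpec(
        spec.n_shape_classes, spec.n_texture_classes, spec.image_size,
        max(4, spec.samples_per_class // 2), spec.seed + 7919 + seed_offset,
    )
    corpus = generate_shapetex(held)
    return np.stack([im.pixels for im in corpus]), np.array([im.shape_label for im in corpus])


def run_experiment(cfg: RunConfig) -> dict:
    """Execute all stages for every (regime, seed); returns the manifest dict.

    The manifest records one entry per (regime, seed, stage) with status,
    wall time and output path; tables land under cfg.out_dir as CSV.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "manifest.json"
    cfg_hash = cfg.hash()
    manifest = {"config_hash": cfg_hash, "entries": {}}
    if manifest_path.exists():
        prior = json.loads(manifest_path.read_text())
        if prior.get("config_hash") == cfg_hash:
            manifest = prior

    bank = probe_bank(cfg.dataset.image_size)
    conflict = generate_cue_conflict(cfg.dataset, cfg.n_conflict_per_pair)
    for seed in cfg.seeds:
        spec = ShapeTexSpec(
            cfg.dataset.n_shape_classes, cfg.dataset.n_texture_classes,
            cfg.dataset.image_size, cfg.dataset.samples_per_class, cfg.dataset.seed + seed,
        )
        corpus = generate_shapetex(spec)
        eval_x, eval_y = _noisy_eval_set(cfg.dataset, seed)
        for regime in cfg.regimes:
            model = None
            for stage in cfg.stages:
                key = f"{regime}/seed{seed}/{stage}"
                dest = out / f"{stage}_{regime}_seed{seed}.csv"
                entry = manifest["entries"].get(key)
                if entry and entry.get("status") == "done" and Path(entry["output"]).exists():
                    if stage != "train":
                        continue  # model retrained below only if later stages need it
                needs_model = stage in ("tuning", "shape_bias", "robustness") or stage == "train"
                if needs_model and model is None:
                    model = train_reference_models(
                        corpus, regime, TrainingConfig(epochs=cfg.epochs, seed=seed)
                    )
                t0 = time.time()
                try:
                    if stage == "train":
                        df = pd.DataFrame(
                            [{"regime": regime, "seed": seed,
                              "train_accuracy": model.meta["train_accuracy"]}]
                        )
                    elif stage == "tuning":
                        df = layerwise_tuning_summary(model, bank).reset_index()
                    elif stage == "shape_bias":
                        sb = shape_bias(classify_cue_conflict(model, conflict))
                        df = pd.DataFrame([{
                            "regime": regime, "seed": seed, "score": sb.score,
                            "n_shape": sb.n_shape, "n_texture": sb.n_texture,
                            "n_other": sb.n_other, "defined": sb.defined,
                        }])
                    elif stage == "robustness":
                        df = robustness_curve(
                            model, eval_x, eval_y, kinds=cfg.robustness_kinds, seed=seed
                        ).reset_index()
                    df.to_csv(dest, index=False)
                    manifest["entries"][key] = {
                        "status": "done", "output": str(dest),
                        "seconds": round(time.time() - t0, 3),
                    }
                except Exception as exc:  # record partial state, then re-raise
                    manifest["entries"][key] = {"status": "failed", "error": str(exc)}
                    manifest_path.write_text(json.dumps(manifest, indent=2))
                    raise
                manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest
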