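"""Experiment orchestration: train and compare models across ablation
transforms and punctual baselines on one fixed train/validation/test split.
"""

from __future__ import annotations

import dataclasses
import json
import os
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import evaluation, models, synthetic
from .raster import RasterStack, read_occurrences, read_stack
from .synthetic import OccurrenceSet, generate_world


@dataclasses.dataclass
class RunConfig:
    """Everything needed to replay a run; serialized into the output dir."""

    manifest: str | None = None
    occurrences: str | None = None
    world: dict | None = None  # kwargs of synthetic.generate_world
    patch_size: int = 16
    channels: tuple[int, ...] = (16, 32, 64)
    train: dict = dataclasses.field(default_factory=dict)
    transforms: tuple[str, ...] = ("none",)
    baselines: tuple[str, ...] = ()  # subset of {"dnn", "rf", "bt"}
    k: int = 30
    k_max: int = 30
    out_dir: str | None = None
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str, **overrides) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update(overrides)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.channels = tuple(cfg.channels)
        cfg.transforms = tuple(cfg.transforms)
        cfg.baselines = tuple(cfg.baselines)
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["channels"] = list(self.channels)
        d["transforms"] = list(self.transforms)
        d["baselines"] = list(self.baselines)
        d["train"] = {
            k: list(v) if isinstance(v, tuple) else v
            for k, v in self.train.items()
        }
        return d


def load_inputs(config: RunConfig) -> tuple[RasterStack, OccurrenceSet]:
    """Stack (expanded + filled) and partitioned occurrences per the config."""
    if config.world is not None:
        world = generate_world(seed=config.seed, **config.world)
        return world.stack, world.occurrences
    if config.manifest is None or config.occurrences is None:
        raise ValueError("config must give either world parameters or input paths")
    stack = read_stack(config.manifest).prepared()
    occ = OccurrenceSet(read_occurrences(config.occurrences))
    if (occ.records["partition"] == "train").all():
        occ = synthetic.split_occurrences(occ, seed=config.seed)
    return stack, occ


def _train_one(
    stack: RasterStack,
    occ: OccurrenceSet,
    config: RunConfig,
    transform: str,
    input_mode: str = "tensor",
):
    model = models.SpeciesClassifier(
        n_layers=len(stack),
        patch_size=config.patch_size,
        channels=config.channels,
        input_mode=input_mode,
    )
    train_cfg = models.TrainConfig(seed=config.seed, **config.train)
    models.train(model, occ, stack, train_cfg, transform=transform)
    return model


def _evaluate_bundle(
    bundle: models.PredictionBundle,
    truths: np.ndarray,
    config: RunConfig,
    use_logits: bool,
) -> evaluation.EvaluationReport:
    label_index = {s: i for i, s in enumerate(bundle.label_space)}
    truth_idx = np.array([label_index[s] for s in truths])
    scores = bundle.logits if use_logits else bundle.probabilities
    return evaluation.evaluate_predictions(
        bundle.probabilities,
        scores,
        truth_idx,
        k=config.k,
        k_max=config.k_max,
        seed=config.seed,
    )


def run_experiment(config: RunConfig) -> dict:
    """Train one model per requested transform (plus baselines) on the same
    split and report their metric curves side by side."""
    stack, occ = load_inputs(config)
    test_df = occ.subset("test")
    if len(test_df) == 0:
        raise ValueError("test partition is empty")
    test_points = test_df[["lon", "lat"]].to_numpy()
    test_truths = test_df["species_id"].to_numpy()

    reports: dict[str, evaluation.EvaluationReport] = {}
    for transform in config.transforms:
        model = _train_one(stack, occ, config, transform)
        bundle = models.predict(
            model, test_points, stack, transform=transform, seed=config.seed
        )
        reports[f"cnn:{transform}"] = _evaluate_bundle(
            bundle, test_truths, config, use_logits=True
        )

    if "dnn" in config.baselines:
        model = _train_one(stack, occ, config, "none", input_mode="punctual")
        bundle = models.predict(model, test_points, stack, "none", seed=config.seed)
        reports["dnn"] = _evaluate_bundle(bundle, test_truths, config, use_logits=True)

    if {"rf", "bt"} & set(config.baselines):
        train_df = occ.subset("train")
        x_tr = models.extract_dataset(
            train_df[["lon", "lat"]].to_numpy(), stack, config.patch_size, "punctual"
        )
        x_te = models.extract_dataset(test_points, stack, config.patch_size, "punctual")
        label_space = occ.species_ids
        if "rf" in config.baselines:
            rf = models.fit_rf_baseline(
                x_tr, train_df["species_id"].to_numpy(),
                label_space=label_space, seed=config.seed,
            )
            reports["rf"] = _evaluate_bundle(
                rf.predict_bundle(x_te), test_truths, config, use_logits=False
            )
        if "bt" in config.baselines:
            bt = models.fit_bt_baseline(
                x_tr, train_df["species_id"].to_numpy(),
                label_space=label_space, seed=config.seed,
            )
            reports["bt"] = _evaluate_bundle(
                bt.predict_bundle(x_te), test_truths, config, use_logits=False
            )

    curves = []
    for name, report in reports.items():
        frame = report.curves.copy()
        frame.insert(0, "model", name)
        curves.append(frame)
    comparison = pd.concat(curves, ignore_index=True)
    result = {
        "config": config.to_dict(),
        "summaries": {name: r.summary for name, r in reports.items()},
    }
    if config.out_dir:
        os.makedirs(config.out_dir, exist_ok=True)
        comparison.to_csv(os.path.join(config.out_dir, "msa_curves.csv"), index=False)
        with open(os.path.join(config.out_dir, "report.json"), "w") as fh:
            json.dump(result, fh, indent=2)
        with open(os.path.join(config.out_dir, "config.yml"), "w") as fh:
            yaml.safe_dump(config.to_dict(), fh)
        for name, report in reports.items():
            safe = name.replace(":", "_")
            report.write(
                os.path.join(config.out_dir, f"per_species_{safe}.csv"),
                os.path.join(config.out_dir, f"summary_{safe}.json"),
            )
    result["curves"] = comparison
    result["reports"] = reports
    return result
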