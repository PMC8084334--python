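"""Desk-scale presets shared by the test-suite and the acceptance script.

These pin the synthetic worlds, model sizes and training schedules that are
known to be CPU-trainable in minutes while exhibiting the qualitative
behaviour of interest (ablation ordering, rare-species advantage).
"""

from __future__ import annotations

import numpy as np

from .models import SpeciesClassifier, TrainConfig
from .synthetic import SyntheticWorld, generate_world


def default_world(seed: int, **overrides) -> SyntheticWorld:
    """The documented default world: 256x256 grid, 6 quantitative layers at
    three correlation lengths, one 5-class categorical layer, 40 species
    (half landscape-structure), 8000 occurrences."""
    params = dict(
        grid_size=256,
        n_quantitative=6,
        correlation_lengths=(4.0, 8.0, 16.0),
        n_landcover_classes=5,
        n_species=40,
        structure_fraction=0.5,
        n_occurrences=8000,
        tail_exponent=1.2,
        window=4,
        selectivity=4.0,
    )
    params.update(overrides)
    return generate_world(seed=seed, **params)


def ablation_world(seed: int, **overrides) -> SyntheticWorld:
    """Structure-dominated variant used for the ablation-ordering protocol:
    all species depend on neighborhood arrangement, none on punctual values,
    so transforms that destroy structure collapse to chance."""
    params = dict(
        grid_size=192,
        n_quantitative=6,
        correlation_lengths=(4.0, 8.0, 16.0),
        n_landcover_classes=5,
        landcover_correlation_length=2.0,
        n_species=64,
        structure_fraction=1.0,
        n_occurrences=3200,
        tail_exponent=0.5,
        window=4,
        selectivity=4.0,
    )
    params.update(overrides)
    return generate_world(seed=seed, **params)


def longtail_world(seed: int, **overrides) -> SyntheticWorld:
    """Long-tail world for the rare-species comparison: a steep frequency
    tail, sharp (thresholded) niches, and rare species whose niches are
    perturbed copies of abundant structure-dependent species — the regime
    where feature sharing across species can pay off while punctual
    memorization cannot."""
    params = dict(
        grid_size=192,
        n_quantitative=6,
        correlation_lengths=(4.0, 8.0, 16.0),
        n_landcover_classes=5,
        n_species=72,
        structure_fraction=0.7,
        n_occurrences=4200,
        tail_exponent=1.9,
        clone_fraction=0.4,
        niche_intercept=-6.0,
        window=4,
        selectivity=4.0,
    )
    params.update(overrides)
    return generate_world(seed=seed, **params)


DESK_PATCH_SIZE = 16
DESK_CHANNELS = (12, 24, 48)
DESK_POOL = "gap"


def desk_model(n_layers: int, input_mode: str = "tensor") -> SpeciesClassifier:
    return SpeciesClassifier(
        n_layers=n_layers,
        patch_size=DESK_PATCH_SIZE,
        channels=DESK_CHANNELS,
        input_mode=input_mode,
        pool=DESK_POOL,
    )


def desk_train_config(seed: int = 0, **overrides) -> TrainConfig:
    params = dict(
        initial_lr=0.1,
        lr_drop_epochs=(17, 22),
        dropout=0.1,
        momentum=0.9,
        max_epochs=24,
        validation_period=5,
        batch_size=64,
        seed=seed,
    )
    params.update(overrides)
    return TrainConfig(**params)


def ablation_train_config(seed: int = 0) -> TrainConfig:
    """Lighter schedule for the 18-training ordering protocol (3 seeds x
    6 models on one CPU)."""
    return desk_train_config(seed=seed, max_epochs=20, lr_drop_epochs=(14, 18))


def rare_species_model(n_layers: int) -> SpeciesClassifier:
    """Wider backbone used for the rare-species comparison: feature sharing
    across species only materializes with enough feature capacity."""
    return SpeciesClassifier(
        n_layers=n_layers, patch_size=DESK_PATCH_SIZE,
        channels=(16, 32, 64), pool=DESK_POOL,
    )


def rare_species_train_config(seed: int = 0) -> TrainConfig:
    return desk_train_config(
        seed=seed, max_epochs=36, lr_drop_epochs=(28, 33), weight_decay=1e-3
    )


def evaluate_on_test(model_or_bundle, world: SyntheticWorld, k: int = 30):
    """Convenience: MSA_k of a fitted model (or bundle) on the world's test
    partition, plus the per-species table."""
    from . import evaluation, models

    test = world.occurrences.subset("test")
    label_space = world.occurrences.species_ids
    idx = {s: i for i, s in enumerate(label_space)}
    truths = np.array([idx[s] for s in test["species_id"]])
    if hasattr(model_or_bundle, "probabilities"):
        bundle = model_or_bundle
    else:
        bundle = models.predict(
            model_or_bundle, test[["lon", "lat"]].to_numpy(), world.stack
        )
    ranks = evaluation.compute_ranks(bundle.probabilities, truths)
    sa, msa = evaluation.mean_species_topk(ranks, truths, k)
    return sa, msa, truths, bundle
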