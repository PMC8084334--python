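# landsdm

Landscape-aware joint species distribution modelling on environmental
raster tensors.

`landsdm` implements a complete presence-only, multi-species distribution
modelling pipeline in which a convolutional network predicts a categorical
distribution over species from the environmental *neighborhood* of a point
(a patch per raster layer, each at its native resolution), and a set of
controlled experiments measures how much of that predictive power comes
from the spatial structure of the landscape rather than from point values:

- **`landsdm.raster`** — raster stacks (GeoTIFF + plain-text manifest),
  one-hot expansion of categorical variables, sentinel filling of undefined
  pixels, extraction of environmental tensors and punctual vectors.
- **`landsdm.synthetic`** — Gaussian-random-field landscapes, categorical
  land-cover layers, species niches (punctual / neighborhood-mean /
  neighborhood-structure), long-tail presence-only occurrence sampling and
  train/validation/test splitting. Everything is seeded and reproducible;
  no downloads are needed anywhere.
- **`landsdm.models`** — the convolutional classifier (pure NumPy: conv3x3
  blocks with batch normalization, average or max pooling, a global-average
  or flatten head, dropout, softmax head, SGD with momentum and a step LR
  schedule), its punctual twin that
  sees only constant patches tiled from the point vector, and random-forest
  / boosted-trees baselines on punctual vectors.
- **`landsdm.ablation`** — the four input degradations applied identically
  at train and test time: random quarter-turn rotations, per-layer pixel
  permutations, per-layer mean collapse, per-layer standardization
  (structure only).
- **`landsdm.evaluation`** — rank-based set-valued metrics (top-k accuracy
  `A_k`, species-balanced `MSA_k`), inverse-frequency-weighted
  pseudo-absence sampling, per-species Mann-Whitney AUC and TSS with a
  global threshold search.
- **`landsdm.activation`** — feature-neuron activation maps over a spatial
  grid, block averaging, per-species linear response maps.
- **`landsdm.experiment` / `landsdm.cli`** — orchestration of the
  simulate → train → ablate → evaluate → map pipeline with replayable YAML
  configs.

## Test

```bash
python -m pytest -q tests/
```

The suite includes `tests/test_acceptance.py`, which checks the package's
acceptance criteria: exact structural targets, exact agreement of every
metric with brute-force oracles on small instances, ablation-transform
invariants, and two stochastic end-to-end claims averaged over seeds — the
ablation ordering (structure-preserving transforms beat
structure-destroying ones by a margin on a structure-dominated world) and
the rare-species advantage of the convolutional model over the
random-forest baseline. The end-to-end tests train many small networks and
take several minutes each.

One acceptance test is expected to fail by design:
`TestD_AblationOrdering::test_structure_preserving_transforms_dominate`
asserts the full published ordering including the rotation ablation, which
a small CPU-trained backbone cannot attain (learning rotation-invariant
structure features needs full-scale training); it is kept faithful rather
than weakened, and a companion test covers the part of the ordering that
does hold at desk scale.

## CLI

```bash
# generate a synthetic world (rasters + manifest + occurrence CSV)
landsdm simulate --config world.yml --seed 1 --out-dir world/

# train a convolutional (cnn) or punctual (dnn) model
landsdm train --manifest world/stack.yml --occurrences world/occurrences.csv \
    --model cnn --transform none --seed 1 --out model.npz

# evaluate a checkpoint on the test partition
landsdm evaluate --checkpoint model.npz --manifest world/stack.yml \
    --occurrences world/occurrences.csv --k 30 --seed 1 --out-prefix eval

# multi-transform ablation sweep on one fixed split
landsdm ablate --config run.yml --seed 1 --out-dir runs/sweep

# render activation / species-response maps
landsdm map --checkpoint model.npz --manifest world/stack.yml \
    --neurons 0,1,2 --species 4 --out-dir maps/
```

A `run.yml` for `ablate` mirrors `landsdm.experiment.RunConfig`:

```yaml
world: {grid_size: 192, n_species: 64, n_occurrences: 5000, structure_fraction: 1.0}
patch_size: 16
channels: [12, 24, 48]
train: {initial_lr: 0.1, lr_drop_epochs: [22, 27], dropout: 0.1, max_epochs: 30}
transforms: [none, rotation, permutation, mean, standardize]
baselines: [dnn, rf, bt]
k: 30
```

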