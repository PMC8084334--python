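"""Joint multi-species predictors and their training loop.

Two neural variants share one convolutional architecture: the tensor model
reads the full environmental patch, while the punctual variant feeds the same
network constant patches tiled from the occurrence-point vector, so any
performance gap is attributable to the neighborhood information alone.  Tree
baselines (random forest, shallow boosted trees) consume punctual vectors.

All models output a categorical distribution over the full species label
space (every species of the occurrence set, including those missing from the
training split).
"""

from __future__ import annotations

import dataclasses
import json
from typing import Sequence

import numpy as np
from sklearn.ensemble import HistGradientBoostingClassifier, RandomForestClassifier

from . import evaluation
from .ablation import AblationSpec, apply_batch, as_spec
from .nn import ConvBackbone, SGDMomentum, dropout_forward
from .raster import RasterStack, extract_punctual_vector, extract_tensor
from .synthetic import OccurrenceSet


class ModelError(ValueError):
    pass


# ---------------------------------------------------------------------------
# head, loss, schedule
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class SpeciesHead:
    """Per-species linear readout: weights (feature_dim, m), intercepts (m,)."""

    weights: np.ndarray
    intercepts: np.ndarray

    @property
    def feature_dim(self) -> int:
        return self.weights.shape[0]

    @property
    def n_species(self) -> int:
        return self.weights.shape[1]


def softmax(logits: np.ndarray) -> np.ndarray:
    """Row-wise softmax with max-subtraction for overflow safety."""
    if not np.all(np.isfinite(logits)):
        raise ModelError("non-finite logits")
    shifted = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_head(z: np.ndarray, head: SpeciesHead) -> np.ndarray:
    """Categorical probabilities from features through the linear head."""
    single = np.ndim(z) == 1
    z = np.atleast_2d(z)
    if z.shape[1] != head.feature_dim:
        raise ModelError(
            f"feature dim {z.shape[1]} does not match head ({head.feature_dim})"
        )
    logits = z @ head.weights + head.intercepts
    probs = softmax(logits)
    return probs[0] if single else probs


PROBABILITY_FLOOR = 1e-12


def cross_entropy(probabilities: np.ndarray, true_species: np.ndarray | int) -> float:
    """Mean negative log-probability of the true species (floored)."""
    probs = np.atleast_2d(probabilities)
    truths = np.atleast_1d(np.asarray(true_species, dtype=int))
    if truths.min() < 0 or truths.max() >= probs.shape[1]:
        raise ModelError("true species index outside the label space")
    p_true = probs[np.arange(len(truths)), truths]
    return float(-np.log(np.clip(p_true, PROBABILITY_FLOOR, None)).mean())


@dataclasses.dataclass
class TrainConfig:
    initial_lr: float = 0.05
    lr_drop_epochs: tuple[int, ...] = (12, 18)
    dropout: float = 0.3
    momentum: float = 0.9
    weight_decay: float = 0.0
    max_epochs: int = 20
    validation_period: int = 5
    batch_size: int = 64
    seed: int = 0

    def __post_init__(self) -> None:
        drops = tuple(self.lr_drop_epochs)
        if any(b <= a for a, b in zip(drops, drops[1:])):
            raise ModelError("lr_drop_epochs must be strictly increasing")
        self.lr_drop_epochs = drops


def reference_train_config(**overrides) -> TrainConfig:
    """The full-scale reference schedule: lr 0.1 dropping tenfold before
    epochs 90/130/150/170, dropout 0.7, momentum 0.9, validation every 5
    epochs.  Desk-scale runs use the shorter presets instead."""
    base = dict(
        initial_lr=0.1,
        lr_drop_epochs=(90, 130, 150, 170),
        dropout=0.7,
        momentum=0.9,
        max_epochs=180,
        validation_period=5,
    )
    base.update(overrides)
    return TrainConfig(**base)


def lr_schedule(epoch: int, config: TrainConfig) -> float:
    """``initial_lr`` divided by 10 for every drop epoch <= ``epoch``."""
    if epoch < 0:
        raise ModelError("epoch must be >= 0")
    n_drops = sum(1 for d in config.lr_drop_epochs if d <= epoch)
    return config.initial_lr * 10.0 ** (-n_drops)


# ---------------------------------------------------------------------------
# prediction bundle
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class PredictionBundle:
    """Per-observation features z, logits and categorical probabilities."""

    features: np.ndarray  # (n, feature_dim)
    logits: np.ndarray  # (n, m)
    probabilities: np.ndarray  # (n, m)
    label_space: np.ndarray  # (m,) species ids, ascending

    def __len__(self) -> int:
        return self.features.shape[0]


# ---------------------------------------------------------------------------
# the convolutional classifier (tensor or punctual input)
# ---------------------------------------------------------------------------


class SpeciesClassifier:
    """Convolutional joint species classifier.

    ``input_mode='tensor'`` consumes real environmental patches;
    ``input_mode='punctual'`` tiles the occurrence-point vector into constant
    patches of the same shape, keeping the architecture (and thus the
    comparison) identical.
    """

    def __init__(
        self,
        n_layers: int,
        patch_size: int,
        channels: Sequence[int] = (32, 64, 256),
        input_mode: str = "tensor",
        pool: str = "gap",
        block_pool: str = "avg",
    ):
        if input_mode not in ("tensor", "punctual"):
            raise ModelError(f"unknown input_mode {input_mode!r}")
        self.backbone = ConvBackbone(
            n_layers, tuple(channels), patch_size, pool=pool, block_pool=block_pool
        )
        self.n_layers = n_layers
        self.patch_size = patch_size
        self.input_mode = input_mode
        self.params: dict[str, np.ndarray] | None = None
        self.bn_state: dict[str, np.ndarray] = {}
        self.label_space: np.ndarray | None = None
        self.norm_mean: np.ndarray | None = None
        self.norm_sd: np.ndarray | None = None
        self.transform_kind: str = "none"
        self.history: list[dict] = []
        self.fitted = False

    @property
    def feature_dim(self) -> int:
        return self.backbone.feature_dim

    @property
    def head(self) -> SpeciesHead:
        if self.params is None:
            raise ModelError("model is not fitted")
        return SpeciesHead(self.params["head_w"], self.params["head_b"])

    # -- internals --------------------------------------------------------

    def _init_params(self, n_species: int, rng: np.random.Generator) -> None:
        params = self.backbone.init_params(rng)
        f = self.feature_dim
        params["head_w"] = (
            rng.standard_normal((f, n_species)) * np.sqrt(1.0 / f)
        ).astype(np.float32)
        params["head_b"] = np.zeros(n_species, dtype=np.float32)
        self.params = params
        self.bn_state = {}
        for i, c in enumerate(self.backbone.channels):
            self.bn_state[f"bn{i}_mean"] = np.zeros(c, dtype=np.float32)
            self.bn_state[f"bn{i}_var"] = np.ones(c, dtype=np.float32)

    def _normalize(self, batch: np.ndarray) -> np.ndarray:
        if self.transform_kind == "standardize" or self.norm_mean is None:
            return batch
        return (batch - self.norm_mean[None, :, None, None]) / self.norm_sd[
            None, :, None, None
        ]

    def forward(
        self,
        batch: np.ndarray,
        train: bool = False,
        dropout: float = 0.0,
        rng: np.random.Generator | None = None,
    ):
        z, caches = self.backbone.forward(
            batch, self.params, self.bn_state, train=train
        )
        z_drop, drop_mask = (
            dropout_forward(z, dropout, rng) if train else (z, None)
        )
        logits = z_drop @ self.params["head_w"] + self.params["head_b"]
        return z, z_drop, drop_mask, logits, caches

    def backward(self, dlogits, z_drop, drop_mask, caches):
        grads = {
            "head_w": z_drop.T @ dlogits,
            "head_b": dlogits.sum(axis=0),
        }
        dz = dlogits @ self.params["head_w"].T
        if drop_mask is not None:
            dz = dz * drop_mask
        grads.update(self.backbone.backward(dz.astype(np.float32), self.params, caches))
        return grads


def extract_dataset(
    points: np.ndarray, stack: RasterStack, patch_size: int, input_mode: str
) -> np.ndarray:
    """Channel-first float32 batch of tensors (or punctual vectors for the
    punctual mode, materialized as constant patches at batch time)."""
    n = len(points)
    n_layers = len(stack)
    if input_mode == "punctual":
        out = np.empty((n, n_layers), dtype=np.float32)
        for i, (x, y) in enumerate(points):
            out[i] = extract_punctual_vector((x, y), stack).values
        return out
    out = np.empty((n, n_layers, patch_size, patch_size), dtype=np.float32)
    for i, (x, y) in enumerate(points):
        tensor = extract_tensor((x, y), stack, patch_size)
        out[i] = tensor.values.transpose(2, 0, 1)
    return out


def _materialize(batch: np.ndarray, patch_size: int) -> np.ndarray:
    """Punctual vectors (n, L) -> constant patches (n, L, P, P)."""
    if batch.ndim == 4:
        return batch
    n, n_layers = batch.shape
    return np.broadcast_to(
        batch[:, :, None, None], (n, n_layers, patch_size, patch_size)
    ).copy()


def train(
    model: SpeciesClassifier,
    occurrences: OccurrenceSet,
    stack: RasterStack,
    config: TrainConfig,
    transform: AblationSpec | str | None = None,
):
    """SGD-with-momentum training with per-access ablation transforms.

    The transform is re-applied to every tensor at every access, in training
    and validation alike.  Validation (mean per-species top-30 accuracy) runs
    every ``validation_period`` epochs and the returned model carries the
    best-scoring checkpoint.  Deterministic under ``config.seed`` up to
    floating-point reduction order.
    """
    spec = as_spec(transform, seed=config.seed)
    model.transform_kind = spec.kind

    label_space = occurrences.species_ids
    label_index = {s: i for i, s in enumerate(label_space)}
    train_df = occurrences.subset("train")
    val_df = occurrences.subset("validation")
    if len(train_df) == 0 or len(val_df) == 0:
        raise ModelError("training and validation partitions must be non-empty")
    unknown = set(val_df["species_id"]) - set(label_index)
    if unknown:
        raise ModelError(f"validation species outside the label space: {unknown}")

    x_train = extract_dataset(
        train_df[["lon", "lat"]].to_numpy(), stack, model.patch_size, model.input_mode
    )
    y_train = np.array([label_index[s] for s in train_df["species_id"]], dtype=int)
    x_val = extract_dataset(
        val_df[["lon", "lat"]].to_numpy(), stack, model.patch_size, model.input_mode
    )
    y_val = np.array([label_index[s] for s in val_df["species_id"]], dtype=int)

    # per-layer standardization statistics from the training split only,
    # applied after the ablation transform (structure-only is exempt: it is
    # already standardized per tensor layer)
    sample = _materialize(x_train, model.patch_size)
    model.norm_mean = sample.mean(axis=(0, 2, 3)).astype(np.float32)
    model.norm_sd = np.maximum(
        sample.std(axis=(0, 2, 3)), 1e-6
    ).astype(np.float32)
    del sample

    rng = np.random.default_rng(config.seed)
    model.label_space = label_space
    model._init_params(len(label_space), rng)
    optimizer = SGDMomentum(
        model.params, momentum=config.momentum, weight_decay=config.weight_decay
    )

    n_train = len(y_train)
    k_val = min(30, len(label_space))
    best_score, best_params = -np.inf, None
    history: list[dict] = []

    for epoch in range(1, config.max_epochs + 1):
        lr = lr_schedule(epoch, config)
        order = rng.permutation(n_train)
        transform_stream = spec.stream(epoch, 0)
        dropout_rng = np.random.default_rng((config.seed, epoch, 1))
        epoch_loss, n_batches = 0.0, 0
        for start in range(0, n_train, config.batch_size):
            idx = order[start : start + config.batch_size]
            xb = _materialize(x_train[idx], model.patch_size)
            xb = apply_batch(spec.kind, xb, transform_stream)
            xb = model._normalize(xb).astype(np.float32)
            z, z_drop, drop_mask, logits, caches = model.forward(
                xb, train=True, dropout=config.dropout, rng=dropout_rng
            )
            probs = softmax(logits.astype(np.float64))
            epoch_loss += cross_entropy(probs, y_train[idx])
            n_batches += 1
            dlogits = probs.copy()
            dlogits[np.arange(len(idx)), y_train[idx]] -= 1.0
            dlogits = (dlogits / len(idx)).astype(np.float32)
            grads = model.backward(dlogits, z_drop, drop_mask, caches)
            optimizer.step(model.params, grads, lr)

        entry = {"epoch": epoch, "loss": epoch_loss / n_batches, "lr": lr}
        if epoch % config.validation_period == 0:
            probs = _predict_probs(model, x_val, spec, stream_context=(epoch, 2))
            ranks = evaluation.compute_ranks(probs, y_val)
            _, msa = evaluation.mean_species_topk(ranks, y_val, k_val)
            entry["val_msa"] = msa
            if msa > best_score:
                best_score = msa
                best_params = {k: v.copy() for k, v in model.params.items()}
        history.append(entry)

    if best_params is not None:
        model.params = best_params
    model.history = history
    model.fitted = True
    return model, history


def _predict_probs(
    model: SpeciesClassifier,
    data: np.ndarray,
    spec: AblationSpec,
    stream_context: tuple[int, ...],
    batch_size: int = 256,
    collect_features: bool = False,
):
    stream = spec.stream(*stream_context)
    zs, logits_all = [], []
    for start in range(0, len(data), batch_size):
        xb = _materialize(data[start : start + batch_size], model.patch_size)
        xb = apply_batch(spec.kind, xb, stream)
        xb = model._normalize(xb).astype(np.float32)
        z, _, _, logits, _ = model.forward(xb, train=False)
        logits_all.append(logits.astype(np.float64))
        if collect_features:
            zs.append(z.astype(np.float64))
    logits = np.concatenate(logits_all, axis=0)
    if collect_features:
        return np.concatenate(zs, axis=0), logits, softmax(logits)
    return softmax(logits)


def predict(
    model: SpeciesClassifier,
    points: np.ndarray,
    stack: RasterStack,
    transform: AblationSpec | str | None = None,
    seed: int = 0,
) -> PredictionBundle:
    """Features, logits and categorical probabilities at each point; sorting
    the probabilities yields the ranked species list."""
    if not model.fitted:
        raise ModelError("model is not fitted")
    spec = as_spec(
        transform if transform is not None else model.transform_kind, seed=seed
    )
    data = extract_dataset(
        np.asarray(points), stack, model.patch_size, model.input_mode
    )
    z, logits, probs = _predict_probs(
        model, data, spec, stream_context=(0, 3), collect_features=True
    )
    return PredictionBundle(
        features=z, logits=logits, probabilities=probs, label_space=model.label_space
    )


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------


def save_checkpoint(model: SpeciesClassifier, path: str) -> None:
    if not model.fitted:
        raise ModelError("cannot checkpoint an unfitted model")
    meta = {
        "n_layers": model.n_layers,
        "patch_size": model.patch_size,
        "channels": list(model.backbone.channels),
        "pool": model.backbone.pool,
        "block_pool": model.backbone.block_pool,
        "input_mode": model.input_mode,
        "transform_kind": model.transform_kind,
        "label_space": [int(s) for s in model.label_space],
        "history": model.history,
    }
    arrays = {f"param_{k}": v for k, v in model.params.items()}
    arrays.update({f"state_{k}": v for k, v in model.bn_state.items()})
    arrays["norm_mean"] = model.norm_mean
    arrays["norm_sd"] = model.norm_sd
    arrays["meta"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_checkpoint(path: str) -> SpeciesClassifier:
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(bytes(data["meta"]).decode())
        model = SpeciesClassifier(
            n_layers=meta["n_layers"],
            patch_size=meta["patch_size"],
            channels=meta["channels"],
            input_mode=meta["input_mode"],
            pool=meta.get("pool", "gap"),
            block_pool=meta.get("block_pool", "avg"),
        )
        model.params = {
            k[len("param_") :]: data[k] for k in data.files if k.startswith("param_")
        }
        model.bn_state = {
            k[len("state_") :]: data[k] for k in data.files if k.startswith("state_")
        }
        model.norm_mean = data["norm_mean"]
        model.norm_sd = data["norm_sd"]
    model.transform_kind = meta["transform_kind"]
    model.label_space = np.asarray(meta["label_space"])
    model.history = meta["history"]
    model.fitted = True
    return model


# ---------------------------------------------------------------------------
# tree baselines over punctual vectors
# ---------------------------------------------------------------------------


class _TreeBaseline:
    """Adapter mapping a scikit-learn classifier onto the full label space."""

    def __init__(self, estimator):
        self.estimator = estimator
        self.label_space: np.ndarray | None = None
        self.fitted = False

    def fit(self, vectors: np.ndarray, labels: np.ndarray, label_space=None):
        labels = np.asarray(labels)
        if np.unique(labels).size < 2:
            raise ModelError("baselines need at least two species in training")
        self.label_space = (
            np.unique(labels) if label_space is None else np.asarray(label_space)
        )
        self.estimator.fit(np.asarray(vectors), labels)
        self.fitted = True
        return self

    def predict_bundle(self, vectors: np.ndarray) -> PredictionBundle:
        if not self.fitted:
            raise ModelError("model is not fitted")
        vectors = np.asarray(vectors)
        raw = self.estimator.predict_proba(vectors)
        probs = np.zeros((len(vectors), len(self.label_space)))
        col = {s: i for i, s in enumerate(self.label_space)}
        for j, cls in enumerate(self.estimator.classes_):
            probs[:, col[cls]] = raw[:, j]
        # trees have no logits: the categorical probabilities double as scores
        return PredictionBundle(
            features=vectors, logits=probs, probabilities=probs,
            label_space=self.label_space,
        )


def fit_rf_baseline(
    vectors: np.ndarray,
    labels: np.ndarray,
    n_trees: int = 100,
    max_depth: int = 16,
    label_space: np.ndarray | None = None,
    seed: int = 0,
) -> _TreeBaseline:
    """Random forest on punctual vectors (100 trees, depth 16 by default)."""
    est = RandomForestClassifier(
        n_estimators=n_trees, max_depth=max_depth, random_state=seed, n_jobs=1
    )
    return _TreeBaseline(est).fit(vectors, labels, label_space)


def fit_bt_baseline(
    vectors: np.ndarray,
    labels: np.ndarray,
    tree_depth: int = 2,
    label_space: np.ndarray | None = None,
    seed: int = 0,
) -> _TreeBaseline:
    """Gradient-boosted trees of depth 2 on punctual vectors."""
    est = HistGradientBoostingClassifier(max_depth=tree_depth, random_state=seed)
    return _TreeBaseline(est).fit(vectors, labels, label_space)
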