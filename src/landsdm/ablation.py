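"""Input-tensor degradations applied identically at train and test time.

Four transforms probe which properties of the environmental neighborhood a
model exploits: ``rotation`` hides orientation, ``permutation`` destroys
spatial structure while keeping each layer's value distribution, ``mean``
keeps only the per-layer average, and ``standardize`` keeps only the spatial
structure (per-layer location and scale are removed).  ``none`` is the
identity.

Randomized transforms are re-drawn at every tensor access from a seeded
stream, so a full run is reproducible while each epoch sees fresh draws.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .raster import EnvironmentalTensor

TRANSFORM_KINDS = ("none", "rotation", "permutation", "mean", "standardize")


class AblationError(ValueError):
    pass


@dataclasses.dataclass
class AblationSpec:
    """A transform token plus the seed of its per-access random stream."""

    kind: str = "none"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in TRANSFORM_KINDS:
            raise AblationError(
                f"unknown transform {self.kind!r}; expected one of {TRANSFORM_KINDS}"
            )

    def stream(self, *context: int) -> np.random.Generator:
        """Deterministic per-context stream (e.g. per epoch, per phase)."""
        return np.random.default_rng((self.seed, *context))


def as_spec(transform: "AblationSpec | str | None", seed: int = 0) -> AblationSpec:
    if transform is None:
        return AblationSpec("none", seed)
    if isinstance(transform, AblationSpec):
        return transform
    return AblationSpec(str(transform), seed)


# ---------------------------------------------------------------------------
# single-tensor operations (patch_size, patch_size, L)
# ---------------------------------------------------------------------------


def rotate_random(
    x: EnvironmentalTensor, stream: np.random.Generator
) -> EnvironmentalTensor:
    """Rotate the whole tensor by one of 0/90/180/270 degrees, drawn
    uniformly; the same rotation is applied to every layer."""
    if x.values.shape[0] != x.values.shape[1]:
        raise AblationError("rotation requires a square patch")
    k = int(stream.integers(4))
    return dataclasses.replace(x, values=np.rot90(x.values, k, axes=(0, 1)).copy())


def permute_random(
    x: EnvironmentalTensor, stream: np.random.Generator
) -> EnvironmentalTensor:
    """Independently permute the pixels of each layer (uniform permutation);
    per-layer value multisets are preserved exactly."""
    p, q, n_layers = x.values.shape
    flat = x.values.reshape(p * q, n_layers).T.copy()  # (L, pixels)
    flat = stream.permuted(flat, axis=1)
    return dataclasses.replace(x, values=flat.T.reshape(p, q, n_layers).copy())


def mean_collapse(x: EnvironmentalTensor) -> EnvironmentalTensor:
    """Replace every layer by its constant spatial mean (idempotent)."""
    means = x.values.mean(axis=(0, 1), keepdims=True)
    return dataclasses.replace(
        x, values=np.broadcast_to(means, x.values.shape).copy()
    )


def standardize_structure(x: EnvironmentalTensor) -> EnvironmentalTensor:
    """Center and scale each layer to mean 0 / population sd 1, keeping only
    its spatial structure; constant layers map to all zeros."""
    means = x.values.mean(axis=(0, 1), keepdims=True)
    sds = x.values.std(axis=(0, 1), keepdims=True)
    out = np.where(sds > 0, (x.values - means) / np.where(sds > 0, sds, 1.0), 0.0)
    return dataclasses.replace(x, values=out)


def apply(
    spec: AblationSpec, x: EnvironmentalTensor, stream: np.random.Generator
) -> EnvironmentalTensor:
    if spec.kind == "none":
        return x
    if spec.kind == "rotation":
        return rotate_random(x, stream)
    if spec.kind == "permutation":
        return permute_random(x, stream)
    if spec.kind == "mean":
        return mean_collapse(x)
    if spec.kind == "standardize":
        return standardize_structure(x)
    raise AblationError(f"unknown transform {spec.kind!r}")


# ---------------------------------------------------------------------------
# batched operations (batch, L, patch, patch) — the training fast path
# ---------------------------------------------------------------------------


def apply_batch(
    kind: str, batch: np.ndarray, stream: np.random.Generator
) -> np.ndarray:
    """Apply a transform to a channel-first batch; returns a new array."""
    if kind == "none":
        return batch
    if kind == "rotation":
        if batch.shape[2] != batch.shape[3]:
            raise AblationError("rotation requires square patches")
        ks = stream.integers(4, size=batch.shape[0])
        out = np.empty_like(batch)
        for k in range(4):
            sel = ks == k
            if sel.any():
                out[sel] = np.rot90(batch[sel], k, axes=(2, 3))
        return out
    if kind == "permutation":
        b, c, h, w = batch.shape
        flat = batch.reshape(b * c, h * w).copy()
        return stream.permuted(flat, axis=1).reshape(b, c, h, w)
    if kind == "mean":
        means = batch.mean(axis=(2, 3), keepdims=True)
        return np.broadcast_to(means, batch.shape).copy()
    if kind == "standardize":
        means = batch.mean(axis=(2, 3), keepdims=True)
        sds = batch.std(axis=(2, 3), keepdims=True)
        safe = np.where(sds > 0, sds, 1.0)
        return np.where(sds > 0, (batch - means) / safe, 0.0).astype(batch.dtype)
    raise AblationError(f"unknown transform {kind!r}")
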