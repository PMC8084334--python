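"""Spatial rendering of learnt features and per-species linear responses.

Last-layer neuron activations are evaluated on a fine grid of quadrat
centers covering the raster domain, then averaged over coarser blocks for
display (the fine/coarse factor is configurable; partial edge blocks average
over the cells they actually contain).
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np

from .ablation import AblationSpec, apply_batch, as_spec
from .models import SpeciesClassifier, _materialize, extract_dataset
from .raster import RasterStack


@dataclasses.dataclass
class ActivationGrid:
    """Fine-grid activations ``(ny, nx, feature_dim)`` with geometry."""

    values: np.ndarray
    origin: tuple[float, float]  # upper-left corner of the fine grid
    resolution: float

    @property
    def feature_dim(self) -> int:
        return self.values.shape[2]

    def neuron(self, i: int) -> np.ndarray:
        return self.values[:, :, i]


def _domain_intersection(stack: RasterStack) -> tuple[float, float, float, float]:
    xmin = max(l.bounds[0] for l in stack)
    ymin = max(l.bounds[1] for l in stack)
    xmax = min(l.bounds[2] for l in stack)
    ymax = min(l.bounds[3] for l in stack)
    if xmin >= xmax or ymin >= ymax:
        raise ValueError("raster layers have no common extent")
    return xmin, ymin, xmax, ymax


def grid_activations(
    model: SpeciesClassifier,
    stack: RasterStack,
    fine_resolution: float,
    transform: AblationSpec | str | None = None,
    seed: int = 0,
    batch_size: int = 256,
) -> ActivationGrid:
    """Evaluate every feature neuron at the center of each quadrat.

    The grid covers the intersection of all layer extents with
    ``floor(extent / fine_resolution)`` cells per axis.
    """
    if not model.fitted:
        raise ValueError("model is not fitted")
    if fine_resolution < min(l.pixel_size for l in stack):
        warnings.warn(
            "quadrat grid finer than the finest raster pixel; adjacent "
            "quadrats will repeat pixel values",
            stacklevel=2,
        )
    xmin, ymin, xmax, ymax = _domain_intersection(stack)
    nx = int((xmax - xmin) // fine_resolution)
    ny = int((ymax - ymin) // fine_resolution)
    xs = xmin + (np.arange(nx) + 0.5) * fine_resolution
    ys = ymax - (np.arange(ny) + 0.5) * fine_resolution
    centers = np.array([(x, y) for y in ys for x in xs])
    spec = as_spec(transform if transform is not None else model.transform_kind, seed)
    data = extract_dataset(centers, stack, model.patch_size, model.input_mode)
    stream = spec.stream(0, 4)
    feats = np.empty((len(centers), model.feature_dim))
    for start in range(0, len(centers), batch_size):
        xb = _materialize(data[start : start + batch_size], model.patch_size)
        xb = apply_batch(spec.kind, xb, stream)
        xb = model._normalize(xb).astype(np.float32)
        z, _, _, _, _ = model.forward(xb, train=False)
        feats[start : start + batch_size] = z
    return ActivationGrid(
        values=feats.reshape(ny, nx, model.feature_dim),
        origin=(xmin, ymax),
        resolution=fine_resolution,
    )


def block_average(fine: np.ndarray, block_factor: int) -> np.ndarray:
    """Mean over ``block_factor``-sized blocks; partial edge blocks are
    averaged over the cells present; NaN cells are ignored."""
    if block_factor < 1:
        raise ValueError("block_factor must be >= 1")
    fine = np.asarray(fine, dtype=float)
    if block_factor == 1:
        return fine.copy()
    ny, nx = fine.shape[:2]
    by = -(-ny // block_factor)
    bx = -(-nx // block_factor)
    out_shape = (by, bx) + fine.shape[2:]
    out = np.empty(out_shape)
    for i in range(by):
        for j in range(bx):
            block = fine[
                i * block_factor : (i + 1) * block_factor,
                j * block_factor : (j + 1) * block_factor,
            ]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", category=RuntimeWarning)
                out[i, j] = np.nanmean(block, axis=(0, 1))
    return out


def species_response_map(
    model: SpeciesClassifier, grid: ActivationGrid, species_id: int
) -> np.ndarray:
    """Linear response ``beta_s . z + alpha_s`` of one species over the grid."""
    head = model.head
    col = int(np.flatnonzero(model.label_space == species_id)[0])
    return grid.values @ head.weights[:, col] + head.intercepts[col]


def render_map(values: np.ndarray, path: str, cmap: str = "viridis") -> None:
    """Save a 2-D map as a PNG with a perceptually uniform colormap."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    im = ax.imshow(values, cmap=cmap)
    fig.colorbar(im, ax=ax, shrink=0.8)
    ax.set_axis_off()
    fig.savefig(path, bbox_inches="tight", dpi=150)
    plt.close(fig)
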