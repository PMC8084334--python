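"""Raster stacks, categorical expansion, nodata filling and tensor extraction.

An environmental variable is a single-band raster with its own geotransform:
layers of one stack may have different pixel sizes, and a patch extracted
around a point therefore covers a different geographic extent on each layer
(always the same *pixel* extent).

Conventions:
  * pixel indexing is 0-based, row-major, origin at the upper-left corner;
  * a geographic point maps to the pixel whose cell contains it;
  * for a patch of even size ``P`` the point's pixel sits at index
    ``(P // 2, P // 2)`` of the patch.
"""

from __future__ import annotations

import dataclasses
import os
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

VARIABLE_KINDS = ("quantitative", "ordinal", "boolean", "categorical")

#: default fraction of the valid range used to push fill values below the
#: valid minimum
DEFAULT_FILL_MARGIN = 0.1

# GeoTIFF tags written alongside the manifest so files stay georeferenced
_MODEL_PIXEL_SCALE_TAG = 33550
_MODEL_TIEPOINT_TAG = 33922


class RasterError(ValueError):
    """Raised on malformed rasters or out-of-bounds extraction requests."""


@dataclasses.dataclass
class RasterLayer:
    """One environmental variable on its own grid.

    Parameters
    ----------
    name:
        Variable name, unique within a stack.
    grid:
        2-D array of values, row-major from the upper-left corner.
    origin:
        ``(x, y)`` geographic coordinate of the grid's upper-left corner.
    pixel_size:
        Ground units per pixel (square pixels).
    kind:
        One of ``quantitative``, ``ordinal``, ``boolean``, ``categorical``.
    nodata_mask:
        Boolean grid flagging undefined pixels; ``None`` means all valid.
    """

    name: str
    grid: np.ndarray
    origin: tuple[float, float]
    pixel_size: float
    kind: str = "quantitative"
    nodata_mask: np.ndarray | None = None
    filled: bool = False
    fill_value_override: float | None = None

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        if self.grid.ndim != 2:
            raise RasterError(f"layer {self.name!r}: grid must be 2-D")
        if self.pixel_size <= 0:
            raise RasterError(f"layer {self.name!r}: pixel_size must be > 0")
        if self.kind not in VARIABLE_KINDS:
            raise RasterError(
                f"layer {self.name!r}: unknown kind {self.kind!r};"
                f" expected one of {VARIABLE_KINDS}"
            )
        if self.nodata_mask is None and np.isnan(self.grid).any():
            self.nodata_mask = np.isnan(self.grid)
        if self.nodata_mask is not None:
            self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
            if self.nodata_mask.shape != self.grid.shape:
                raise RasterError(
                    f"layer {self.name!r}: nodata mask shape mismatch"
                )

    # -- geometry ---------------------------------------------------------

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """``(xmin, ymin, xmax, ymax)`` of the layer extent."""
        nrows, ncols = self.grid.shape
        ox, oy = self.origin
        return (ox, oy - nrows * self.pixel_size, ox + ncols * self.pixel_size, oy)

    def contains(self, x: float, y: float) -> bool:
        xmin, ymin, xmax, ymax = self.bounds
        return (xmin <= x < xmax) and (ymin < y <= ymax)

    def index_of(self, x: float, y: float) -> tuple[int, int]:
        """Row/column of the pixel containing the point."""
        if not self.contains(x, y):
            raise RasterError(
                f"point ({x}, {y}) outside layer {self.name!r} bounds {self.bounds}"
            )
        ox, oy = self.origin
        col = int((x - ox) // self.pixel_size)
        row = int((oy - y) // self.pixel_size)
        nrows, ncols = self.grid.shape
        return min(row, nrows - 1), min(col, ncols - 1)

    # -- values -----------------------------------------------------------

    def valid_values(self) -> np.ndarray:
        if self.nodata_mask is None:
            return self.grid.ravel()
        return self.grid[~self.nodata_mask]

    @property
    def fill_value(self) -> float:
        """Value used for undefined pixels and out-of-grid padding.

        Strictly below the minimum of valid values: ``min - margin * range``
        for a non-constant layer, ``min - 1`` otherwise.
        """
        if self.fill_value_override is not None:
            return self.fill_value_override
        valid = self.valid_values()
        if valid.size == 0:
            raise RasterError(f"layer {self.name!r} has no valid pixel")
        lo, hi = float(valid.min()), float(valid.max())
        if hi == lo:
            return lo - 1.0
        return lo - DEFAULT_FILL_MARGIN * (hi - lo)

    def window(self, row: int, col: int, patch_size: int) -> np.ndarray:
        """``patch_size`` x ``patch_size`` window whose center pixel
        (index ``patch_size // 2``) is ``(row, col)``; parts falling outside
        the grid are padded with the layer fill value."""
        half = patch_size // 2
        r0, c0 = row - half, col - half
        out = np.full((patch_size, patch_size), self.fill_value, dtype=float)
        nrows, ncols = self.grid.shape
        rs, re = max(r0, 0), min(r0 + patch_size, nrows)
        cs, ce = max(c0, 0), min(c0 + patch_size, ncols)
        if rs < re and cs < ce:
            out[rs - r0 : re - r0, cs - c0 : ce - c0] = self.grid[rs:re, cs:ce]
        return out


def fill_undefined(
    layer: RasterLayer, margin_fraction: float = DEFAULT_FILL_MARGIN
) -> RasterLayer:
    """Replace undefined pixels by a sentinel strictly below the valid minimum.

    The sentinel is ``min_valid - margin_fraction * (max_valid - min_valid)``,
    or ``min_valid - 1`` when the layer is constant.  The nodata mask is kept
    for provenance.
    """
    valid = layer.valid_values()
    if valid.size == 0:
        raise RasterError(f"layer {layer.name!r} is entirely undefined")
    lo, hi = float(valid.min()), float(valid.max())
    fill = lo - 1.0 if hi == lo else lo - margin_fraction * (hi - lo)
    if layer.nodata_mask is None or not layer.nodata_mask.any():
        return dataclasses.replace(
            layer, grid=layer.grid.copy(), filled=True, fill_value_override=fill
        )
    grid = layer.grid.copy()
    grid[layer.nodata_mask] = fill
    return dataclasses.replace(
        layer,
        grid=grid,
        nodata_mask=layer.nodata_mask.copy(),
        filled=True,
        fill_value_override=fill,
    )


class RasterStack:
    """Ordered collection of :class:`RasterLayer`."""

    def __init__(self, layers: Iterable[RasterLayer], expanded: bool = False):
        self.layers: list[RasterLayer] = list(layers)
        names = [l.name for l in self.layers]
        if len(set(names)) != len(names):
            raise RasterError("duplicate layer names in stack")
        self.expanded = expanded

    def __len__(self) -> int:
        return len(self.layers)

    def __iter__(self) -> Iterator[RasterLayer]:
        return iter(self.layers)

    def __getitem__(self, key: int | str) -> RasterLayer:
        if isinstance(key, str):
            for layer in self.layers:
                if layer.name == key:
                    return layer
            raise KeyError(key)
        return self.layers[key]

    @property
    def layer_names(self) -> list[str]:
        return [l.name for l in self.layers]

    def fill_all(self, margin_fraction: float = DEFAULT_FILL_MARGIN) -> "RasterStack":
        return RasterStack(
            [fill_undefined(l, margin_fraction) for l in self.layers],
            expanded=self.expanded,
        )

    def prepared(self, margin_fraction: float = DEFAULT_FILL_MARGIN) -> "RasterStack":
        """Categorical expansion followed by nodata filling."""
        stack = self if self.expanded else expand_categorical(self)
        return stack.fill_all(margin_fraction)


def expand_categorical(stack: RasterStack) -> RasterStack:
    """One-hot encode every categorical layer.

    A categorical variable with ``c`` observed classes becomes ``c`` boolean
    layers named ``"<name>=<class>"`` in ascending class order; every valid
    pixel carries exactly one 1 across the derived layers.  Other layers pass
    through unchanged.
    """
    if stack.expanded:
        raise RasterError("stack already expanded")
    out: list[RasterLayer] = []
    for layer in stack:
        if layer.kind != "categorical":
            out.append(layer)
            continue
        valid = layer.valid_values()
        if valid.size == 0:
            raise RasterError(
                f"categorical layer {layer.name!r} has no valid pixel"
            )
        classes = np.unique(valid)
        for cls in classes:
            grid = (layer.grid == cls).astype(float)
            if layer.nodata_mask is not None:
                grid[layer.nodata_mask] = np.nan
            out.append(
                RasterLayer(
                    name=f"{layer.name}={_format_class(cls)}",
                    grid=grid,
                    origin=layer.origin,
                    pixel_size=layer.pixel_size,
                    kind="boolean",
                    nodata_mask=None
                    if layer.nodata_mask is None
                    else layer.nodata_mask.copy(),
                )
            )
    return RasterStack(out, expanded=True)


def _format_class(cls: float) -> str:
    return str(int(cls)) if float(cls).is_integer() else str(cls)


@dataclasses.dataclass
class EnvironmentalTensor:
    """3-D patch ``(patch_size, patch_size, L)`` around one point."""

    values: np.ndarray
    center: tuple[float, float]
    layer_names: list[str]

    @property
    def patch_size(self) -> int:
        return self.values.shape[0]

    @property
    def n_layers(self) -> int:
        return self.values.shape[2]

    def center_pixel(self) -> np.ndarray:
        half = self.patch_size // 2
        return self.values[half, half, :].copy()


@dataclasses.dataclass
class PunctualVector:
    """Environmental values at the exact point, one scalar per layer."""

    values: np.ndarray
    center: tuple[float, float]
    layer_names: list[str]


def extract_tensor(
    point: tuple[float, float], stack: RasterStack, patch_size: int
) -> EnvironmentalTensor:
    """Extract the environmental tensor centered on ``point``.

    Each layer contributes the window of its *native* grid whose center pixel
    contains the point, so the geographic footprint differs between layers of
    different resolution.  Windows overflowing a grid edge are padded with
    that layer's fill value.
    """
    if patch_size < 1:
        raise RasterError("patch_size must be >= 1")
    if not stack.expanded:
        raise RasterError("stack must be expanded before extraction")
    x, y = point
    values = np.empty((patch_size, patch_size, len(stack)), dtype=float)
    for i, layer in enumerate(stack):
        row, col = layer.index_of(x, y)  # raises when out of bounds
        values[:, :, i] = layer.window(row, col, patch_size)
    return EnvironmentalTensor(values=values, center=(x, y), layer_names=stack.layer_names)


def extract_punctual_vector(
    point: tuple[float, float], stack: RasterStack
) -> PunctualVector:
    """Center-pixel value of every layer at ``point``.

    Equals the center pixel of :func:`extract_tensor` for every layer.
    """
    if not stack.expanded:
        raise RasterError("stack must be expanded before extraction")
    x, y = point
    values = np.empty(len(stack), dtype=float)
    for i, layer in enumerate(stack):
        row, col = layer.index_of(x, y)
        values[i] = layer.grid[row, col]
    return PunctualVector(values=values, center=(x, y), layer_names=stack.layer_names)


def vector_to_constant_tensor(
    vector: PunctualVector, patch_size: int
) -> EnvironmentalTensor:
    """Tile each punctual value over a constant ``patch_size`` square layer."""
    values = np.broadcast_to(
        vector.values[None, None, :], (patch_size, patch_size, len(vector.values))
    ).copy()
    return EnvironmentalTensor(
        values=values, center=vector.center, layer_names=list(vector.layer_names)
    )


# ---------------------------------------------------------------------------
# I/O: GeoTIFF + plain-text manifest, occurrence CSV, NPZ debug export
# ---------------------------------------------------------------------------


def write_stack(stack: RasterStack, directory: str, manifest: str = "stack.yml") -> str:
    """Write one GeoTIFF per layer plus a YAML manifest; returns manifest path."""
    os.makedirs(directory, exist_ok=True)
    entries = []
    for layer in stack:
        fname = f"{layer.name.replace('=', '_eq_')}.tif"
        grid = layer.grid.astype(np.float32)
        if layer.nodata_mask is not None and not layer.filled:
            grid = grid.copy()
            grid[layer.nodata_mask] = np.nan
        px = float(layer.pixel_size)
        ox, oy = (float(v) for v in layer.origin)
        tifffile.imwrite(
            os.path.join(directory, fname),
            grid,
            extratags=[
                (_MODEL_PIXEL_SCALE_TAG, "d", 3, (px, px, 0.0)),
                (_MODEL_TIEPOINT_TAG, "d", 6, (0.0, 0.0, 0.0, ox, oy, 0.0)),
            ],
        )
        entries.append(
            {
                "name": layer.name,
                "file": fname,
                "kind": layer.kind,
                "origin": [ox, oy],
                "pixel_size": px,
            }
        )
    manifest_path = os.path.join(directory, manifest)
    with open(manifest_path, "w") as fh:
        yaml.safe_dump({"layers": entries, "expanded": stack.expanded}, fh)
    return manifest_path


def read_stack(manifest_path: str) -> RasterStack:
    """Read a stack from its YAML manifest (NaN pixels become nodata)."""
    with open(manifest_path) as fh:
        spec = yaml.safe_load(fh)
    directory = os.path.dirname(os.path.abspath(manifest_path))
    layers = []
    for entry in spec["layers"]:
        grid = tifffile.imread(os.path.join(directory, entry["file"])).astype(float)
        layers.append(
            RasterLayer(
                name=entry["name"],
                grid=grid,
                origin=tuple(entry["origin"]),
                pixel_size=float(entry["pixel_size"]),
                kind=entry.get("kind", "quantitative"),
            )
        )
    return RasterStack(layers, expanded=bool(spec.get("expanded", False)))


def write_occurrences(records: pd.DataFrame, path: str) -> None:
    cols = ["lon", "lat", "species_id"]
    if "partition" in records.columns:
        cols.append("partition")
    records[cols].to_csv(path, index=False)


def read_occurrences(path: str) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"lon", "lat", "species_id"} - set(df.columns)
    if missing:
        raise RasterError(f"occurrence CSV {path!r} lacks columns {sorted(missing)}")
    return df


def export_tensor_npz(tensor: EnvironmentalTensor, path: str) -> None:
    """Debug export: the patch array plus its layer-name index."""
    np.savez(
        path,
        values=tensor.values,
        center=np.asarray(tensor.center),
        layer_names=np.asarray(tensor.layer_names),
    )


def load_tensor_npz(path: str) -> EnvironmentalTensor:
    with np.load(path, allow_pickle=False) as data:
        return EnvironmentalTensor(
            values=data["values"],
            center=tuple(data["center"]),
            layer_names=[str(n) for n in data["layer_names"]],
        )
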