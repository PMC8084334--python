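"""Synthetic landscapes and presence-only multi-species occurrence sets.

The simulator produces worlds in exactly the formats the extraction module
reads, with species whose occurrence intensity depends either on the value of
the environment at the point itself (``punctual``), on its average over a
neighborhood (``landscape_mean``), or purely on the spatial arrangement of
values in the neighborhood (``landscape_structure``).  Structure-mode species
are, by construction, invisible to punctual predictors: their intensity is
invariant to adding a constant to a layer.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .raster import RasterLayer, RasterStack, expand_categorical

NICHE_MODES = ("punctual", "landscape_mean", "landscape_structure")


class SyntheticError(ValueError):
    pass


# ---------------------------------------------------------------------------
# spatial statistics
# ---------------------------------------------------------------------------


def morans_i(grid: np.ndarray) -> float:
    """Moran's I under rook contiguity (non-toroidal), binary weights."""
    x = np.asarray(grid, dtype=float)
    x = x - x.mean()
    denom = (x * x).sum()
    if denom == 0:
        return 0.0
    sh = (x[:, :-1] * x[:, 1:]).sum()
    sv = (x[:-1, :] * x[1:, :]).sum()
    n_pairs = x[:, :-1].size + x[:-1, :].size
    return float(x.size * (sh + sv) / (n_pairs * denom))


# ---------------------------------------------------------------------------
# layer generators
# ---------------------------------------------------------------------------


def generate_grf_layer(
    shape: tuple[int, int],
    correlation_length: float,
    seed: int,
    name: str = "grf",
    origin: tuple[float, float] | None = None,
    pixel_size: float = 1.0,
    kind: str = "quantitative",
) -> RasterLayer:
    """Zero-mean unit-variance Gaussian random field.

    Synthesis is white noise smoothed by a Gaussian kernel of standard
    deviation ``correlation_length / 2`` (toroidal), then re-standardized;
    ``correlation_length == 0`` yields plain white noise.
    """
    nrows, ncols = shape
    if nrows <= 0 or ncols <= 0:
        raise SyntheticError(f"non-positive grid shape {shape}")
    if correlation_length < 0:
        raise SyntheticError("correlation_length must be >= 0")
    rng = np.random.default_rng(seed)
    field = rng.standard_normal(shape)
    if correlation_length > 0:
        field = ndimage.gaussian_filter(field, sigma=correlation_length / 2.0, mode="wrap")
    field = (field - field.mean()) / field.std()
    if origin is None:
        origin = (0.0, nrows * pixel_size)
    return RasterLayer(
        name=name, grid=field, origin=origin, pixel_size=pixel_size, kind=kind
    )


def generate_categorical_layer(
    shape: tuple[int, int],
    n_classes: int,
    correlation_length: float,
    seed: int,
    name: str = "landcover",
    origin: tuple[float, float] | None = None,
    pixel_size: float = 1.0,
) -> RasterLayer:
    """Contiguous-patch categorical layer from a quantile-thresholded GRF.

    Classes are labelled ``1..n_classes`` and hold equal pixel shares up to
    quantile granularity; every class is present.
    """
    if n_classes < 2:
        raise SyntheticError("n_classes must be >= 2")
    if n_classes > shape[0] * shape[1]:
        raise SyntheticError("n_classes exceeds the pixel count")
    base = generate_grf_layer(
        shape, correlation_length, seed, name=name, origin=origin, pixel_size=pixel_size
    )
    edges = np.quantile(base.grid, np.linspace(0, 1, n_classes + 1)[1:-1])
    classes = 1.0 + np.searchsorted(edges, base.grid, side="left")
    if np.unique(classes).size < n_classes:  # pathological ties in the field
        raise SyntheticError("could not realize every class; increase grid size")
    return RasterLayer(
        name=name,
        grid=classes.astype(float),
        origin=base.origin,
        pixel_size=pixel_size,
        kind="categorical",
    )


# ---------------------------------------------------------------------------
# species niches and intensity surfaces
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class SpeciesNiche:
    """How one species' occurrence intensity depends on the environment.

    ``layer_weights`` maps layer names to coefficients; the weighted per-pixel
    statistic depends on ``mode``:

    * ``punctual`` — the pixel value itself (one channel);
    * ``landscape_mean`` — the mean over a ``(2*window+1)`` square (one
      channel);
    * ``landscape_structure`` — the two signed half-window contrasts per
      layer: ``v`` (mean above the pixel minus mean below) and ``h`` (left
      minus right).  The antisymmetric zero-sum kernels cancel additive
      shifts of the layer and are jointly-Gaussian-independent of the
      pixel's own value and of every symmetric window summary (means,
      variances, histograms), so structure species carry no signal that a
      punctual, layer-averaged or pixel-permuted input could deliver.
      Optional extras: ``pair_weight`` adds a cross-layer
      gradient-alignment term ``m(v_a, v_b) + m(h_a, h_b)``
      (``m(x, y) = |x + y| - |x - y|``) between the first two weighted
      layers, and ``orbit_pool`` replaces the per-layer combination by its
      logsumexp over the four quarter-turn rotations (a niche insensitive
      to orientation).

    Weights may be a scalar (first channel) or one coefficient per channel;
    intensity is ``softplus`` of the combined statistic.
    """

    species_id: int
    mode: str
    layer_weights: dict[str, "float | tuple[float, ...]"]
    window: int = 4
    base_rate: float = 1.0
    intercept: float = 0.0  # negative values threshold the niche, making it
    # occupy only the upper tail of its statistic (sharper concentration)
    pair_weight: float = 0.0  # structure mode: coefficient of the
    # cross-layer gradient-alignment statistic of the first two layers
    orbit_pool: bool = False  # structure mode: pool the weighted contrast
    # over the four quarter-turn rotations (logsumexp), making the niche
    # itself rotation-invariant — a species that keys on an arrangement
    # pattern whatever its orientation

    def __post_init__(self) -> None:
        if self.mode not in NICHE_MODES:
            raise SyntheticError(
                f"unknown niche mode {self.mode!r}; expected one of {NICHE_MODES}"
            )
        if self.base_rate <= 0:
            raise SyntheticError("base_rate must be > 0")
        if self.mode != "punctual" and self.window < 1:
            raise SyntheticError("window must be >= 1 for landscape modes")


def _contrast_kernel(window: int) -> np.ndarray:
    """Antisymmetric detector: +mean of the upper half-block, -mean of the
    lower; orthogonal to every symmetric window summary by construction."""
    size = 2 * window + 1
    kernel = np.zeros((size, size))
    kernel[:window, :] = 1.0 / (window * size)
    kernel[window + 1 :, :] = -1.0 / (window * size)
    return kernel


def _logsumexp(stacked: np.ndarray) -> np.ndarray:
    top = stacked.max(axis=0)
    return top + np.log(np.exp(stacked - top).sum(axis=0))


def _niche_statistic(grid: np.ndarray, mode: str, window: int) -> np.ndarray:
    """Statistic channels, shape (n_channels, H, W)."""
    if mode == "punctual":
        return grid[None]
    if mode == "landscape_mean":
        return ndimage.uniform_filter(grid, size=2 * window + 1, mode="wrap")[None]
    if mode == "landscape_structure":
        kernel = _contrast_kernel(window)
        v = ndimage.correlate(grid, kernel, mode="wrap")
        h = ndimage.correlate(grid, kernel.T, mode="wrap")
        return np.stack([v, h])
    raise SyntheticError(f"unknown niche mode {mode!r}")


def species_intensity(niche: SpeciesNiche, stack: RasterStack) -> RasterLayer:
    """Non-negative occurrence-intensity surface for one species."""
    if not stack.expanded:
        raise SyntheticError("stack must be expanded")
    ref: RasterLayer | None = None
    total: np.ndarray | None = None
    orbit = niche.mode == "landscape_structure" and niche.orbit_pool
    s0 = s1 = None
    for name, weight in niche.layer_weights.items():
        layer = stack[name]
        if ref is None:
            ref = layer
            total = np.zeros(layer.grid.shape)
            if orbit:
                s0 = np.zeros(layer.grid.shape)
                s1 = np.zeros(layer.grid.shape)
        elif layer.grid.shape != ref.grid.shape:
            raise SyntheticError("weighted layers must share a common grid")
        channels = _niche_statistic(layer.grid, niche.mode, niche.window)
        weights = np.atleast_1d(np.asarray(weight, dtype=float))
        if orbit:
            # matched filter at the native orientation and its quarter turn;
            # the other two rotations are their negatives
            a = weights[0]
            b = weights[1] if len(weights) > 1 else 0.0
            v, h = channels[0], channels[1]
            s0 += a * v + b * h
            s1 += a * h - b * v
        else:
            for c, w in zip(channels, weights):
                total += w * c
    if orbit and s0 is not None:
        stacked = np.stack([s0, s1, -s0, -s1])
        total = total + _logsumexp(stacked) - np.log(4.0)
    if ref is None:  # no weighted layer: flat world
        ref = stack[0]
        total = np.zeros(ref.grid.shape)
    if niche.mode == "landscape_structure" and niche.pair_weight != 0.0:
        names = list(niche.layer_weights)
        if len(names) < 2:
            raise SyntheticError("pair_weight needs at least two weighted layers")
        va, ha = _niche_statistic(
            stack[names[0]].grid, niche.mode, niche.window
        )
        vb, hb = _niche_statistic(
            stack[names[1]].grid, niche.mode, niche.window
        )
        alignment = (
            np.abs(va + vb) - np.abs(va - vb) + np.abs(ha + hb) - np.abs(ha - hb)
        )
        total += niche.pair_weight * alignment
    intensity = np.logaddexp(0.0, total + niche.intercept)  # softplus
    return RasterLayer(
        name=f"intensity_{niche.species_id}",
        grid=intensity,
        origin=ref.origin,
        pixel_size=ref.pixel_size,
        kind="quantitative",
    )


# ---------------------------------------------------------------------------
# occurrence sets
# ---------------------------------------------------------------------------

PARTITIONS = ("train", "validation", "test")


class OccurrenceSet:
    """Presence-only records ``(lon, lat, species_id)`` with a partition label."""

    def __init__(self, records: pd.DataFrame):
        records = records.reset_index(drop=True).copy()
        if "partition" not in records.columns:
            records["partition"] = "train"
        self.records = records

    def __len__(self) -> int:
        return len(self.records)

    @property
    def species_ids(self) -> np.ndarray:
        """All species in the set, ascending — the fixed label space."""
        return np.unique(self.records["species_id"].to_numpy())

    def subset(self, partition: str) -> pd.DataFrame:
        if partition not in PARTITIONS:
            raise SyntheticError(f"unknown partition {partition!r}")
        return self.records[self.records["partition"] == partition]

    def counts(self, partition: str | None = None) -> pd.Series:
        df = self.records if partition is None else self.subset(partition)
        return df["species_id"].value_counts()

    def points(self, partition: str | None = None) -> np.ndarray:
        df = self.records if partition is None else self.subset(partition)
        return df[["lon", "lat"]].to_numpy()

    def labels(self, partition: str | None = None) -> np.ndarray:
        df = self.records if partition is None else self.subset(partition)
        return df["species_id"].to_numpy()


def sample_occurrences(
    stack: RasterStack,
    niches: Sequence[SpeciesNiche],
    n_total: int,
    tail_exponent: float,
    seed: int,
) -> OccurrenceSet:
    """Draw a presence-only occurrence set with a long-tail species profile.

    Species counts follow a multinomial with probabilities proportional to
    ``base_rate * rank^(-tail_exponent)`` (rank = 1-based position in
    ``niches``); locations are drawn per species proportionally to
    :func:`species_intensity`, uniformly within the chosen pixel.
    """
    rng = np.random.default_rng(seed)
    ranks = np.arange(1, len(niches) + 1, dtype=float)
    weights = np.array([n.base_rate for n in niches]) * ranks ** (-tail_exponent)
    counts = rng.multinomial(n_total, weights / weights.sum())
    rows = []
    for niche, count in zip(niches, counts):
        if count == 0:
            continue
        layer = species_intensity(niche, stack)
        total = layer.grid.sum()
        if not np.isfinite(total) or total <= 0:
            raise SyntheticError(
                f"species {niche.species_id}: intensity surface is degenerate"
            )
        p = (layer.grid / total).ravel()
        idx = rng.choice(p.size, size=count, p=p)
        r, c = np.unravel_index(idx, layer.grid.shape)
        ox, oy = layer.origin
        u = rng.uniform(0.05, 0.95, size=(count, 2))
        lon = ox + (c + u[:, 0]) * layer.pixel_size
        lat = oy - (r + u[:, 1]) * layer.pixel_size
        for j in range(count):
            rows.append((lon[j], lat[j], niche.species_id))
    df = pd.DataFrame(rows, columns=["lon", "lat", "species_id"])
    df = df.sample(frac=1.0, random_state=np.random.RandomState(seed)).reset_index(
        drop=True
    )
    return OccurrenceSet(df)


def split_occurrences(
    occ: OccurrenceSet,
    test_fraction: float = 0.1,
    validation_fraction: float = 0.1,
    seed: int = 0,
) -> OccurrenceSet:
    """Uniform random partition: test fraction first, then a validation
    fraction of the remaining training records.  No stratification, so a
    rare species' only record may land outside the training split."""
    if not (0 < test_fraction < 1 and 0 < validation_fraction < 1):
        raise SyntheticError("fractions must lie in (0, 1)")
    n = len(occ)
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_test = int(round(n * test_fraction))
    n_val = int(round((n - n_test) * validation_fraction))
    partition = np.full(n, "train", dtype=object)
    partition[order[:n_test]] = "test"
    partition[order[n_test : n_test + n_val]] = "validation"
    records = occ.records.copy()
    records["partition"] = partition
    return OccurrenceSet(records)


# ---------------------------------------------------------------------------
# world presets
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class SyntheticWorld:
    stack: RasterStack  # expanded + filled, ready for extraction
    raw_stack: RasterStack  # pre-expansion, as written to disk
    niches: list[SpeciesNiche]
    occurrences: OccurrenceSet
    seed: int


def build_niches(
    stack: RasterStack,
    n_species: int,
    structure_fraction: float,
    seed: int,
    window: int = 4,
    selectivity: float = 3.0,
    layers_per_species: int = 2,
    punctual_fraction: float | None = None,
    clone_fraction: float = 0.0,
    intercept: float = 0.0,
) -> list[SpeciesNiche]:
    """Random niches over the quantitative layers of an expanded stack.

    The leading ``structure_fraction`` of species are ``landscape_structure``;
    the rest alternate ``punctual`` / ``landscape_mean`` (or are all punctual
    when ``punctual_fraction`` is 1).  Weights are rescaled so the combined
    statistic has standard deviation ``selectivity`` over the landscape,
    keeping species comparably concentrated across modes.

    The trailing ``clone_fraction`` of species — the rarest ranks under a
    long-tail draw — receive lightly perturbed copies of earlier species'
    niches instead of fresh ones, emulating communities where rare species
    share the habitat preferences of common relatives.
    """
    rng = np.random.default_rng(seed)
    quant = [l.name for l in stack if l.kind == "quantitative"]
    if not quant:
        raise SyntheticError("stack has no quantitative layer")
    # statistic channels per (layer, mode) are reused across species
    cache: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]] = {}

    def channels(name: str, mode: str) -> tuple[np.ndarray, np.ndarray]:
        """Standardized statistic channels and their raw sds."""
        key = (name, mode)
        if key not in cache:
            stats = _niche_statistic(stack[name].grid, mode, window)
            sds = stats.reshape(len(stats), -1).std(axis=1)
            sds = np.where(sds > 0, sds, 1.0)
            cache[key] = (stats / sds[:, None, None], sds)
        return cache[key]

    n_clone = int(round(n_species * clone_fraction))
    n_fresh = n_species - n_clone
    n_structure = int(round(n_fresh * structure_fraction))
    niches = []
    for s in range(n_fresh):
        if s < n_structure:
            mode = "landscape_structure"
        elif punctual_fraction is not None and punctual_fraction >= 1.0:
            mode = "punctual"
        else:
            mode = "punctual" if (s - n_structure) % 2 == 0 else "landscape_mean"
        k = min(layers_per_species, len(quant))
        chosen = rng.choice(len(quant), size=k, replace=False)
        combined = np.zeros(stack[quant[0]].grid.shape)
        raw_weights: dict[str, np.ndarray] = {}
        for li in chosen:
            stats, _ = channels(quant[li], mode)
            w = rng.normal(size=len(stats))
            raw_weights[quant[li]] = w
        weights_out: dict[str, float | tuple[float, ...]] = {}
        for name, w in raw_weights.items():
            stats, _ = channels(name, mode)
            combined += np.tensordot(w, stats, axes=(0, 0))
        sd = combined.std()
        scale = selectivity / sd if sd > 0 else 1.0
        # fold the per-channel standardization into the stored weights so
        # the niche stays a pure function of raw layer statistics
        for name, w in raw_weights.items():
            folded = w * scale / channels(name, mode)[1]
            weights_out[name] = (
                float(folded[0]) if len(folded) == 1 else tuple(map(float, folded))
            )
        niches.append(
            SpeciesNiche(
                species_id=s, mode=mode, layer_weights=weights_out, window=window,
                intercept=intercept,
            )
        )
    clone_pool = [i for i in range(n_fresh)
                  if niches[i].mode == "landscape_structure"] or list(range(n_fresh))
    for s in range(n_fresh, n_species):
        src = niches[clone_pool[int(rng.integers(len(clone_pool)))]]
        perturbed = {
            name: tuple(
                float(x * (1.0 + 0.1 * rng.normal()))
                for x in np.atleast_1d(np.asarray(w, dtype=float))
            )
            for name, w in src.layer_weights.items()
        }
        perturbed = {
            n: (v[0] if len(v) == 1 else v) for n, v in perturbed.items()
        }
        niches.append(
            SpeciesNiche(
                species_id=s, mode=src.mode, layer_weights=perturbed,
                window=src.window, intercept=src.intercept,
                pair_weight=src.pair_weight, orbit_pool=src.orbit_pool,
            )
        )
    return niches


def generate_world(
    seed: int,
    grid_size: int = 256,
    n_quantitative: int = 6,
    correlation_lengths: Sequence[float] = (4.0, 8.0, 16.0),
    n_landcover_classes: int = 5,
    landcover_correlation_length: float = 8.0,
    n_species: int = 40,
    structure_fraction: float = 0.5,
    n_occurrences: int = 8000,
    tail_exponent: float = 1.2,
    window: int = 4,
    selectivity: float = 3.0,
    test_fraction: float = 0.1,
    validation_fraction: float = 0.1,
    punctual_fraction: float | None = None,
    clone_fraction: float = 0.0,
    niche_intercept: float = 0.0,
) -> SyntheticWorld:
    """Generate a complete desk-scale world, reproducible under ``seed``."""
    rng = np.random.default_rng(seed)
    shape = (grid_size, grid_size)
    layers = []
    for i in range(n_quantitative):
        cl = correlation_lengths[i % len(correlation_lengths)]
        layers.append(
            generate_grf_layer(
                shape, cl, seed=int(rng.integers(2**31)), name=f"env_{i}"
            )
        )
    layers.append(
        generate_categorical_layer(
            shape, n_landcover_classes,
            correlation_length=landcover_correlation_length,
            seed=int(rng.integers(2**31)),
        )
    )
    raw_stack = RasterStack(layers)
    stack = expand_categorical(raw_stack).fill_all()
    niches = build_niches(
        stack,
        n_species,
        structure_fraction,
        seed=int(rng.integers(2**31)),
        window=window,
        selectivity=selectivity,
        punctual_fraction=punctual_fraction,
        clone_fraction=clone_fraction,
        intercept=niche_intercept,
    )
    occ = sample_occurrences(
        stack, niches, n_occurrences, tail_exponent, seed=int(rng.integers(2**31))
    )
    occ = split_occurrences(
        occ, test_fraction, validation_fraction, seed=int(rng.integers(2**31))
    )
    return SyntheticWorld(
        stack=stack, raw_stack=raw_stack, niches=niches, occurrences=occ, seed=seed
    )
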