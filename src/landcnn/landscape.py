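"""Synthetic landscape predictors, deme layouts, and composite resistance.

The classifier is trained on data simulated over five kinds of spatial
predictor, mirroring a typical landscape-genetics design:

``distance``
    a homogeneous all-ones raster — the isolation-by-distance null, where the
    landscape is featureless and only geographic separation limits gene flow;
``slope``
    a smooth non-negative field (gradient magnitude of a smoothed random
    surface), standing in for terrain steepness that impedes dispersal;
``rivers``
    a flow-accumulation analogue: a small connected set of channel cells with
    values increasing downstream, zero off-channel;
``habitat_shifts``
    21 binary rasters (0 = open habitat / low resistance, 1 = closed / high
    resistance), one per 1000-year epoch from 21 kyr to the present, with
    temporal autocorrelation between consecutive slices;
``niche_suitability``
    7 resistance rasters in [0, 1], one per named late-Quaternary climate
    period, computed as 1 - suitability from autocorrelated smooth fields.

A composite resistance surface is ``1 + sum_k w_k * layer_k`` with per-kind
effect weights ``w_k``; the additive baseline of 1 is the implicit distance
layer, so the IBD model is exactly the zero-weight limit of every
isolation-by-resistance model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .raster import RasterGrid

__all__ = [
    "Deme",
    "DemeSet",
    "LayerStack",
    "PREDICTOR_KINDS",
    "STATIC_KINDS",
    "DYNAMIC_KINDS",
    "HABITAT_EPOCHS_KYR",
    "NICHE_EPOCHS_KYR",
    "generate_deme_layout",
    "generate_layer_stack",
    "composite_resistance",
]

PREDICTOR_KINDS = ("distance", "slope", "rivers", "habitat_shifts", "niche_suitability")
STATIC_KINDS = ("distance", "slope", "rivers")
DYNAMIC_KINDS = ("habitat_shifts", "niche_suitability")

#: 21 one-thousand-year epochs, oldest first: (21, 20) ... (1, 0) kyr.
HABITAT_EPOCHS_KYR: tuple[tuple[float, float], ...] = tuple(
    (float(k), float(k - 1)) for k in range(21, 0, -1)
)

#: Seven late-Quaternary climate periods, oldest first: Last Glacial Maximum,
#: Heinrich Stadial 1, Bolling-Allerod, Younger Dryas, Greenlandian,
#: Northgrippian, Meghalayan (extended to the present so the epochs tile
#: the full 21 kyr window).
NICHE_EPOCHS_KYR: tuple[tuple[float, float], ...] = (
    (21.0, 17.0),
    (17.0, 14.7),
    (14.7, 12.9),
    (12.9, 11.7),
    (11.7, 8.326),
    (8.326, 4.2),
    (4.2, 0.0),
)


@dataclass
class Deme:
    id: int
    x: float
    y: float
    sampled: bool
    n_individuals: int


@dataclass
class DemeSet:
    """Deme localities with sampled-subset flags and per-deme sample sizes."""

    demes: list[Deme]

    def __post_init__(self) -> None:
        ids = [d.id for d in self.demes]
        if ids != list(range(1, len(ids) + 1)):
            raise ValueError("deme ids must be unique and consecutive from 1")
        for d in self.demes:
            if d.sampled and d.n_individuals < 1:
                raise ValueError(f"sampled deme {d.id} must have n_individuals >= 1")

    def __len__(self) -> int:
        return len(self.demes)

    def __iter__(self):
        return iter(self.demes)

    @property
    def n_sampled(self) -> int:
        return sum(d.sampled for d in self.demes)

    @property
    def sampled_ids(self) -> list[int]:
        return [d.id for d in self.demes if d.sampled]

    def coordinates(self) -> np.ndarray:
        return np.array([[d.x, d.y] for d in self.demes])

    def sample_sizes(self) -> dict[int, int]:
        """Per-deme individual counts (0 for unsampled demes)."""
        return {d.id: (d.n_individuals if d.sampled else 0) for d in self.demes}

    def with_sampling(
        self, sampled_ids: Sequence[int], n_individuals: Sequence[int]
    ) -> "DemeSet":
        """Same layout, different sampling design (used by the bias study)."""
        if len(sampled_ids) != len(n_individuals):
            raise ValueError("sampled_ids and n_individuals length mismatch")
        size = dict(zip(sampled_ids, n_individuals))
        return DemeSet(
            demes=[
                Deme(d.id, d.x, d.y, d.id in size, size.get(d.id, 0))
                for d in self.demes
            ]
        )

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            {
                "id": [d.id for d in self.demes],
                "x": [d.x for d in self.demes],
                "y": [d.y for d in self.demes],
                "sampled": [int(d.sampled) for d in self.demes],
                "n_individuals": [d.n_individuals for d in self.demes],
            }
        )
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "DemeSet":
        df = pd.read_csv(path, sep="\t")
        return cls(
            demes=[
                Deme(int(r.id), float(r.x), float(r.y), bool(r.sampled), int(r.n_individuals))
                for r in df.itertuples()
            ]
        )


@dataclass
class LayerStack:
    """An ordered stack of rasters for one predictor kind.

    Static kinds hold one layer; ``habitat_shifts`` holds 21 and
    ``niche_suitability`` 7, each layer paired with its (start_kyr, end_kyr)
    epoch, oldest first.
    """

    kind: str
    layers: list[RasterGrid]
    epoch_years: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.kind not in PREDICTOR_KINDS:
            raise ValueError(f"unknown predictor kind {self.kind!r}")
        if self.kind in STATIC_KINDS and len(self.layers) != 1:
            raise ValueError(f"{self.kind} stack must hold exactly 1 layer")
        if self.kind == "habitat_shifts" and len(self.layers) != 21:
            raise ValueError("habitat_shifts stack must hold 21 layers")
        if self.kind == "niche_suitability" and len(self.layers) != 7:
            raise ValueError("niche_suitability stack must hold 7 layers")
        if not self.epoch_years:
            if self.kind == "habitat_shifts":
                self.epoch_years = list(HABITAT_EPOCHS_KYR)
            elif self.kind == "niche_suitability":
                self.epoch_years = list(NICHE_EPOCHS_KYR)
            else:
                self.epoch_years = [(21.0, 0.0)]
        geom = self.layers[0]
        for lyr in self.layers[1:]:
            if not geom.same_geometry(lyr):
                raise ValueError("all layers in a stack must share grid geometry")

    @property
    def n_layers(self) -> int:
        return len(self.layers)

    def layer_at_kyr(self, kyr: float) -> RasterGrid:
        """The layer whose epoch contains a time point (kyr before present)."""
        if self.kind in STATIC_KINDS:
            return self.layers[0]
        for lyr, (start, end) in zip(self.layers, self.epoch_years):
            if end <= kyr <= start:
                return lyr
        raise ValueError(f"time {kyr} kyr outside the stack's epochs")


def generate_deme_layout(
    n_total: int,
    n_sampled: int,
    extent: RasterGrid,
    sample_size_scheme: Sequence[int],
    seed: int,
) -> DemeSet:
    """Place demes on unmasked raster cells.

    Demes are placed with pairwise separation of at least 2 cells (Chebyshev),
    a random subset of ``n_sampled`` is flagged as genotyped and assigned the
    individual counts in ``sample_size_scheme``.
    """
    if n_sampled > n_total:
        raise ValueError("n_sampled cannot exceed n_total")
    if len(sample_size_scheme) != n_sampled:
        raise ValueError("sample_size_scheme must have n_sampled entries")
    rng = np.random.default_rng(seed)
    rows, cols = np.where(~extent.nodata_mask)
    order = rng.permutation(len(rows))
    placed: list[tuple[int, int]] = []
    for idx in order:
        r, c = int(rows[idx]), int(cols[idx])
        if all(max(abs(r - pr), abs(c - pc)) >= 2 for pr, pc in placed):
            placed.append((r, c))
            if len(placed) == n_total:
                break
    if len(placed) < n_total:
        raise ValueError(
            f"extent too small: placed {len(placed)} of {n_total} demes "
            "with 2-cell separation"
        )
    sampled_idx = set(rng.choice(n_total, size=n_sampled, replace=False).tolist())
    demes: list[Deme] = []
    k = 0
    for i, (r, c) in enumerate(placed):
        x, y = extent.cell_center(r, c)
        if i in sampled_idx:
            demes.append(Deme(i + 1, x, y, True, int(sample_size_scheme[k])))
            k += 1
        else:
            demes.append(Deme(i + 1, x, y, False, 0))
    return DemeSet(demes=demes)


def _smooth_field(shape: tuple[int, int], sigma: float, rng: np.random.Generator) -> np.ndarray:
    noise = rng.standard_normal(shape)
    return ndimage.gaussian_filter(noise, sigma=sigma, mode="reflect")


def _minmax(values: np.ndarray) -> np.ndarray:
    lo, hi = float(values.min()), float(values.max())
    if hi > lo:
        return (values - lo) / (hi - lo)
    return np.clip(values, 0.0, 1.0)


def _river_channels(
    shape: tuple[int, int], n_channels: int, rng: np.random.Generator
) -> np.ndarray:
    """Random-walk channels from the top edge to the bottom edge.

    Each channel accumulates "flow" as it descends, so values increase
    downstream; channels that merge add their accumulation, mimicking a
    flow-accumulation raster.
    """
    n_rows, n_cols = shape
    acc = np.zeros(shape)
    for _ in range(n_channels):
        c = int(rng.integers(0, n_cols))
        flow = 1.0
        for r in range(n_rows):
            acc[r, c] += flow
            flow += 1.0
            step = int(rng.integers(-1, 2))  # down-left, down, down-right
            c = int(np.clip(c + step, 0, n_cols - 1))
    return acc


def generate_layer_stack(
    kind: str,
    grid_spec: RasterGrid,
    params: Mapping[str, float] | None = None,
    seed: int = 0,
) -> LayerStack:
    """Generate a synthetic predictor stack on the geometry of ``grid_spec``.

    Parameters
    ----------
    kind
        One of :data:`PREDICTOR_KINDS`.
    grid_spec
        Template raster supplying shape, cell size, origin, and nodata mask.
    params
        Generator knobs: ``smoothing`` (Gaussian sigma in cells, default 3),
        ``n_channels`` (rivers, default 2), ``closed_fraction`` (habitat,
        default 0.5), ``rho`` (temporal autocorrelation of dynamic stacks,
        default 0.85).
    seed
        Seed for the layer's random field; generation is bit-reproducible.
    """
    params = dict(params or {})
    sigma = float(params.get("smoothing", 3.0))
    rho = float(params.get("rho", 0.85))
    rng = np.random.default_rng(seed)
    shape = grid_spec.shape

    if kind == "distance":
        layers = [grid_spec.copy_with(np.ones(shape))]
    elif kind == "slope":
        surface = _smooth_field(shape, sigma, rng)
        gy, gx = np.gradient(surface)
        layers = [grid_spec.copy_with(_minmax(np.hypot(gx, gy)))]
    elif kind == "rivers":
        n_channels = int(params.get("n_channels", 2))
        acc = _river_channels(shape, n_channels, rng)
        if acc.max() > 0:
            acc = acc / acc.max()
        layers = [grid_spec.copy_with(acc)]
    elif kind in DYNAMIC_KINDS:
        n_slices = 21 if kind == "habitat_shifts" else 7
        closed_fraction = float(params.get("closed_fraction", 0.5))
        latent = _smooth_field(shape, sigma, rng)
        layers = []
        for _ in range(n_slices):
            latent = rho * latent + np.sqrt(1.0 - rho**2) * _smooth_field(shape, sigma, rng)
            if kind == "habitat_shifts":
                thr = np.quantile(latent, 1.0 - closed_fraction)
                layers.append(grid_spec.copy_with((latent > thr).astype(float)))
            else:
                suitability = _minmax(latent)
                layers.append(grid_spec.copy_with(1.0 - suitability))
    else:
        raise ValueError(f"unknown predictor kind {kind!r}")
    return LayerStack(kind=kind, layers=layers)


def _normalize_layer(values: np.ndarray) -> np.ndarray:
    # Layers already on [0,1] (all synthetic generators) pass through
    # unchanged; anything else is min-max rescaled so the effect-weight prior
    # is comparable across predictors.
    lo, hi = float(values.min()), float(values.max())
    if lo >= 0.0 and hi <= 1.0:
        return values
    if hi > lo:
        return (values - lo) / (hi - lo)
    return np.clip(values, 0.0, 1.0)


def composite_resistance(
    layers: Mapping[str, RasterGrid],
    weights: Mapping[str, float],
    template: RasterGrid | None = None,
) -> RasterGrid:
    """Weighted additive composite of predictor layers into one resistance surface.

    ``output = 1 + sum_k weights[k] * normalized(layers[k])`` — the constant 1
    is the implicit distance layer, so with no weighted layers the result is
    the uniform IBD surface.  Every unmasked output cell is therefore >= 1.
    """
    use = {k: v for k, v in layers.items() if k != "distance"}
    if template is None:
        if layers:
            template = next(iter(layers.values()))
        else:
            raise ValueError("composite_resistance needs at least one layer or a template")
    out = np.ones(template.shape)
    for kind, layer in use.items():
        if not template.same_geometry(layer):
            raise ValueError(f"layer {kind!r} geometry does not match")
        if kind not in weights:
            raise ValueError(f"no effect weight supplied for layer {kind!r}")
        out += float(weights[kind]) * _normalize_layer(layer.values)
    return template.copy_with(out)
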