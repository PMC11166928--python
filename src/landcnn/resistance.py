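"""Least-cost resistance distances and migration schedules.

The resistance raster is treated as an 8-connected grid graph: moving between
two adjacent cells costs the mean of their resistances times the step length
(1 for rook moves, sqrt(2) for diagonal moves, in cell units).  The
least-cost (resistance) distance ``x`` between two demes is the minimal
accumulated cost over all paths between their cells.

Each pairwise distance is converted to a per-generation migration rate with a
cubic decay, ``m_ij = d * (1 / x_ij)**3``, where ``d`` is a dispersal scalar;
migration therefore falls off steeply with effective landscape resistance.
(A weaker, squared decay leaves rates so high that simulated data show no
genetic structure.)  Rates are capped so that every row sum stays at or below
0.5 per generation, keeping total emigration probabilities valid.

For models with time-varying predictors the conversion is repeated per epoch,
yielding a :class:`MigrationSchedule` whose epochs tile the full window from
the present back to the ancestral split.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra

from .landscape import DemeSet, LayerStack, composite_resistance
from .models import LandscapeModel
from .raster import RasterGrid

__all__ = [
    "ResistanceDistanceMatrix",
    "MigrationEpoch",
    "MigrationSchedule",
    "least_cost_distances",
    "resistance_to_migration",
    "build_migration_schedule",
    "DEFAULT_ROW_SUM_CAP",
]

DEFAULT_ROW_SUM_CAP = 0.5
_SQRT2 = float(np.sqrt(2.0))


@dataclass
class ResistanceDistanceMatrix:
    """Symmetric least-cost distances among demes, in cell units."""

    deme_ids: list[int]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.deme_ids)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape does not match deme count")

    @property
    def n(self) -> int:
        return len(self.deme_ids)

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.values, index=self.deme_ids, columns=self.deme_ids).to_csv(
            path, sep="\t", index_label="deme"
        )


@dataclass
class MigrationEpoch:
    start_gen: float  # generations before present (younger bound)
    end_gen: float    # generations before present (older bound)
    matrix: np.ndarray


@dataclass
class MigrationSchedule:
    """Ordered epochs of symmetric per-generation migration matrices.

    Epochs are ordered from the present backwards in time and tile
    ``[0, split_gen]`` without gaps.
    """

    epochs: list[MigrationEpoch]
    dispersal: float
    deme_ids: list[int]

    def __post_init__(self) -> None:
        if not self.epochs:
            raise ValueError("schedule must contain at least one epoch")
        t = 0.0
        for ep in self.epochs:
            if not np.isclose(ep.start_gen, t):
                raise ValueError("epochs must tile time without gaps or overlap")
            if ep.end_gen <= ep.start_gen:
                raise ValueError("epoch end must exceed start")
            t = ep.end_gen
            m = ep.matrix
            if not np.allclose(m, m.T):
                raise ValueError("migration matrices must be symmetric")
            if np.any(np.diag(m) != 0):
                raise ValueError("migration matrix diagonal must be zero")
            if np.any(m < 0):
                raise ValueError("migration rates must be non-negative")

    @property
    def n_epochs(self) -> int:
        return len(self.epochs)

    @property
    def split_gen(self) -> float:
        return self.epochs[-1].end_gen

    def to_json_dict(self) -> dict:
        return {
            "dispersal": self.dispersal,
            "deme_ids": self.deme_ids,
            "epochs": [
                {
                    "start_gen": ep.start_gen,
                    "end_gen": ep.end_gen,
                    "matrix": ep.matrix.tolist(),
                }
                for ep in self.epochs
            ],
        }


def _grid_graph(raster: RasterGrid):
    """Sparse 8-connected cost graph over unmasked cells."""
    ok = ~raster.nodata_mask
    vals = raster.values
    if np.any(vals[ok] <= 0):
        raise ValueError("resistance raster must be strictly positive on unmasked cells")
    n_rows, n_cols = raster.shape
    node_id = -np.ones(raster.shape, dtype=np.int64)
    node_id[ok] = np.arange(int(ok.sum()))
    rows_i, cols_i, costs = [], [], []
    # Four forward offsets cover all 8 neighbours once (graph is undirected).
    for dr, dc, step in ((0, 1, 1.0), (1, 0, 1.0), (1, 1, _SQRT2), (1, -1, _SQRT2)):
        r0 = slice(max(0, -dr), n_rows - max(0, dr))
        c0 = slice(max(0, -dc), n_cols - max(0, dc))
        r1 = slice(max(0, dr), n_rows - max(0, -dr))
        c1 = slice(max(0, dc), n_cols - max(0, -dc))
        a, b = node_id[r0, c0], node_id[r1, c1]
        w = 0.5 * (vals[r0, c0] + vals[r1, c1]) * step
        keep = (a >= 0) & (b >= 0)
        rows_i.append(a[keep].ravel())
        cols_i.append(b[keep].ravel())
        costs.append(w[keep].ravel())
    n_nodes = int(ok.sum())
    graph = coo_matrix(
        (np.concatenate(costs), (np.concatenate(rows_i), np.concatenate(cols_i))),
        shape=(n_nodes, n_nodes),
    ).tocsr()
    return graph, node_id


def least_cost_distances(raster: RasterGrid, demes: DemeSet) -> ResistanceDistanceMatrix:
    """Pairwise least-cost distances among all demes over the resistance raster."""
    graph, node_id = _grid_graph(raster)
    sources = []
    for d in demes:
        r, c = raster.cell_index(d.x, d.y)
        if raster.nodata_mask[r, c]:
            raise ValueError(f"deme {d.id} lies on a nodata cell")
        sources.append(int(node_id[r, c]))
    dist = dijkstra(graph, directed=False, indices=sources)
    mat = dist[:, sources]
    mat = 0.5 * (mat + mat.T)  # exact symmetry (dijkstra is symmetric up to fp order)
    np.fill_diagonal(mat, 0.0)
    if not np.all(np.isfinite(mat)):
        i, j = np.argwhere(~np.isfinite(mat))[0]
        raise ValueError(
            f"demes {demes.demes[i].id} and {demes.demes[j].id} are unreachable "
            "(separated by nodata cells)"
        )
    return ResistanceDistanceMatrix(deme_ids=[d.id for d in demes], values=mat)


def resistance_to_migration(
    x: ResistanceDistanceMatrix | np.ndarray,
    dispersal: float,
    row_sum_cap: float | None = DEFAULT_ROW_SUM_CAP,
) -> np.ndarray:
    """Convert resistance distances to per-generation migration rates.

    ``m_ij = dispersal * (1 / x_ij)**3`` off the diagonal.  If the largest row
    sum exceeds ``row_sum_cap``, the whole matrix is rescaled by a single
    factor so every row sum is <= the cap (preserving symmetry and the
    relative migration structure); pass ``row_sum_cap=None`` to disable.
    """
    xv = x.values if isinstance(x, ResistanceDistanceMatrix) else np.asarray(x, dtype=float)
    off = ~np.eye(xv.shape[0], dtype=bool)
    if np.any(xv[off] <= 0):
        raise ValueError("off-diagonal resistance distances must be > 0 (co-located demes?)")
    m = np.zeros_like(xv)
    m[off] = dispersal * (1.0 / xv[off]) ** 3
    if row_sum_cap is not None:
        max_row = float(m.sum(axis=1).max())
        if max_row > row_sum_cap:
            m *= row_sum_cap / max_row
    return m


def build_migration_schedule(
    model: LandscapeModel,
    stacks: Mapping[str, LayerStack],
    weights: Mapping[str, float],
    dispersal: float,
    demes: DemeSet,
    *,
    gens_per_kyr: float = 1000.0,
    split_gen: float = 21_000.0,
    row_sum_cap: float | None = DEFAULT_ROW_SUM_CAP,
) -> MigrationSchedule:
    """Per-epoch migration matrices for one landscape model.

    Static-only models yield a single epoch covering ``[0, split_gen]``;
    models with a dynamic predictor yield one epoch per climate slice (21 for
    habitat shifts, 7 for niche suitability).  Each epoch's matrix is the
    chain composite_resistance -> least_cost_distances ->
    resistance_to_migration on that epoch's layers.
    """
    for p in model.predictors:
        if p not in stacks:
            raise ValueError(f"model {model.id} needs predictor {p!r} missing from stacks")
    if "distance" in stacks:
        template = stacks["distance"].layers[0]
    else:
        template = next(iter(stacks.values())).layers[0]

    static_layers = {
        p: stacks[p].layers[0]
        for p in model.predictors
        if stacks[p].kind in ("slope", "rivers")
    }
    dyn = model.dynamic_predictor
    epochs: list[MigrationEpoch] = []
    if dyn is None:
        surface = composite_resistance(static_layers, weights, template=template)
        x = least_cost_distances(surface, demes)
        m = resistance_to_migration(x, dispersal, row_sum_cap)
        epochs.append(MigrationEpoch(0.0, split_gen, m))
    else:
        stack = stacks[dyn]
        # Layers are stored oldest-first; epochs run from the present backwards.
        for layer, (start_kyr, end_kyr) in zip(
            reversed(stack.layers), reversed(stack.epoch_years)
        ):
            layers = dict(static_layers)
            layers[dyn] = layer
            surface = composite_resistance(layers, weights, template=template)
            x = least_cost_distances(surface, demes)
            m = resistance_to_migration(x, dispersal, row_sum_cap)
            epochs.append(
                MigrationEpoch(end_kyr * gens_per_kyr, start_kyr * gens_per_kyr, m)
            )
        if not np.isclose(epochs[-1].end_gen, split_gen):
            raise ValueError("dynamic stack epochs do not reach the split time")
    return MigrationSchedule(epochs=epochs, dispersal=dispersal, deme_ids=[d.id for d in demes])
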