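import itertools

import networkx as nx
import numpy as np
import pytest

from landcnn.landscape import Deme, DemeSet, generate_layer_stack
from landcnn.models import enumerate_models
from landcnn.raster import RasterGrid
from landcnn.resistance import (
    ResistanceDistanceMatrix,
    build_migration_schedule,
    least_cost_distances,
    resistance_to_migration,
)

SQRT2 = np.sqrt(2.0)


def demes_at_cells(raster, cells):
    demes = []
    for i, (r, c) in enumerate(cells):
        x, y = raster.cell_center(r, c)
        demes.append(Deme(i + 1, x, y, True, 1))
    return DemeSet(demes=demes)


def networkx_oracle(raster, cells):
    """Independent least-cost oracle on the same 8-connected cost convention."""
    g = nx.Graph()
    n_rows, n_cols = raster.shape
    for r, c in itertools.product(range(n_rows), range(n_cols)):
        for dr, dc in ((0, 1), (1, 0), (1, 1), (1, -1)):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < n_rows and 0 <= c2 < n_cols:
                step = SQRT2 if dr and dc else 1.0
                w = 0.5 * (raster.values[r, c] + raster.values[r2, c2]) * step
                g.add_edge((r, c), (r2, c2), weight=w)
    n = len(cells)
    out = np.zeros((n, n))
    for i in range(n):
        lengths = nx.single_source_dijkstra_path_length(g, cells[i])
        for j in range(n):
            out[i, j] = lengths[cells[j]]
    return out


def exhaustive_oracle(raster, a, b):
    """Truly brute-force minimum over every simple 8-connected path."""
    n_rows, n_cols = raster.shape
    best = [np.inf]

    def visit(cell, cost, seen):
        if cost >= best[0]:
            return
        if cell == b:
            best[0] = cost
            return
        r, c = cell
        for dr, dc in itertools.product((-1, 0, 1), repeat=2):
            if dr == dc == 0:
                continue
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < n_rows and 0 <= c2 < n_cols and (r2, c2) not in seen:
                step = SQRT2 if dr and dc else 1.0
                w = 0.5 * (raster.values[r, c] + raster.values[r2, c2]) * step
                visit((r2, c2), cost + w, seen | {(r2, c2)})

    visit(a, 0.0, {a})
    return best[0]


class TestLeastCostDistances:
    def test_uniform_straight_row(self):
        raster = RasterGrid(values=np.ones((8, 8)))
        ds = demes_at_cells(raster, [(3, 1), (3, 6)])
        d = least_cost_distances(raster, ds)
        assert d.values[0, 1] == pytest.approx(5.0)

    def test_exhaustive_enumeration_on_3x3(self):
        rng = np.random.default_rng(8)
        for _ in range(5):
            raster = RasterGrid(values=rng.integers(1, 10, size=(3, 3)).astype(float))
            cells = [(0, 0), (2, 2)]
            d = least_cost_distances(raster, demes_at_cells(raster, cells))
            assert d.values[0, 1] == pytest.approx(
                exhaustive_oracle(raster, cells[0], cells[1])
            )

    def test_matches_independent_dijkstra_on_random_grids(self):
        """50 random <=5x5 integer-resistance grids against networkx."""
        rng = np.random.default_rng(123)
        for _ in range(50):
            n_rows = int(rng.integers(2, 6))
            n_cols = int(rng.integers(2, 6))
            raster = RasterGrid(values=rng.integers(1, 20, size=(n_rows, n_cols)).astype(float))
            k = int(rng.integers(2, 4))
            flat = rng.choice(n_rows * n_cols, size=k, replace=False)
            cells = [(int(f // n_cols), int(f % n_cols)) for f in flat]
            d = least_cost_distances(raster, demes_at_cells(raster, cells))
            assert np.allclose(d.values, networkx_oracle(raster, cells))

    def test_wall_with_gap(self):
        vals = np.ones((7, 7))
        vals[:, 3] = 100.0
        vals[3, 3] = 1.0  # the gap
        raster = RasterGrid(values=vals)
        ds = demes_at_cells(raster, [(0, 0), (0, 6)])
        d = least_cost_distances(raster, ds).values[0, 1]
        unobstructed = 6.0
        straight_through = 5.0 + 0.5 * (1 + 100) + 0.5 * (100 + 1)
        assert unobstructed < d < straight_through
        assert np.allclose(d, networkx_oracle(raster, [(0, 0), (0, 6)])[0, 1])

    def test_monotone_in_cell_resistance(self):
        rng = np.random.default_rng(5)
        raster = RasterGrid(values=rng.uniform(1, 5, size=(6, 6)))
        cells = [(0, 0), (5, 5), (2, 4)]
        base = least_cost_distances(raster, demes_at_cells(raster, cells)).values
        for _ in range(10):
            r, c = rng.integers(0, 6, size=2)
            bumped = raster.copy_with(raster.values.copy())
            bumped.values[r, c] += rng.uniform(0.5, 10)
            after = least_cost_distances(bumped, demes_at_cells(bumped, cells)).values
            assert np.all(after >= base - 1e-12)

    def test_symmetry_and_zero_diagonal(self):
        rng = np.random.default_rng(2)
        raster = RasterGrid(values=rng.uniform(1, 10, size=(9, 9)))
        ds = demes_at_cells(raster, [(0, 0), (4, 7), (8, 2)])
        d = least_cost_distances(raster, ds).values
        assert np.allclose(d, d.T)
        assert np.all(np.diag(d) == 0)

    def test_unreachable_pair_raises(self):
        vals = np.ones((5, 5))
        mask = np.zeros((5, 5), dtype=bool)
        mask[:, 2] = True  # nodata wall
        raster = RasterGrid(values=vals, nodata_mask=mask)
        ds = demes_at_cells(raster, [(0, 0), (0, 4)])
        with pytest.raises(ValueError, match="unreachable"):
            least_cost_distances(raster, ds)


class TestResistanceToMigration:
    def test_printed_equation_values(self):
        x = np.array([[0.0, 1.0], [1.0, 0.0]])
        m = resistance_to_migration(x, dispersal=1.0, row_sum_cap=None)
        assert m[0, 1] == 1.0
        x2 = np.array([[0.0, 2.0], [2.0, 0.0]])
        m2 = resistance_to_migration(x2, dispersal=0.2, row_sum_cap=None)
        assert m2[0, 1] == 0.2 * 0.125

    def test_cubic_scaling_under_doubling(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(1, 10, size=(4, 4))
        x = (x + x.T) / 2
        np.fill_diagonal(x, 0)
        for d in (0.1, 0.23, 0.3):
            m1 = resistance_to_migration(x, d, row_sum_cap=None)
            m2 = resistance_to_migration(2 * x, d, row_sum_cap=None)
            off = ~np.eye(4, dtype=bool)
            assert np.allclose(m2[off] * 8.0, m1[off], rtol=0, atol=0)

    def test_row_sum_cap(self):
        x = np.array([[0.0, 0.5, 0.5], [0.5, 0.0, 0.5], [0.5, 0.5, 0.0]])
        m = resistance_to_migration(x, dispersal=0.3)  # uncapped rates would be 2.4 each
        sums = m.sum(axis=1)
        assert sums.max() == pytest.approx(0.5)
        assert np.allclose(m, m.T)

    def test_colocated_demes_error(self):
        x = np.array([[0.0, 0.0], [0.0, 0.0]])
        with pytest.raises(ValueError, match="co-located"):
            resistance_to_migration(x, 0.2)


@pytest.fixture(scope="module")
def setting():
    grid = RasterGrid(values=np.ones((15, 15)))
    stacks = {
        kind: generate_layer_stack(kind, grid, seed=k)
        for k, kind in enumerate(
            ("distance", "slope", "rivers", "habitat_shifts", "niche_suitability")
        )
    }
    demes = demes_at_cells(grid, [(1, 1), (1, 13), (13, 1), (13, 13), (7, 7)])
    return stacks, demes


class TestMigrationSchedule:

    def test_distance_only_single_epoch(self, setting):
        stacks, demes = setting
        model1 = enumerate_models()[0]
        sched = build_migration_schedule(model1, stacks, {}, 0.2, demes)
        assert sched.n_epochs == 1
        assert sched.split_gen == 21_000.0
        x = least_cost_distances(stacks["distance"].layers[0], demes)
        expect = resistance_to_migration(x, 0.2)
        assert np.allclose(sched.epochs[0].matrix, expect)

    def test_habitat_model_has_21_epochs(self, setting):
        stacks, demes = setting
        model4 = enumerate_models()[3]
        sched = build_migration_schedule(
            model4, stacks, {"habitat_shifts": 3.0}, 0.15, demes
        )
        assert sched.n_epochs == 21
        starts = [ep.start_gen for ep in sched.epochs]
        assert starts == [1000.0 * k for k in range(21)]
        assert sched.epochs[-1].end_gen == 21_000.0

    def test_niche_model_has_7_epochs_and_static_collapse(self, setting):
        """Model 12 (slope+rivers+suitability): zeroing the suitability weight
        must make all 7 epoch matrices identical (only the dynamic layer
        varies across epochs)."""
        stacks, demes = setting
        model12 = enumerate_models()[11]
        weights = {"slope": 2.5, "rivers": 4.0, "niche_suitability": 0.0}
        sched = build_migration_schedule(model12, stacks, weights, 0.2, demes)
        assert sched.n_epochs == 7
        for ep in sched.epochs[1:]:
            assert np.allclose(ep.matrix, sched.epochs[0].matrix)
        # with a nonzero suitability weight the epochs differ
        weights["niche_suitability"] = 4.0
        sched2 = build_migration_schedule(model12, stacks, weights, 0.2, demes)
        assert any(
            not np.allclose(ep.matrix, sched2.epochs[0].matrix)
            for ep in sched2.epochs[1:]
        )

    def test_epochs_tile_21000_generations(self, setting):
        stacks, demes = setting
        for model in (enumerate_models()[3], enumerate_models()[4]):
            w = {p: 2.0 for p in model.predictors}
            sched = build_migration_schedule(model, stacks, w, 0.2, demes)
            t = 0.0
            for ep in sched.epochs:
                assert ep.start_gen == pytest.approx(t)
                t = ep.end_gen
            assert t == pytest.approx(21_000.0)

    def test_missing_predictor_raises(self, setting):
        stacks, demes = setting
        partial = {"distance": stacks["distance"]}
        with pytest.raises(ValueError, match="missing"):
            build_migration_schedule(
                enumerate_models()[1], partial, {"slope": 2.0}, 0.2, demes
            )
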