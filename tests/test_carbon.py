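import itertools

import numpy as np
import pytest

from bluecarbon import (
    CODES,
    CarbonDensityTable,
    GROUPS,
    LULCGrid,
    group_storage,
    jenks_breaks,
    level_map,
    pool_total,
    sequestration,
    total_storage,
)

from conftest import make_random_grid, make_random_series


def exhaustive_jenks(values, k):
    """Independent oracle: try every contiguous partition of the sorted
    values; first (lexicographically smallest breaks) strict minimum wins."""
    vals = sorted(float(v) for v in values)
    n = len(vals)

    def cost(cls):
        m = np.mean(cls)
        return float(sum((v - m) ** 2 for v in cls))

    best, best_cost = None, np.inf
    for breaks in itertools.combinations(range(1, n), k - 1):
        bounds = (0, *breaks, n)
        classes = [vals[bounds[i] : bounds[i + 1]] for i in range(k)]
        c = sum(cost(cls) for cls in classes)
        if c < best_cost - 1e-12:
            best, best_cost = classes, c
    return best


class TestPoolTotal:
    @pytest.mark.parametrize(
        "pools,total",
        [
            ((2.8, 1.8, 13.8, 0.0), 18.4),  # tidal flat
            ((2.5, 11.1, 26.5, 0.2), 40.3),  # grassland
            ((0.0, 0.0, 0.0, 0.0), 0.0),
        ],
    )
    def test_four_pool_sum(self, pools, total):
        assert pool_total(*pools) == pytest.approx(total)

    def test_negative_pool_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            pool_total(-1.0, 0, 0, 0)


class TestDensityTable:
    def test_packaged_table_flags_exactly_three_inconsistent_rows(self, density_table):
        # coastal marsh, paddy field, rainfed cropland
        assert density_table.inconsistent_rows() == [3, 7, 10]

    def test_strict_mode_uses_pool_sums(self):
        strict = CarbonDensityTable.from_csv(strict=True)
        assert strict.density(3) == pytest.approx(26.5 + 10.5 + 26.6 + 0.4)
        assert strict.density(2) == pytest.approx(18.4)

    def test_missing_code_reported(self, density_table):
        with pytest.raises(KeyError):
            density_table.density(12)


class TestStorage:
    def test_one_hectare_examples(self, density_table):
        paddy = LULCGrid(np.array([[7]]), cell_size=100.0)
        assert total_storage(paddy, density_table) == pytest.approx(25.5)
        pair = LULCGrid(np.array([[1, 2]]), cell_size=100.0)
        assert total_storage(pair, density_table) == pytest.approx(32.4)

    def test_all_nodata_is_zero(self, density_table):
        empty = LULCGrid(np.zeros((3, 3), dtype=int), cell_size=100.0)
        assert total_storage(empty, density_table) == 0.0

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_per_cell_brute_force(self, seed, density_table):
        rng = np.random.default_rng(40 + seed)
        g = make_random_grid(seed, (15, 15), 30.0, mask=rng.random((15, 15)) > 0.2)
        expected = sum(
            density_table.density(int(v)) * g.cell_area_ha
            for v in g.cells.ravel()
            if v != 0
        )
        assert total_storage(g, density_table) == pytest.approx(expected, rel=1e-9)

    def test_higher_density_class_never_decreases_storage(self, density_table):
        g = make_random_grid(8, (6, 6))
        base = total_storage(g, density_table)
        cells = g.cells.copy()
        cells[0, 0] = 4  # grassland: the maximum density
        assert total_storage(g.with_cells(cells), density_table) >= base

    def test_group_storage_partitions_total(self, density_table):
        g = make_random_grid(9, (10, 10))
        by_group = group_storage(g, density_table)
        assert set(by_group) == set(GROUPS)
        assert sum(by_group.values()) == pytest.approx(total_storage(g, density_table))

    def test_single_marsh_cell_is_all_natural_wetland(self, density_table):
        g = LULCGrid(np.array([[3]]), cell_size=100.0)
        by_group = group_storage(g, density_table)
        assert by_group["natural wetland"] == pytest.approx(32.4)
        assert sum(v for k, v in by_group.items() if k != "natural wetland") == 0.0


class TestSequestration:
    def test_identical_grids_zero(self, density_table):
        g = make_random_grid(1, (5, 5))
        assert sequestration(g, g.with_cells(g.cells, "b"), density_table) == 0.0

    @pytest.mark.parametrize(
        "code_a,code_b,expected",
        [(1, 2, 18.4 - 14.0), (3, 9, 8.0 - 32.4)],
    )
    def test_single_cell_transitions(self, code_a, code_b, expected, density_table):
        a = LULCGrid(np.array([[code_a]]), cell_size=100.0)
        b = LULCGrid(np.array([[code_b]]), cell_size=100.0)
        assert sequestration(a, b, density_table) == pytest.approx(expected)

    def test_period_sequestration_telescopes(self, density_table):
        series = make_random_series(13)
        per_period = sum(
            sequestration(series[k], series[k + 1], density_table)
            for k in range(len(series) - 1)
        )
        full = sequestration(series[0], series[-1], density_table)
        assert per_period == pytest.approx(full, abs=1e-9)


class TestJenks:
    def test_three_obvious_clusters(self):
        assert jenks_breaks([1, 2, 11, 12, 101, 102], 3) == [
            [1, 2],
            [11, 12],
            [101, 102],
        ]

    def test_k1_is_one_class(self):
        assert jenks_breaks([3, 1, 2], 1) == [[1, 2, 3]]

    def test_k_exceeding_distinct_values_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            jenks_breaks([1, 1, 2], 3)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_exhaustive_search(self, seed):
        rng = np.random.default_rng(200 + seed)
        n = int(rng.integers(5, 13))
        values = np.round(rng.uniform(0, 50, size=n), 1)
        k = int(rng.integers(2, min(5, len(set(values.tolist()))) + 1))
        assert jenks_breaks(values, k) == exhaustive_jenks(values, k)

    def test_packaged_densities_match_exhaustive(self, density_table):
        densities = [density_table.density(c) for c in CODES]
        assert jenks_breaks(densities, 4) == exhaustive_jenks(densities, 4)


class TestLevelMap:
    def test_density_extremes_map_to_outer_levels(self, density_table):
        g = LULCGrid(np.array([[9, 4]]), cell_size=100.0)  # construction, grassland
        levels, legend = level_map(g, density_table)
        assert legend == {1: "Lowest", 2: "Lower", 3: "Higher", 4: "Highest"}
        assert levels[0, 0] == 1  # 8.0 Mg/ha is the minimum density
        assert levels[0, 1] == 4  # 40.3 Mg/ha is the maximum density

    def test_uniform_grid_single_level(self, density_table):
        g = LULCGrid(np.full((4, 4), 7), cell_size=100.0)
        levels, _ = level_map(g, density_table)
        assert len(np.unique(levels)) == 1
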