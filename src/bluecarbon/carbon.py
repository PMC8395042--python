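"""Carbon-stock bookkeeping over LULC maps (InVEST-style pool model).

Each class carries four carbon pools (above-ground, below-ground, soil, dead
organic matter, all Mg/ha); the class density is their sum,

    C_i = C_above + C_below + C_soil + C_dead,

and total storage of a map is the density-weighted class area,

    C_tot = sum_i C_i * S_i   (S_i in ha, C_tot in Mg).

Sequestration over a period is simply later-minus-earlier storage: the model
assumes carbon tracks land cover immediately, with no relaxation toward a new
steady state.

The shipped density table has three rows whose printed total differs from
the pool sum (coastal marsh, paddy field, rainfed cropland). By default the
printed totals drive all storage computations and the inconsistency is
surfaced by :meth:`CarbonDensityTable.inconsistent_rows`; ``strict`` mode
recomputes totals from the pools instead.

Carbon-level maps classify the per-class densities into k ordered levels
("Lowest" .. "Highest") with Fisher-Jenks natural breaks: the contiguous
partition of the sorted values minimizing total within-class sum of squared
deviations.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np

from .lulc import CODES, CODE_GROUPS, GROUPS, NODATA, LULCGrid

LEVEL_NAMES_4 = ("Lowest", "Lower", "Higher", "Highest")

_DEFAULT_TABLE = resources.files("bluecarbon") / "data" / "carbon_density.csv"


def pool_total(c_above: float, c_below: float, c_soil: float, c_dead: float) -> float:
    """Sum the four carbon pools (Mg/ha) into a class density."""
    pools = (c_above, c_below, c_soil, c_dead)
    for p in pools:
        if p < 0:
            raise ValueError(f"negative carbon density {p}")
    return float(sum(pools))


@dataclass(frozen=True)
class CarbonDensityTable:
    """Per-class pool densities and totals, Mg/ha.

    ``strict=False`` (default) uses the table's printed total column in all
    storage computations; ``strict=True`` replaces it with the pool sum.
    """

    pools: dict[int, tuple[float, float, float, float]]
    totals: dict[int, float]
    strict: bool = False

    def __post_init__(self) -> None:
        for code, ps in self.pools.items():
            if any(p < 0 for p in ps) or self.totals.get(code, 0.0) < 0:
                raise ValueError(f"negative density for code {code}")

    @classmethod
    def from_csv(cls, path: str | Path | None = None, strict: bool = False) -> "CarbonDensityTable":
        """Load a table with columns code,name,c_above,c_below,c_soil,c_dead,c_total.
        ``path=None`` loads the packaged coastal table."""
        opener = open(path) if path is not None else _DEFAULT_TABLE.open()
        with opener as fh:
            rows = list(csv.DictReader(fh))
        pools = {}
        totals = {}
        for r in rows:
            code = int(r["code"])
            pools[code] = (
                float(r["c_above"]),
                float(r["c_below"]),
                float(r["c_soil"]),
                float(r["c_dead"]),
            )
            totals[code] = float(r["c_total"])
        return cls(pools=pools, totals=totals, strict=strict)

    def density(self, code: int) -> float:
        """Effective class density (Mg/ha) under the table's mode."""
        if code not in self.totals:
            raise KeyError(f"code {code} missing from carbon density table")
        if self.strict:
            return pool_total(*self.pools[code])
        return self.totals[code]

    def density_vector(self) -> np.ndarray:
        """Densities indexed by code-1, for vectorized per-cell lookups."""
        return np.array([self.density(c) for c in sorted(self.totals)])

    def inconsistent_rows(self, atol: float = 1e-9) -> list[int]:
        """Codes whose printed total differs from the four-pool sum."""
        return [
            c
            for c in sorted(self.totals)
            if abs(pool_total(*self.pools[c]) - self.totals[c]) > atol
        ]


# ---------------------------------------------------------------------------
# storage and sequestration
# ---------------------------------------------------------------------------


def _density_lut(table: CarbonDensityTable) -> np.ndarray:
    """Density lookup by raw code value; nodata slot is 0."""
    codes = sorted(table.totals)
    lut = np.zeros(max(codes) + 1)
    for c in codes:
        lut[c] = table.density(c)
    return lut


def carbon_map(grid: LULCGrid, table: CarbonDensityTable) -> np.ndarray:
    """Per-cell carbon storage (Mg): class density x cell area in ha.
    Nodata cells hold 0."""
    present = np.unique(grid.cells[grid.mask])
    missing = [int(c) for c in present if c not in table.totals]
    if missing:
        raise KeyError(f"codes {missing} missing from carbon density table")
    return _density_lut(table)[grid.cells] * grid.cell_area_ha


def total_storage(grid: LULCGrid, table: CarbonDensityTable) -> float:
    """Total carbon storage of a map (Mg)."""
    return float(carbon_map(grid, table).sum())


def sequestration(grid_a: LULCGrid, grid_b: LULCGrid, table: CarbonDensityTable) -> float:
    """Net carbon change later-minus-earlier (Mg); negative is a loss."""
    if not grid_a.congruent_with(grid_b):
        raise ValueError("grids are not congruent")
    return total_storage(grid_b, table) - total_storage(grid_a, table)


def sequestration_map(grid_a: LULCGrid, grid_b: LULCGrid, table: CarbonDensityTable) -> np.ndarray:
    """Per-cell carbon change (Mg) between two dates."""
    if not grid_a.congruent_with(grid_b):
        raise ValueError("grids are not congruent")
    return carbon_map(grid_b, table) - carbon_map(grid_a, table)


def group_storage(grid: LULCGrid, table: CarbonDensityTable) -> dict[str, float]:
    """Storage split by summary group; the four values sum to total storage."""
    cm = carbon_map(grid, table)
    out = {g: 0.0 for g in GROUPS}
    for code in CODES:
        out[CODE_GROUPS[code]] += float(cm[grid.cells == code].sum())
    return out


# ---------------------------------------------------------------------------
# Fisher-Jenks natural breaks
# ---------------------------------------------------------------------------


def jenks_breaks(values: Sequence[float], k: int) -> list[list[float]]:
    """Partition values into k contiguous classes of the sorted order,
    minimizing the total within-class sum of squared deviations.

    Classic Fisher-Jenks dynamic program, O(k n²) with prefix sums. Among
    equal-cost partitions the one whose break indices are lexicographically
    smallest (leftmost breaks) is returned, which makes the result
    deterministic. Returns the k classes as lists of the sorted values.
    """
    vals = sorted(float(v) for v in values)
    n = len(vals)
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if k > len(set(vals)):
        raise ValueError(
            f"k={k} exceeds the number of distinct values ({len(set(vals))})"
        )
    pref = np.concatenate([[0.0], np.cumsum(vals)])
    pref2 = np.concatenate([[0.0], np.cumsum(np.square(vals))])

    def ssd(i: int, j: int) -> float:
        # within-class sum of squared deviations of vals[i:j]
        m = j - i
        s = pref[j] - pref[i]
        return float(pref2[j] - pref2[i] - s * s / m)

    # suffix[m][i] = min cost of splitting vals[i:] into m classes; greedy
    # forward reconstruction then yields the lexicographically smallest
    # (leftmost) break indices among equal-cost optima
    suffix = np.full((k + 1, n + 1), np.inf)
    suffix[0, n] = 0.0
    for m in range(1, k + 1):
        for i in range(n - m, -1, -1):
            best = np.inf
            for j in range(i + 1, n - m + 2):
                c = ssd(i, j) + suffix[m - 1, j]
                if c < best:
                    best = c
            suffix[m, i] = best
    classes: list[list[float]] = []
    i = 0
    for m in range(k, 0, -1):
        target = suffix[m, i]
        for j in range(i + 1, n - m + 2):
            c = ssd(i, j) + suffix[m - 1, j]
            if c <= target + 1e-9 * max(1.0, abs(target)):
                classes.append(vals[i:j])
                i = j
                break
    return classes


def jenks_class_of(value: float, classes: list[list[float]]) -> int:
    """0-based index of the Jenks class containing ``value`` (classes are
    ordered low to high; membership by class upper bound)."""
    for idx, cls in enumerate(classes[:-1]):
        if value <= cls[-1]:
            return idx
    return len(classes) - 1


def level_map(
    grid: LULCGrid, table: CarbonDensityTable, k: int = 4
) -> tuple[np.ndarray, dict[int, str]]:
    """Label each cell 1..k by the Jenks class of its class density.

    Levels are ordered by density (1 = lowest). Returns the integer raster
    (0 on nodata) and a legend mapping level -> name; for k=4 the names are
    Lowest/Lower/Higher/Highest.
    """
    densities = [table.density(c) for c in CODES]
    classes = jenks_breaks(densities, k)
    code_level = {c: jenks_class_of(table.density(c), classes) + 1 for c in CODES}
    lut = np.zeros(max(CODES) + 1, dtype=np.int64)
    for c, lvl in code_level.items():
        lut[c] = lvl
    if k == 4:
        legend = {i + 1: LEVEL_NAMES_4[i] for i in range(4)}
    else:
        legend = {i + 1: f"Level {i + 1}" for i in range(k)}
    return lut[grid.cells], legend
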