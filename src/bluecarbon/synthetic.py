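"""Synthetic coastal LULC series with the dynamics the analysis assumes.

The generator emulates an accreting shoreline: date 0 is a land-sea gradient
(an inshore strip of paddy/construction/cropland, then coastal marsh, then
tidal flat, then offshore water seaward). Each subsequent date applies, in a
fixed order, the six driving processes as per-cell Bernoulli moves:

1. accretion      — water (1) next to non-water turns to tidal flat (2)
2. succession     — 2->3 and 3->4
3. regressive succession — 3->2
4. erosion        — 2/3/4 next to water revert to 1
5. reclamation    — any of 1-5 within reach of the initial land edge turns
                    into a draw from {6,7,8,9,10}
6. restoration    — any of 6-10 reverts to tidal flat or marsh

A cell changes at most once per interval (each process skips cells already
moved this interval), mirroring one process step per mapped period. All
draws come from one seeded generator consumed in raster row-major order, so
a scenario is bit-reproducible.

``materialize_from_matrix`` goes the other way: it lays out a pair of grids
that exactly realize a printed area transition matrix, which turns published
tables into test fixtures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .lulc import NODATA, LULCGrid, LULCSeries
from .transitions import TransitionMatrix

RECLAMATION_CODES = (6, 7, 8, 9, 10)

_DEFAULT_RATES = {
    "accretion": 0.35,
    "succession": 0.25,
    "regressive_succession": 0.03,
    "erosion": 0.05,
    "reclamation": 0.08,
    "restoration": 0.02,
}
# mix of pond/paddy/reservoir/construction/cropland conversions; ponds and
# paddy dominate reclamation on this kind of coast
_DEFAULT_TARGETS = {6: 0.30, 7: 0.25, 8: 0.10, 9: 0.15, 10: 0.20}


@dataclass(frozen=True)
class CoastScenario:
    """Configuration of one synthetic coastal run.

    rates
        Per-interval move probabilities in [0,1] for the six processes,
        keyed accretion / succession / regressive_succession / erosion /
        reclamation / restoration.
    reclamation_targets
        Distribution over codes 6-10 for reclaimed cells; must sum to 1.
    reclamation_reach
        Max column distance from the initial land edge within which
        reclamation operates (human conversion hugs the shore).
    """

    shape: tuple[int, int] = (60, 80)
    cell_size: float = 100.0
    n_dates: int = 4
    rates: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_RATES))
    reclamation_targets: dict[int, float] = field(
        default_factory=lambda: dict(_DEFAULT_TARGETS)
    )
    reclamation_reach: int = 25
    seed: int = 0
    date_labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.shape[1] < 3:
            raise ValueError(f"degenerate shape {self.shape}: need >= 3 columns")
        if self.n_dates < 2:
            raise ValueError("n_dates must be >= 2")
        for k in _DEFAULT_RATES:
            if k not in self.rates:
                raise ValueError(f"missing rate {k!r}")
            if not 0.0 <= self.rates[k] <= 1.0:
                raise ValueError(f"rate {k}={self.rates[k]} outside [0, 1]")
        tot = sum(self.reclamation_targets.values())
        if abs(tot - 1.0) > 1e-9:
            raise ValueError(f"reclamation_targets sum to {tot}, expected 1")
        if any(c not in RECLAMATION_CODES for c in self.reclamation_targets):
            raise ValueError("reclamation_targets keys must be in 6..10")

    def labels(self) -> tuple[str, ...]:
        if self.date_labels is not None:
            if len(self.date_labels) != self.n_dates:
                raise ValueError("date_labels length != n_dates")
            return self.date_labels
        return tuple(f"t{k}" for k in range(self.n_dates))


def _initial_grid(scenario: CoastScenario, rng: np.random.Generator) -> np.ndarray:
    """Land-sea gradient: land strip | marsh band | tidal-flat band | water."""
    rows, cols = scenario.shape
    land_w = max(1, cols // 6)
    marsh_w = max(1, cols // 6)
    flat_w = max(1, cols // 6)
    grid = np.full((rows, cols), 1, dtype=np.int64)
    land_codes = rng.choice([7, 9, 10], size=(rows, land_w))
    grid[:, :land_w] = land_codes
    grid[:, land_w : land_w + marsh_w] = 3
    grid[:, land_w + marsh_w : land_w + marsh_w + flat_w] = 2
    return grid


def _adjacent_to(cells: np.ndarray, predicate: np.ndarray) -> np.ndarray:
    """4-neighbourhood: True where at least one N/S/E/W neighbour satisfies
    the predicate mask."""
    adj = np.zeros(cells.shape, dtype=bool)
    adj[1:, :] |= predicate[:-1, :]
    adj[:-1, :] |= predicate[1:, :]
    adj[:, 1:] |= predicate[:, :-1]
    adj[:, :-1] |= predicate[:, 1:]
    return adj


def _apply_interval(
    cells: np.ndarray,
    scenario: CoastScenario,
    rng: np.random.Generator,
    land_edge_col: int,
) -> np.ndarray:
    """One interval of coastal dynamics; each cell moves at most once."""
    rows, cols = cells.shape
    out = cells.copy()
    moved = np.zeros(cells.shape, dtype=bool)
    valid = cells != NODATA
    rates = scenario.rates

    def draw(eligible: np.ndarray, rate: float) -> np.ndarray:
        # one uniform per raster cell in row-major order keeps the stream
        # layout-independent of how many cells are eligible
        u = rng.random(cells.shape)
        return eligible & ~moved & (u < rate)

    # 1. accretion: water adjacent to non-water becomes tidal flat
    nonwater = valid & (cells != 1)
    hit = draw((cells == 1) & _adjacent_to(cells, nonwater), rates["accretion"])
    out[hit] = 2
    moved |= hit

    # 2. succession: 2->3, 3->4
    hit = draw(cells == 2, rates["succession"])
    out[hit] = 3
    moved |= hit
    hit = draw(cells == 3, rates["succession"])
    out[hit] = 4
    moved |= hit

    # 3. regressive succession: 3->2
    hit = draw(cells == 3, rates["regressive_succession"])
    out[hit] = 2
    moved |= hit

    # 4. erosion: flats/marsh/grassland adjacent to water revert to water
    water = valid & (cells == 1)
    erodible = np.isin(cells, (2, 3, 4)) & _adjacent_to(cells, water)
    hit = draw(erodible, rates["erosion"])
    out[hit] = 1
    moved |= hit

    # 5. reclamation: water/wetland near the initial land edge -> 6..10
    cols_idx = np.arange(cols)[None, :]
    near_shore = cols_idx <= land_edge_col + scenario.reclamation_reach
    hit = draw(np.isin(cells, (1, 2, 3, 4, 5)) & near_shore, rates["reclamation"])
    targets = sorted(scenario.reclamation_targets)
    probs = [scenario.reclamation_targets[t] for t in targets]
    choice = rng.choice(targets, size=cells.shape, p=probs)
    out[hit] = choice[hit]
    moved |= hit

    # 6. restoration: artificial/other classes revert to flat or marsh
    hit = draw(np.isin(cells, RECLAMATION_CODES), rates["restoration"])
    restored = rng.choice([2, 3], size=cells.shape)
    out[hit] = restored[hit]

    return out


def apply_interval(
    grid: LULCGrid,
    scenario: CoastScenario,
    rng: np.random.Generator,
    land_edge_col: int = 0,
) -> LULCGrid:
    """Advance an arbitrary grid by one interval of the scenario's dynamics
    (useful for studying a single process from a chosen initial state)."""
    return grid.with_cells(_apply_interval(grid.cells, scenario, rng, land_edge_col))


def generate_series(scenario: CoastScenario) -> LULCSeries:
    """Run the scenario and return its dated series.

    Same scenario + seed is bit-identical; different seeds give different
    series (with overwhelming probability at non-trivial rates).
    """
    rng = np.random.default_rng(scenario.seed)
    labels = scenario.labels()
    cells = _initial_grid(scenario, rng)
    land_edge_col = max(1, scenario.shape[1] // 6) - 1
    grids = [
        LULCGrid(cells, cell_size=scenario.cell_size, date_label=labels[0])
    ]
    for k in range(1, scenario.n_dates):
        cells = _apply_interval(cells, scenario, rng, land_edge_col)
        grids.append(
            LULCGrid(cells, cell_size=scenario.cell_size, date_label=labels[k])
        )
    return LULCSeries(grids)


def single_process_scenario(process: str, rate: float = 0.3, **kwargs) -> CoastScenario:
    """Scenario in which only one named process has a nonzero rate."""
    rates = {k: 0.0 for k in _DEFAULT_RATES}
    if process not in rates:
        raise ValueError(f"unknown process {process!r}")
    rates[process] = rate
    return CoastScenario(rates=rates, **kwargs)


def materialize_from_matrix(
    matrix: TransitionMatrix,
    cell_size: float = 100.0,
    period: tuple[str, str] = ("start", "end"),
) -> tuple[LULCGrid, LULCGrid]:
    """Build a congruent grid pair that exactly realizes an area matrix.

    Every entry must be a non-negative integer multiple of the cell area
    (100 m cells make any 0.01-km²-precision table integral). The spatial
    layout is arbitrary row-major fill — only the cross-tabulation matters.
    Recomputing the transition matrix of the returned pair reproduces the
    input exactly.
    """
    cell_km2 = cell_size**2 / 1e6
    counts = np.zeros(matrix.areas.shape, dtype=np.int64)
    for i in range(matrix.areas.shape[0]):
        for j in range(matrix.areas.shape[1]):
            area = matrix.areas[i, j]
            n = round(area / cell_km2)
            if abs(n * cell_km2 - area) > 1e-6:
                raise ValueError(
                    f"area {area} km² for transition {i + 1}->{j + 1} is not an "
                    f"integer multiple of the cell area {cell_km2} km²"
                )
            counts[i, j] = n
    total = int(counts.sum())
    if total == 0:
        empty = np.zeros((1, 1), dtype=np.int64)
        return (
            LULCGrid(empty, cell_size=cell_size, date_label=period[0]),
            LULCGrid(empty, cell_size=cell_size, date_label=period[1]),
        )
    cols = int(np.ceil(np.sqrt(total)))
    rows_n = int(np.ceil(total / cols))
    a = np.full(rows_n * cols, NODATA, dtype=np.int64)
    b = np.full(rows_n * cols, NODATA, dtype=np.int64)
    pos = 0
    for i in range(counts.shape[0]):
        for j in range(counts.shape[1]):
            n = counts[i, j]
            a[pos : pos + n] = i + 1
            b[pos : pos + n] = j + 1
            pos += n
    shape = (rows_n, cols)
    return (
        LULCGrid(a.reshape(shape), cell_size=cell_size, date_label=period[0]),
        LULCGrid(b.reshape(shape), cell_size=cell_size, date_label=period[1]),
    )
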