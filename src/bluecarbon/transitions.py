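"""Period transition matrices between two LULC maps, with transfer marginals.

``areas[i-1, j-1]`` is the area (km²) of cells coded ``i`` at the start date
and ``j`` at the end date; the diagonal is the unchanged area. Marginals
follow the change-matrix convention: transfer-out of class i is its row sum
excluding the diagonal, transfer-in of class j its column sum excluding the
diagonal. Areas are exact underneath (integer cell counts scaled by the cell
area); rounding to 0.01 km² happens only at serialization.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .lulc import CODES, CODE_NAMES, NODATA, LULCGrid

_N = len(CODES)
_OUT_LABEL = "Transfer-Out Area"
_IN_LABEL = "Transfer-in area"


@dataclass(frozen=True)
class TransitionMatrix:
    """10x10 start-class x end-class area matrix (km²) for one period."""

    areas: np.ndarray
    period: tuple[str, str] = ("", "")
    cell_size: float | None = None

    def __post_init__(self) -> None:
        areas = np.asarray(self.areas, dtype=float)
        if areas.shape != (_N, _N):
            raise ValueError(f"areas must be {_N}x{_N}, got {areas.shape}")
        if (areas < 0).any():
            i, j = map(int, np.argwhere(areas < 0)[0])
            raise ValueError(
                f"negative area {areas[i, j]} for transition {i + 1}->{j + 1}"
            )
        object.__setattr__(self, "areas", areas)

    @property
    def total_area_km2(self) -> float:
        return float(self.areas.sum())

    @property
    def changed_area_km2(self) -> float:
        return float(self.areas.sum() - np.trace(self.areas))

    def transfer_out(self, code: int) -> float:
        """Row sum excluding the diagonal: area lost by ``code`` (km²)."""
        _check_code(code)
        i = code - 1
        return float(self.areas[i].sum() - self.areas[i, i])

    def transfer_in(self, code: int) -> float:
        """Column sum excluding the diagonal: area gained by ``code`` (km²)."""
        _check_code(code)
        j = code - 1
        return float(self.areas[:, j].sum() - self.areas[j, j])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TransitionMatrix):
            return NotImplemented
        return self.period == other.period and np.allclose(
            self.areas, other.areas, rtol=0, atol=1e-9
        )


def _check_code(code: int) -> None:
    if code not in CODES:
        raise ValueError(f"invalid LULC code {code!r}: expected 1..10")


def transition_matrix(grid_a: LULCGrid, grid_b: LULCGrid) -> TransitionMatrix:
    """Cross-tabulate two congruent maps into an area transition matrix.

    Both grids must share shape/cell size/origin and have identical nodata
    masks; nodata cells are excluded, so the matrix total equals the mapped
    study area and is conserved across the periods of one series.
    """
    if not grid_a.congruent_with(grid_b):
        raise ValueError(
            f"grids are not congruent: {grid_a.shape}/{grid_a.cell_size} vs "
            f"{grid_b.shape}/{grid_b.cell_size}"
        )
    if not np.array_equal(grid_a.mask, grid_b.mask):
        raise ValueError("nodata masks differ between the two dates")
    a = grid_a.cells[grid_a.mask]
    b = grid_b.cells[grid_a.mask]
    counts = np.bincount((a - 1) * _N + (b - 1), minlength=_N * _N).reshape(_N, _N)
    return TransitionMatrix(
        counts * grid_a.cell_area_km2,
        period=(grid_a.date_label, grid_b.date_label),
        cell_size=grid_a.cell_size,
    )


def series_transition_matrices(series) -> list[TransitionMatrix]:
    """Consecutive-period matrices plus the full first-to-last matrix."""
    mats = [
        transition_matrix(series[k], series[k + 1]) for k in range(len(series) - 1)
    ]
    if len(series) > 2:
        mats.append(transition_matrix(series[0], series[-1]))
    return mats


def write_matrix_csv(matrix: TransitionMatrix, path: str | Path) -> Path:
    """Write the change-matrix layout: one row per start class, a trailing
    transfer-out column, and a final transfer-in row. Values print with two
    decimals (0.01 km²)."""
    path = Path(path)
    names = [CODE_NAMES[c] for c in CODES]
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["from\\to", *names, _OUT_LABEL])
        for i, c in enumerate(CODES):
            row = [f"{matrix.areas[i, j]:.2f}" for j in range(_N)]
            w.writerow([names[i], *row, f"{matrix.transfer_out(c):.2f}"])
        w.writerow(
            [_IN_LABEL, *[f"{matrix.transfer_in(c):.2f}" for c in CODES], ""]
        )
    return path


def read_matrix_csv(path: str | Path, period: tuple[str, str] = ("", "")) -> TransitionMatrix:
    """Read a matrix written by :func:`write_matrix_csv` (or the packaged
    printed tables). Only the 10x10 body is used; marginals are recomputed.
    Negative entries raise ``ValueError``."""
    path = Path(path)
    with open(path) as fh:
        rows = list(csv.reader(fh))
    if not rows or len(rows[0]) < _N + 1:
        raise ValueError(f"{path}: malformed matrix CSV")
    header = rows[0][1 : _N + 1]
    name_to_code = {name: code for code, name in CODE_NAMES.items()}
    try:
        col_codes = [name_to_code[h] for h in header]
    except KeyError as e:
        raise ValueError(f"{path}: unknown class column {e.args[0]!r}") from None
    areas = np.zeros((_N, _N))
    seen = 0
    for row in rows[1:]:
        if not row or row[0] == _IN_LABEL:
            continue
        if row[0] not in name_to_code:
            raise ValueError(f"{path}: unknown class row {row[0]!r}")
        i = name_to_code[row[0]] - 1
        for col_idx, code in enumerate(col_codes):
            v = float(row[1 + col_idx])
            if v < 0:
                raise ValueError(
                    f"{path}: negative area {v} at row {row[0]!r}, "
                    f"column {CODE_NAMES[code]!r}"
                )
            areas[i, code - 1] = v
        seen += 1
    if seen != _N:
        raise ValueError(f"{path}: expected {_N} class rows, found {seen}")
    return TransitionMatrix(areas, period=period)


PRINTED_PERIODS = ("1990_2000", "2000_2009", "2009_2015", "1990_2015")


def load_printed_matrix(period: str) -> TransitionMatrix:
    """Load one of the packaged published change matrices (off-diagonal
    change areas only; the unchanged diagonal was not published)."""
    if period not in PRINTED_PERIODS:
        raise ValueError(f"unknown period {period!r}; expected one of {PRINTED_PERIODS}")
    from importlib import resources

    path = resources.files("bluecarbon") / "data" / f"transition_{period}.csv"
    with resources.as_file(path) as p:
        return read_matrix_csv(p, period=tuple(period.split("_")))


def load_printed_marginals(period: str) -> tuple[dict[int, float], dict[int, float]]:
    """Transfer-out/in marginal cells exactly as published for one period."""
    if period not in PRINTED_PERIODS:
        raise ValueError(f"unknown period {period!r}; expected one of {PRINTED_PERIODS}")
    from importlib import resources

    path = resources.files("bluecarbon") / "data" / f"transition_{period}.csv"
    with resources.as_file(path) as p:
        return read_matrix_marginals(p)


def read_matrix_marginals(path: str | Path) -> tuple[dict[int, float], dict[int, float]]:
    """Read the transfer-out column and transfer-in row as stored in the file
    (useful for checking a published table against its own body)."""
    path = Path(path)
    with open(path) as fh:
        rows = list(csv.reader(fh))
    name_to_code = {name: code for code, name in CODE_NAMES.items()}
    col_codes = [name_to_code[h] for h in rows[0][1 : _N + 1]]
    out: dict[int, float] = {}
    into: dict[int, float] = {}
    for row in rows[1:]:
        if not row:
            continue
        if row[0] == _IN_LABEL:
            for col_idx, code in enumerate(col_codes):
                into[code] = float(row[1 + col_idx])
        elif row[0] in name_to_code:
            out[name_to_code[row[0]]] = float(row[_N + 1])
    return out, into
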