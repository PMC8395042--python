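"""Land-use/land-cover (LULC) domain types, the 10-class coastal scheme, and raster I/O.

The study system is a coastal strip mapped at several dates with integer
class codes 1-10:

====  =====================  ==================
code  name                   group
====  =====================  ==================
1     Offshore waters        waters
2     Tidal flat             natural wetland
3     Coastal marsh          natural wetland
4     Grassland              other land
5     River and lake         natural wetland
6     Aquaculture fish pond  artificial wetland
7     Paddy field            artificial wetland
8     Reservoir              artificial wetland
9     Construction land      other land
10    Rainfed cropland       other land
====  =====================  ==================

Grassland sits in "other land" for group summaries even though it takes part
in natural succession/erosion; the grouping and the process taxonomy are kept
in separate lookup tables (see :mod:`bluecarbon.processes`).

Rasters are single-band integer grids, either ESRI ASCII grids or plain
single-band TIFFs. Nodata is the sentinel 0; cells outside the study mask
carry nodata at every date so total mapped area is conserved across dates.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np

NODATA = 0
CODES = tuple(range(1, 11))

_SCHEME_PATH = resources.files("bluecarbon") / "data" / "lulc_classes.csv"


def _load_scheme() -> dict[int, tuple[str, str]]:
    with _SCHEME_PATH.open() as fh:
        rows = list(csv.DictReader(fh))
    return {int(r["code"]): (r["name"], r["group"]) for r in rows}


_SCHEME = _load_scheme()

CODE_NAMES: dict[int, str] = {c: _SCHEME[c][0] for c in CODES}
CODE_GROUPS: dict[int, str] = {c: _SCHEME[c][1] for c in CODES}
GROUPS = ("natural wetland", "artificial wetland", "other land", "waters")


def group_of(code: int) -> str:
    """Return the summary group of a class code.

    >>> group_of(3)
    'natural wetland'
    >>> group_of(8)
    'artificial wetland'
    """
    if code not in CODE_GROUPS:
        raise ValueError(f"invalid LULC code {code!r}: expected 1..10")
    return CODE_GROUPS[code]


def name_of(code: int) -> str:
    """Return the class name of a code (e.g. 2 -> 'Tidal flat')."""
    if code not in CODE_NAMES:
        raise ValueError(f"invalid LULC code {code!r}: expected 1..10")
    return CODE_NAMES[code]


@dataclass(frozen=True)
class LULCGrid:
    """One dated categorical raster.

    Parameters
    ----------
    cells
        2-D integer array of codes 1-10, with 0 marking nodata.
    cell_size
        Cell side length in metres (>0). Cell area is
        ``cell_size**2 / 1e4`` ha, ``cell_size**2 / 1e6`` km².
    date_label
        Free-text date tag (e.g. "1990").
    origin
        (x, y) of the upper-left corner; row 0 is the northernmost row.
    """

    cells: np.ndarray
    cell_size: float
    date_label: str = ""
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        cells = np.asarray(self.cells)
        if cells.ndim != 2:
            raise ValueError(f"cells must be 2-D, got shape {cells.shape}")
        if not np.issubdtype(cells.dtype, np.integer):
            raise ValueError(f"cells must be integer, got dtype {cells.dtype}")
        if self.cell_size <= 0:
            raise ValueError(f"cell_size must be > 0, got {self.cell_size}")
        bad = (cells != NODATA) & ((cells < 1) | (cells > 10))
        if bad.any():
            idx = tuple(int(v) for v in np.argwhere(bad)[0])
            raise ValueError(
                f"out-of-range LULC code {int(cells[idx])} at cell {idx}"
            )
        object.__setattr__(self, "cells", cells)

    @property
    def shape(self) -> tuple[int, int]:
        return self.cells.shape

    @property
    def cell_area_ha(self) -> float:
        return self.cell_size**2 / 1e4

    @property
    def cell_area_km2(self) -> float:
        return self.cell_size**2 / 1e6

    @property
    def mask(self) -> np.ndarray:
        """Boolean array, True on mapped (non-nodata) cells."""
        return self.cells != NODATA

    def with_cells(self, cells: np.ndarray, date_label: str | None = None) -> "LULCGrid":
        return replace(
            self,
            cells=cells,
            date_label=self.date_label if date_label is None else date_label,
        )

    def congruent_with(self, other: "LULCGrid") -> bool:
        return (
            self.shape == other.shape
            and self.cell_size == other.cell_size
            and self.origin == other.origin
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LULCGrid):
            return NotImplemented
        return (
            self.congruent_with(other)
            and self.date_label == other.date_label
            and np.array_equal(self.cells, other.cells)
        )


@dataclass(frozen=True)
class LULCSeries:
    """A time-ordered stack of congruent grids with identical nodata masks."""

    grids: tuple[LULCGrid, ...]

    def __init__(self, grids: Sequence[LULCGrid]):
        grids = tuple(grids)
        if len(grids) < 2:
            raise ValueError(f"a series needs >= 2 dates, got {len(grids)}")
        first = grids[0]
        for k, g in enumerate(grids[1:], start=1):
            if not first.congruent_with(g):
                raise ValueError(f"grid {k} is not congruent with grid 0")
            if not np.array_equal(first.mask, g.mask):
                raise ValueError(f"grid {k} nodata mask differs from grid 0")
        object.__setattr__(self, "grids", grids)

    def __len__(self) -> int:
        return len(self.grids)

    def __getitem__(self, i: int) -> LULCGrid:
        return self.grids[i]

    def __iter__(self) -> Iterator[LULCGrid]:
        return iter(self.grids)

    @property
    def date_labels(self) -> tuple[str, ...]:
        return tuple(g.date_label for g in self.grids)

    @property
    def cell_size(self) -> float:
        return self.grids[0].cell_size

    def codes_per_date(self) -> np.ndarray:
        """(n_dates, rows, cols) stacked code array."""
        return np.stack([g.cells for g in self.grids])


# ---------------------------------------------------------------------------
# raster I/O
# ---------------------------------------------------------------------------

_ASCII_HEADER_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize")


def read_lulc_raster(path: str | Path, date_label: str = "") -> LULCGrid:
    """Read a single-band integer raster (ESRI ASCII grid or TIFF).

    Format is sniffed from the suffix: ``.asc``/``.txt``/``.grd`` parse as
    ESRI ASCII, ``.tif``/``.tiff`` through tifffile. Nodata values are mapped
    to the sentinel 0; any other code outside 1..10 raises ``ValueError``
    naming the offending cell.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        arr = np.asarray(tifffile.imread(path)).astype(np.int64)
        cell_size, origin, nodata = _read_tiff_sidecar(path)
    else:
        arr, cell_size, origin, nodata = _read_ascii_grid(path)
    if nodata is not None and nodata != NODATA:
        arr = np.where(arr == nodata, NODATA, arr)
    return LULCGrid(arr, cell_size=cell_size, date_label=date_label or path.stem, origin=origin)


def write_lulc_raster(grid: LULCGrid, path: str | Path) -> Path:
    """Write a grid so that :func:`read_lulc_raster` restores it bit-identically."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, grid.cells.astype(np.int32))
        _write_tiff_sidecar(grid, path)
    else:
        _write_ascii_grid(grid, path)
    return path


def _read_ascii_grid(path: Path) -> tuple[np.ndarray, float, tuple[float, float], int | None]:
    header: dict[str, float] = {}
    nodata: int | None = None
    rows: list[list[int]] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            key = parts[0].lower()
            if key in _ASCII_HEADER_KEYS:
                header[key] = float(parts[1])
            elif key == "nodata_value":
                nodata = int(float(parts[1]))
            else:
                rows.append([int(float(v)) for v in parts])
    missing = [k for k in ("ncols", "nrows", "cellsize") if k not in header]
    if missing:
        raise ValueError(f"{path}: ASCII grid header missing {missing}")
    arr = np.array(rows, dtype=np.int64)
    expect = (int(header["nrows"]), int(header["ncols"]))
    if arr.shape != expect:
        raise ValueError(f"{path}: data shape {arr.shape} != header {expect}")
    xll = header.get("xllcorner", 0.0)
    yll = header.get("yllcorner", 0.0)
    # origin is the upper-left corner; ASCII grids declare the lower-left
    origin = (xll, yll + header["cellsize"] * expect[0])
    return arr, header["cellsize"], origin, nodata


def _write_ascii_grid(grid: LULCGrid, path: Path) -> None:
    nrows, ncols = grid.shape
    xll = grid.origin[0]
    yll = grid.origin[1] - grid.cell_size * nrows
    with open(path, "w") as fh:
        fh.write(f"ncols {ncols}\n")
        fh.write(f"nrows {nrows}\n")
        fh.write(f"xllcorner {xll:g}\n")
        fh.write(f"yllcorner {yll:g}\n")
        fh.write(f"cellsize {grid.cell_size:g}\n")
        fh.write(f"NODATA_value {NODATA}\n")
        for row in grid.cells:
            fh.write(" ".join(str(int(v)) for v in row) + "\n")


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".hdr")


def _write_tiff_sidecar(grid: LULCGrid, path: Path) -> None:
    # plain TIFF carries no georeferencing; keep cell size/origin alongside
    with open(_sidecar(path), "w") as fh:
        fh.write(f"cellsize {grid.cell_size:g}\n")
        fh.write(f"origin {grid.origin[0]:g} {grid.origin[1]:g}\n")
        fh.write(f"nodata {NODATA}\n")


def _read_tiff_sidecar(path: Path) -> tuple[float, tuple[float, float], int | None]:
    side = _sidecar(path)
    cell_size, origin, nodata = 1.0, (0.0, 0.0), None
    if side.exists():
        for line in side.read_text().splitlines():
            parts = line.split()
            if not parts:
                continue
            if parts[0] == "cellsize":
                cell_size = float(parts[1])
            elif parts[0] == "origin":
                origin = (float(parts[1]), float(parts[2]))
            elif parts[0] == "nodata":
                nodata = int(parts[1])
    return cell_size, origin, nodata
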