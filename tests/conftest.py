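import numpy as np
import pytest

from bluecarbon import CarbonDensityTable, LULCGrid, LULCSeries


@pytest.fixture(scope="session")
def density_table() -> CarbonDensityTable:
    """The packaged coastal carbon-density table (printed totals mode)."""
    return CarbonDensityTable.from_csv()


def make_random_grid(
    seed: int,
    shape: tuple[int, int] = (20, 20),
    cell_size: float = 100.0,
    date_label: str = "t",
    mask: np.ndarray | None = None,
) -> LULCGrid:
    """Uniform random codes 1..10 with an optional shared nodata mask."""
    rng = np.random.default_rng(seed)
    cells = rng.integers(1, 11, size=shape)
    if mask is not None:
        cells = np.where(mask, cells, 0)
    return LULCGrid(cells, cell_size=cell_size, date_label=date_label)


def make_random_series(
    seed: int,
    n_dates: int = 4,
    shape: tuple[int, int] = (15, 15),
    cell_size: float = 100.0,
) -> LULCSeries:
    """Random multi-date series sharing one nodata mask."""
    rng = np.random.default_rng(seed)
    mask = rng.random(shape) > 0.1
    return LULCSeries(
        [
            make_random_grid(seed + k, shape, cell_size, date_label=f"t{k}", mask=mask)
            for k in range(n_dates)
        ]
    )


@pytest.fixture
def random_series() -> LULCSeries:
    return make_random_series(7)
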