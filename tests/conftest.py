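import numpy as np
import pytest

from landshift import CellGrid, build_weights
from landshift.grid import ALL_CLASSES, DYNAMIC_CLASSES, OTHERS
from landshift.synthetic import SyntheticSpec, gen_landscape


def make_uniform_grid(
    n_rows: int = 4,
    n_cols: int = 4,
    others: float = 10.0,
    cell_side_km: float = 10.0,
    year: int = 2000,
) -> CellGrid:
    """Grid with every dynamic class at an equal share of the dynamic area."""
    share = (100.0 - others) / len(DYNAMIC_CLASSES)
    fractions = {c: np.full((n_rows, n_cols), share) for c in DYNAMIC_CLASSES}
    fractions[OTHERS] = np.full((n_rows, n_cols), others)
    return CellGrid(n_rows, n_cols, fractions, cell_side_km=cell_side_km, year=year)


@pytest.fixture(scope="session")
def landscape():
    """Default-scale synthetic landscape, fixed seed (shared, read-only)."""
    return gen_landscape(SyntheticSpec(seed=42))


@pytest.fixture(scope="session")
def landscape_weights(landscape):
    W = build_weights(landscape)
    W.eigenvalues()  # warm the cache once for the whole session
    return W


@pytest.fixture(scope="session")
def small_landscape():
    return gen_landscape(SyntheticSpec(seed=7, n_rows=16, n_cols=16))


@pytest.fixture(scope="session")
def small_weights(small_landscape):
    return build_weights(small_landscape)


@pytest.fixture
def uniform_grid():
    return make_uniform_grid()


__all__ = ["make_uniform_grid", "ALL_CLASSES"]
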