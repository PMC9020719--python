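"""Cellular space, spatial neighborhood weights, and raster-to-cell aggregation.

The study region is discretised into a regular lattice of square cells
(10 km sides by default).  Each cell carries a fractional land-use
composition in percent of cell area — six dynamic classes plus a static
``others`` class (artificial surfaces, water, bare land) — alongside named
driver fields, named restriction masks and a validity flag for cells inside
the study region.  All downstream stages (regression, allocation,
validation) operate on this container.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

#: Dynamic land-use classes, in canonical order (used for deterministic
#: tie-breaking during allocation competition).
DYNAMIC_CLASSES: tuple[str, ...] = (
    "forest_vegetation",
    "grassland_vegetation",
    "planted_pasture",
    "agriculture",
    "mosaic_of_occupation",
    "forestry",
)

#: Static class excluded from change (cities, water, bare land).
OTHERS: str = "others"

ALL_CLASSES: tuple[str, ...] = DYNAMIC_CLASSES + (OTHERS,)

#: Classes representing human land use; restriction masks damp their expansion.
ANTHROPIC_CLASSES: tuple[str, ...] = (
    "planted_pasture",
    "agriculture",
    "mosaic_of_occupation",
    "forestry",
)

FRACTION_TOL = 1e-6


class GridError(ValueError):
    """Configuration or dimension error in the cellular space."""


@dataclass
class CellGrid:
    """Regular lattice of cells with fractional land-use composition.

    Parameters
    ----------
    n_rows, n_cols
        Lattice shape; cell (0, 0) is the north-west corner, row-major
        0-based indexing.
    cell_side_km
        Side length of a (square) cell in projected km.
    fractions
        Mapping class name -> (n_rows, n_cols) float array of percent of
        cell area, in [0, 100].  For every valid cell the fractions
        (including ``others``) sum to 100.
    drivers
        Named real-valued per-cell fields (explanatory variables).
    masks
        Named per-cell fields in [0, 1] (restriction / protection levels).
    valid
        Boolean per-cell field; ``False`` marks cells outside the study
        region, excluded from weights, sums and statistics.
    year
        Time stamp of the composition snapshot.
    """

    n_rows: int
    n_cols: int
    fractions: dict[str, np.ndarray]
    cell_side_km: float = 10.0
    drivers: dict[str, np.ndarray] = field(default_factory=dict)
    masks: dict[str, np.ndarray] = field(default_factory=dict)
    valid: np.ndarray | None = None
    year: int = 2000

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise GridError("grid shape must be positive")
        if self.valid is None:
            self.valid = np.ones((self.n_rows, self.n_cols), dtype=bool)
        self.valid = np.asarray(self.valid, dtype=bool)
        for name, arr in self.fractions.items():
            self.fractions[name] = np.asarray(arr, dtype=float)
            if self.fractions[name].shape != self.shape:
                raise GridError(f"fraction field {name!r} has wrong shape")

    # -- basic geometry ----------------------------------------------------

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def cell_area_km2(self) -> float:
        return self.cell_side_km**2

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())

    @property
    def total_area_km2(self) -> float:
        """Area of the study region (valid cells only)."""
        return self.n_valid * self.cell_area_km2

    def class_area_km2(self, cls: str) -> float:
        """Total area of one class over valid cells, in km²."""
        f = self.fractions[cls]
        return float(f[self.valid].sum() / 100.0 * self.cell_area_km2)

    # -- invariants --------------------------------------------------------

    def check(self, tol: float = FRACTION_TOL) -> None:
        """Validate the compositional invariants; raise GridError on violation."""
        missing = [c for c in ALL_CLASSES if c not in self.fractions]
        if missing:
            raise GridError(f"missing class fields: {missing}")
        total = np.zeros(self.shape)
        for c in ALL_CLASSES:
            f = self.fractions[c]
            if np.any(f[self.valid] < -tol) or np.any(f[self.valid] > 100 + tol):
                raise GridError(f"class {c!r} has fractions outside [0, 100]")
            total += f
        bad = self.valid & (np.abs(total - 100.0) > tol)
        if bad.any():
            rows, cols = np.nonzero(bad)
            cells = [(int(r), int(c)) for r, c in zip(rows[:5], cols[:5])]
            raise GridError(
                f"fraction sums differ from 100 in {bad.sum()} cells, e.g. {cells}"
            )

    def copy(self) -> "CellGrid":
        return CellGrid(
            n_rows=self.n_rows,
            n_cols=self.n_cols,
            fractions={c: a.copy() for c, a in self.fractions.items()},
            cell_side_km=self.cell_side_km,
            drivers={k: v.copy() for k, v in self.drivers.items()},
            masks={k: v.copy() for k, v in self.masks.items()},
            valid=self.valid.copy(),
            year=self.year,
        )


@dataclass
class SpatialWeights:
    """Row-standardized contiguity weights over the valid cells of a grid.

    ``matrix`` is an (n_cells, n_cells) sparse CSR matrix in row-major cell
    order; rows of valid cells with at least one neighbor sum to 1, rows of
    isolated or invalid cells are empty.  Eigenvalues of the standardized
    matrix are computed lazily and cached: they give the exact
    log-determinant ln|I − ρW| and the admissible interval for the spatial
    autoregressive coefficient ρ.
    """

    matrix: sp.csr_matrix
    scheme: str
    shape: tuple[int, int]
    valid: np.ndarray
    _eigvals: np.ndarray | None = None

    @property
    def n_cells(self) -> int:
        return self.matrix.shape[0]

    def lag(self, field2d: np.ndarray) -> np.ndarray:
        """Spatial lag W·y of a per-cell field, returned with the grid shape."""
        flat = np.asarray(field2d, dtype=float).ravel()
        return (self.matrix @ flat).reshape(self.shape)

    def eigenvalues(self) -> np.ndarray:
        """Real eigenvalues of the row-standardized W (dense, cached).

        W = D⁻¹A with symmetric non-negative A is similar to the symmetric
        D^{-1/2}AD^{-1/2}, so its spectrum is real; isolated rows contribute
        zero eigenvalues.
        """
        if self._eigvals is None:
            # recover the 0/1 adjacency from the sparsity pattern of W
            adj = (self.matrix > 0).astype(float)
            deg = np.asarray(adj.sum(axis=1)).ravel()
            with np.errstate(divide="ignore"):
                dinv_sqrt = np.where(deg > 0, 1.0 / np.sqrt(np.maximum(deg, 1e-300)), 0.0)
            sym = adj.multiply(dinv_sqrt[:, None]).multiply(dinv_sqrt[None, :])
            self._eigvals = np.linalg.eigvalsh(sym.toarray())
        return self._eigvals

    def rho_bounds(self) -> tuple[float, float]:
        """Open admissible interval for ρ from the extreme eigenvalues."""
        ev = self.eigenvalues()
        lo = ev.min()
        hi = ev.max()
        lower = 1.0 / lo if lo < 0 else -np.inf
        upper = 1.0 / hi if hi > 0 else np.inf
        return (lower, upper)


def build_weights(grid: CellGrid, scheme: str = "queen") -> SpatialWeights:
    """Build row-standardized contiguity weights on the grid's valid cells.

    Queen contiguity (8 neighbors, the default) or rook (4 neighbors).
    Only valid cells receive neighbors; the adjacency is symmetric before
    row standardization, there are no self-neighbors, and ordering is
    deterministic row-major.
    """
    if scheme not in ("queen", "rook"):
        raise GridError(f"unknown contiguity scheme {scheme!r}")
    if grid.n_valid < 1:
        raise GridError("grid has no valid cells")
    nr, nc = grid.shape
    if scheme == "rook":
        offsets = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        offsets = [
            (-1, -1), (-1, 0), (-1, 1),
            (0, -1), (0, 1),
            (1, -1), (1, 0), (1, 1),
        ]
    rows_idx, cols_idx = [], []
    valid = grid.valid
    rr, cc = np.nonzero(valid)
    flat = rr * nc + cc
    for dr, dc in offsets:
        nrr, ncc = rr + dr, cc + dc
        inside = (nrr >= 0) & (nrr < nr) & (ncc >= 0) & (ncc < nc)
        src = flat[inside]
        nrr, ncc = nrr[inside], ncc[inside]
        ok = valid[nrr, ncc]
        rows_idx.append(src[ok])
        cols_idx.append((nrr * nc + ncc)[ok])
    i = np.concatenate(rows_idx) if rows_idx else np.array([], dtype=int)
    j = np.concatenate(cols_idx) if cols_idx else np.array([], dtype=int)
    n = grid.n_cells
    adj = sp.csr_matrix((np.ones(len(i)), (i, j)), shape=(n, n))
    deg = np.asarray(adj.sum(axis=1)).ravel()
    with np.errstate(divide="ignore"):
        inv = np.where(deg > 0, 1.0 / np.maximum(deg, 1e-300), 0.0)
    w = adj.multiply(inv[:, None]).tocsr()
    w.sort_indices()
    return SpatialWeights(matrix=w, scheme=scheme, shape=grid.shape, valid=valid.copy())


def _block_shape(raster: np.ndarray, grid: CellGrid) -> tuple[int, int]:
    hr, wc = raster.shape
    if hr % grid.n_rows or wc % grid.n_cols:
        raise GridError(
            f"raster shape {raster.shape} is not an integer multiple of "
            f"grid shape {grid.shape}"
        )
    return hr // grid.n_rows, wc // grid.n_cols


def aggregate_percentage(high_res_mask: np.ndarray, grid: CellGrid) -> np.ndarray:
    """Percent of each cell's pixels that are True in a high-resolution mask.

    The raster dimensions must be integer multiples of the grid shape; each
    cell receives 100 × (true pixels in its block) / (pixels in block).
    """
    mask = np.asarray(high_res_mask, dtype=bool)
    br, bc = _block_shape(mask, grid)
    blocks = mask.reshape(grid.n_rows, br, grid.n_cols, bc)
    return 100.0 * blocks.mean(axis=(1, 3))


def aggregate_min_distance(
    high_res_mask: np.ndarray,
    grid: CellGrid,
    sentinel_km: float = 1e6,
) -> np.ndarray:
    """Minimum Euclidean distance (km) from each cell centroid to a True pixel.

    Distances are centroid-to-centroid in projected km; a cell whose own
    block contains a True pixel gets 0.  An empty mask yields a field of
    ``sentinel_km`` with a warning.
    """
    mask = np.asarray(high_res_mask, dtype=bool)
    br, bc = _block_shape(mask, grid)
    if not mask.any():
        warnings.warn("empty feature mask: min-distance field set to sentinel")
        return np.full(grid.shape, float(sentinel_km))
    px_km = grid.cell_side_km / br  # pixel pitch along rows
    py_km = grid.cell_side_km / bc
    pr, pc = np.nonzero(mask)
    # pixel centroids in km, origin at raster's NW corner
    py = (pr + 0.5) * px_km
    px = (pc + 0.5) * py_km
    # zero inside cells containing a source pixel
    contains = aggregate_percentage(mask, grid) > 0
    out = np.empty(grid.shape)
    cy = (np.arange(grid.n_rows) + 0.5) * grid.cell_side_km
    cx = (np.arange(grid.n_cols) + 0.5) * grid.cell_side_km
    for r in range(grid.n_rows):
        d2 = (cy[r] - py) ** 2 + (cx[:, None] - px[None, :]) ** 2
        out[r, :] = np.sqrt(d2.min(axis=1))
    out[contains] = 0.0
    return out
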