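"""Iterative, competition-mediated allocation of demanded land-use change.

Each simulated year the allocator distributes the national per-class demand
across cells in proportion to the change-potential surfaces.  A class only
changes in cells whose potential sign matches its national demand direction
(a growing class gains where potential is positive; a shrinking class loses
where it is negative).  Within each cell the competing per-class changes
are rebalanced so the compositional constraints hold — every fraction stays
in [0, 100] and the cell total (with the frozen ``others`` share) stays at
exactly 100 — by scaling down whichever of the gain or loss side requests
more.  A per-class iteration factor (ITF) is then updated multiplicatively
in proportion to the remaining demand gap and the candidate year is
recomputed from the year-start map, until every class's allocated total is
within the configured maximum error of its demand.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .grid import ANTHROPIC_CLASSES, DYNAMIC_CLASSES, OTHERS, CellGrid
from .potential import PotentialSurface


class AllocationError(RuntimeError):
    """Allocation failed to converge (the report rides along)."""

    def __init__(self, message: str, report: "AllocationReport"):
        super().__init__(message)
        self.report = report


@dataclass
class AllocationParams:
    """Tunables of the iterative allocator.

    max_error is a fraction of total study area (convergence band per
    class); itf_gain is the multiplicative update gain λ ∈ (0, 2];
    min_cell_change (percent of cell) zeroes negligible per-cell deltas;
    anthropic_cap (percent) optionally caps the summed human-use fraction
    per cell, a reduced stand-in for legal-reserve rules.
    """

    max_error: float = 0.005
    max_iterations: int = 1000
    itf_gain: float = 0.5
    min_cell_change: float = 0.0
    anthropic_cap: float | None = None
    allow_nonconvergence: bool = False

    def __post_init__(self) -> None:
        if self.max_error <= 0:
            raise ValueError("max_error must be > 0")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if not 0 < self.itf_gain <= 2:
            raise ValueError("itf_gain must lie in (0, 2]")


@dataclass
class AllocationReport:
    """Convergence record for one simulated year."""

    year: int
    iterations: int
    gaps_km2: dict[str, float] = field(default_factory=dict)
    converged: bool = False


def rebalance_cell(
    fractions: Mapping[str, float],
    deltas: Mapping[str, float],
    frozen_others: float | None = None,
) -> dict[str, float]:
    """Rebalance one cell's requested per-class changes (percent units).

    Losses are clipped so no fraction goes negative, gains so no fraction
    exceeds the dynamic share of the cell; then the side requesting more
    total change is scaled down proportionally so the deltas sum to zero
    across dynamic classes.  Pure function; infeasible requests resolve to
    zero change, never an error.
    """
    classes = [c for c in DYNAMIC_CLASSES if c in fractions]
    if frozen_others is None:
        frozen_others = float(fractions.get(OTHERS, 0.0))
    f = np.array([[float(fractions[c])] for c in classes])
    d = np.array([[float(deltas.get(c, 0.0))] for c in classes])
    out = _rebalance(f, d, frozen_others)
    return {c: float(out[i, 0]) for i, c in enumerate(classes)}


def _rebalance(
    fracs: np.ndarray, deltas: np.ndarray, others: np.ndarray | float
) -> np.ndarray:
    """Vectorized per-cell competition; arrays are (n_classes, n_cells)."""
    dyn_share = 100.0 - np.asarray(others, dtype=float)
    d = np.clip(deltas, -fracs, dyn_share - fracs)
    gains = np.clip(d, 0.0, None)
    losses = -np.clip(d, None, 0.0)
    g = gains.sum(axis=0)
    l = losses.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        fg = np.where(g > l, np.where(g > 0, l / np.maximum(g, 1e-300), 0.0), 1.0)
        fl = np.where(l > g, np.where(l > 0, g / np.maximum(l, 1e-300), 0.0), 1.0)
    return gains * fg - losses * fl


def _apply_anthropic_cap(
    deltas: np.ndarray,
    fracs: np.ndarray,
    classes: list[str],
    cap: float,
) -> np.ndarray:
    """Scale down anthropic gains that would push a cell past the cap."""
    anth = np.array([c in ANTHROPIC_CLASSES for c in classes])
    anth_frac = fracs[anth].sum(axis=0)
    gains = np.clip(deltas[anth], 0.0, None)
    losses = -np.clip(deltas[anth], None, 0.0)
    net = gains.sum(axis=0) - losses.sum(axis=0)
    allowed = np.maximum(cap - anth_frac, 0.0) + losses.sum(axis=0)
    g = gains.sum(axis=0)
    need_scale = (net > cap - anth_frac) & (g > 0)
    factor = np.where(need_scale, np.clip(allowed / np.maximum(g, 1e-300), 0.0, 1.0), 1.0)
    out = deltas.copy()
    out[anth] = gains * factor - losses
    return out


def allocate_year(
    grid_prev: CellGrid,
    potentials: Mapping[str, PotentialSurface],
    demand_km2: Mapping[str, float],
    params: AllocationParams | None = None,
    year: int | None = None,
) -> tuple[CellGrid, AllocationReport]:
    """Allocate one year of change so class totals meet national demand.

    Iterates: candidate per-cell deltas = potential × ITF (sign-gated to
    the class's demand direction), per-cell competition rebalancing, then a
    multiplicative ITF update proportional to each class's remaining demand
    gap.  Converges when every class's allocated total is within
    max_error × study area of its demand; raises AllocationError (report
    attached) otherwise, unless the params accept non-convergence.
    """
    params = params or AllocationParams()
    year = year if year is not None else grid_prev.year + 1
    missing = [c for c in DYNAMIC_CLASSES if c not in potentials]
    if missing:
        raise ValueError(f"missing potential surfaces for classes: {missing}")
    classes = list(DYNAMIC_CLASSES)
    valid = grid_prev.valid
    vflat = valid.ravel()
    cell_area = grid_prev.cell_area_km2
    total_area = grid_prev.total_area_km2
    tol_km2 = params.max_error * total_area

    fracs = np.stack([grid_prev.fractions[c].ravel() for c in classes])
    fracs = fracs[:, vflat]
    others = grid_prev.fractions[OTHERS].ravel()[vflat]
    pots = np.stack([
        np.asarray(potentials[c].values, dtype=float).ravel() for c in classes
    ])[:, vflat] * 100.0  # percent units

    areas0 = fracs.sum(axis=1) / 100.0 * cell_area
    demand = np.array([float(demand_km2[c]) for c in classes])
    if abs(demand.sum() - areas0.sum()) > tol_km2:
        raise ValueError(
            f"demand total {demand.sum():.1f} km² differs from current dynamic "
            f"area {areas0.sum():.1f} km² by more than the maximum error"
        )
    # direction of the national demand gap; classes with any gap stay in
    # play so out-of-tolerance classes always have competition counterparties
    gap0 = demand - areas0
    eps = 1e-9 * max(total_area, 1.0)
    direction = np.where(gap0 > eps, 1.0, np.where(gap0 < -eps, -1.0, 0.0))

    itf = np.ones(len(classes))
    floor = max(1e-9 * total_area, 1e-9)
    report = AllocationReport(year=year, iterations=0)
    new = fracs
    for it in range(1, params.max_iterations + 1):
        deltas = pots * itf[:, None]
        # a class moves only in the direction of its national demand gap
        deltas = np.where(direction[:, None] == 0.0, 0.0, deltas)
        deltas = np.where(deltas * direction[:, None] > 0.0, deltas, 0.0)
        if params.min_cell_change > 0:
            deltas = np.where(np.abs(deltas) < params.min_cell_change, 0.0, deltas)
        if params.anthropic_cap is not None:
            deltas = _apply_anthropic_cap(deltas, fracs, classes, params.anthropic_cap)
        deltas = _rebalance(fracs, deltas, others)
        new = fracs + deltas
        areas = new.sum(axis=1) / 100.0 * cell_area
        gaps = areas - demand
        report.iterations = it
        report.gaps_km2 = {c: float(g) for c, g in zip(classes, gaps)}
        if np.all(np.abs(gaps) <= tol_km2):
            report.converged = True
            break
        rel = (demand - areas) / np.maximum(np.abs(demand), floor)
        mult = np.clip(1.0 + params.itf_gain * direction * rel, 0.1, 10.0)
        itf = np.clip(itf * np.where(direction == 0.0, 1.0, mult), 1e-12, 1e12)

    if not report.converged:
        msg = (
            f"allocation for year {year} did not converge in "
            f"{report.iterations} iterations; gaps (km²): "
            + ", ".join(f"{c}={g:.1f}" for c, g in report.gaps_km2.items())
        )
        if params.allow_nonconvergence:
            warnings.warn(msg)
        else:
            raise AllocationError(msg, report)

    out = grid_prev.copy()
    out.year = year
    for i, c in enumerate(classes):
        f = out.fractions[c].ravel()
        f[vflat] = new[i]
        out.fractions[c] = f.reshape(grid_prev.shape)
    # others is untouched by construction (frozen class)
    return out, report
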