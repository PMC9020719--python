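"""Yearly scenario simulation: demand + potential + allocation, 2000–2050.

A scenario is data, not code: a named bundle of demand endpoints per class,
a restriction-mask schedule (which legal protections apply from which
year, and how strongly), a driver schedule (fields that switch at given
years, e.g. road-distance surfaces after paving), and allocation
parameters.  The engine steps year by year: update scheduled drivers,
recompute each class's potential surface from last year's map (the
potential is dynamic), damp it by the active restrictions, then allocate
the year's demanded change across cells.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .allocation import AllocationParams, AllocationReport, allocate_year
from .demand import DemandEndpoint, scenario_demand_table
from .grid import DYNAMIC_CLASSES, CellGrid, SpatialWeights
from .potential import MaskRule, PotentialModel, apply_restrictions, compute_potential


@dataclass(frozen=True)
class DriverUpdate:
    """From ``year_from`` on, driver ``name`` is replaced by field ``source``."""

    year_from: int
    name: str
    source: str


@dataclass
class ScenarioConfig:
    """Everything that distinguishes one scenario run from another."""

    name: str
    endpoints: dict[str, DemandEndpoint]
    mask_schedule: list[MaskRule] = field(default_factory=list)
    driver_schedule: list[DriverUpdate] = field(default_factory=list)
    allocation: AllocationParams = field(default_factory=AllocationParams)
    seed: int = 0
    snapshot_years: list[int] | None = None  # None -> every year

    def __post_init__(self) -> None:
        years = [e.initial_year for e in self.endpoints.values()] + [
            e.final_year for e in self.endpoints.values()
        ]
        if years:
            self.start_year = min(years)
            self.end_year = max(years)
        for rule in self.mask_schedule:
            if not self.start_year <= rule.year_from <= self.end_year:
                raise ValueError(
                    f"mask schedule year {rule.year_from} outside "
                    f"[{self.start_year}, {self.end_year}]"
                )

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "demand": {
                c: {
                    "initial_year": e.initial_year,
                    "final_year": e.final_year,
                    "initial_area_km2": e.initial_area_km2,
                    "final_area_km2": e.final_area_km2,
                }
                for c, e in self.endpoints.items()
            },
            "masks": [
                {"year_from": r.year_from, "mask": r.mask, "levels": dict(r.levels)}
                for r in self.mask_schedule
            ],
            "drivers": [asdict(u) for u in self.driver_schedule],
            "allocation": asdict(self.allocation),
            "seed": self.seed,
            "snapshot_years": self.snapshot_years,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ScenarioConfig":
        endpoints = {
            c: DemandEndpoint(
                c,
                int(v["initial_year"]),
                int(v["final_year"]),
                float(v["initial_area_km2"]),
                float(v["final_area_km2"]),
            )
            for c, v in d["demand"].items()
        }
        return cls(
            name=d.get("name", "scenario"),
            endpoints=endpoints,
            mask_schedule=[
                MaskRule(int(r["year_from"]), r["mask"], dict(r.get("levels", {})))
                for r in d.get("masks", [])
            ],
            driver_schedule=[
                DriverUpdate(int(u["year_from"]), u["name"], u["source"])
                for u in d.get("drivers", [])
            ],
            allocation=AllocationParams(**d.get("allocation", {})),
            seed=int(d.get("seed", 0)),
            snapshot_years=d.get("snapshot_years"),
        )

    def hash(self) -> str:
        """Content hash, stable under key reordering."""
        blob = json.dumps(self.to_dict(), sort_keys=True, default=float)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class RunResult:
    """Yearly snapshots plus per-year allocation reports and provenance."""

    snapshots: dict[int, CellGrid]
    reports: list[AllocationReport]
    provenance: dict

    @property
    def years(self) -> list[int]:
        return sorted(self.snapshots)

    def final(self) -> CellGrid:
        return self.snapshots[self.years[-1]]

    def initial(self) -> CellGrid:
        return self.snapshots[self.years[0]]


def _apply_driver_schedule(
    grid: CellGrid, schedule: Sequence[DriverUpdate], year: int
) -> None:
    latest: dict[str, DriverUpdate] = {}
    for u in sorted(schedule, key=lambda u: u.year_from):
        if u.year_from <= year:
            latest[u.name] = u
    for name, u in latest.items():
        if u.source not in grid.drivers:
            raise ValueError(f"driver schedule source field {u.source!r} missing")
        grid.drivers[name] = grid.drivers[u.source].copy()


def run_scenario(
    initial: CellGrid,
    config: ScenarioConfig,
    models: Mapping[str, PotentialModel],
    W: SpatialWeights,
) -> RunResult:
    """Simulate the scenario from the initial map to the final demand year.

    Deterministic given the config: the pipeline itself has no stochastic
    step (the seed is provenance for synthetic inputs).  Allocation
    non-convergence propagates with the failing year attached.
    """
    missing = [c for c in DYNAMIC_CLASSES if c not in models]
    if missing:
        raise ValueError(f"missing potential models for classes: {missing}")
    series = scenario_demand_table(config.endpoints)
    start = config.start_year
    end = config.end_year
    if initial.year != start:
        raise ValueError(
            f"initial grid year {initial.year} != demand initial year {start}"
        )
    initial.check()
    grid = initial.copy()
    snapshots: dict[int, CellGrid] = {}
    keep = set(config.snapshot_years) if config.snapshot_years else None
    if keep is None or start in keep:
        snapshots[start] = grid.copy()
    reports: list[AllocationReport] = []
    for year in range(start + 1, end + 1):
        _apply_driver_schedule(grid, config.driver_schedule, year)
        potentials = {}
        for cls in DYNAMIC_CLASSES:
            surf = compute_potential(models[cls], grid, W)
            surf.year = year
            surf = apply_restrictions(surf, grid.masks, config.mask_schedule, year)
            potentials[cls] = surf
        demand_t = {cls: series[cls][year] for cls in DYNAMIC_CLASSES}
        try:
            grid, report = allocate_year(
                grid, potentials, demand_t, config.allocation, year=year
            )
        except Exception as exc:
            raise RuntimeError(f"scenario {config.name!r} failed at year {year}") from exc
        reports.append(report)
        if keep is None or year in keep:
            snapshots[year] = grid.copy()
    if end not in snapshots:
        snapshots[end] = grid.copy()
    provenance = {
        "scenario": config.name,
        "config_hash": config.hash(),
        "seed": config.seed,
        "version": __version__,
    }
    return RunResult(snapshots=snapshots, reports=reports, provenance=provenance)


def summarize(
    run: RunResult, regions: np.ndarray | None = None
) -> pd.DataFrame:
    """Per-year, per-class (optionally per-region) areas in km²."""
    if not run.snapshots:
        raise ValueError("empty run")
    rows = []
    for year in run.years:
        g = run.snapshots[year]
        if regions is None:
            labels = {"all": g.valid}
        else:
            reg = np.asarray(regions)
            if reg.shape != g.shape:
                raise ValueError("region label field does not match the grid")
            labels = {
                str(r): (reg == r) & g.valid for r in np.unique(reg[g.valid])
            }
        for cls in DYNAMIC_CLASSES:
            f = g.fractions[cls]
            for name, m in labels.items():
                rows.append(
                    {
                        "year": year,
                        "class": cls,
                        "region": name,
                        "area_km2": float(f[m].sum() / 100.0 * g.cell_area_km2),
                    }
                )
    return pd.DataFrame(rows)


def change_summary(run: RunResult) -> pd.DataFrame:
    """Signed net change and direction symbol per class over the run."""
    df = summarize(run)
    first, last = min(df.year), max(df.year)
    a0 = df[df.year == first].groupby("class")["area_km2"].sum()
    a1 = df[df.year == last].groupby("class")["area_km2"].sum()
    rows = []
    for cls in DYNAMIC_CLASSES:
        delta = a1[cls] - a0[cls]
        direction = "increase" if delta > 0 else ("reduction" if delta < 0 else "stable")
        symbol = {"increase": "↗", "reduction": "↘", "stable": "→"}[direction]
        rows.append(
            {
                "class": cls,
                "area_initial_km2": a0[cls],
                "area_final_km2": a1[cls],
                "change_km2": delta,
                "direction": direction,
                "symbol": symbol,
            }
        )
    return pd.DataFrame(rows)
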