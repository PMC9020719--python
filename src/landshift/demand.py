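"""Linear annual demand trajectories per land-use class and scenario.

Demand is exogenous ("pre-computed"): national targets come from a global
integrated-assessment model, reduced to one endpoint pair per class — the
observed area in the initial year and the projected area in the final year.
The annual change is the endpoint difference divided by the number of years
in the period, and the yearly demand series is built by adding that annual
change cumulatively, so the trajectory is exactly linear and closes on the
final endpoint.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .grid import DYNAMIC_CLASSES


class DemandError(ValueError):
    """Invalid demand configuration."""


@dataclass(frozen=True)
class DemandEndpoint:
    """Area targets for one class at the start and end of the period."""

    class_id: str
    initial_year: int
    final_year: int
    initial_area_km2: float
    final_area_km2: float

    def __post_init__(self) -> None:
        if self.final_year <= self.initial_year:
            raise DemandError(
                f"{self.class_id}: final_year {self.final_year} must exceed "
                f"initial_year {self.initial_year}"
            )
        if self.initial_area_km2 < 0 or self.final_area_km2 < 0:
            raise DemandError(f"{self.class_id}: areas must be non-negative")

    @property
    def n_years(self) -> int:
        return self.final_year - self.initial_year


@dataclass(frozen=True)
class DemandSeries:
    """Yearly area targets (km²) for one class over the whole period."""

    class_id: str
    targets: dict[int, float]  # year -> km²

    def __getitem__(self, year: int) -> float:
        return self.targets[year]

    @property
    def years(self) -> list[int]:
        return sorted(self.targets)

    def direction(self) -> int:
        """Sign of the net change over the period: +1, 0 or -1."""
        ys = self.years
        delta = self.targets[ys[-1]] - self.targets[ys[0]]
        return (delta > 0) - (delta < 0)


def annual_change(endpoint: DemandEndpoint) -> float:
    """Annual change in area (km²/year): endpoint difference over the period.

    The sign carries the direction of change (negative for shrinking
    classes).
    """
    return (endpoint.final_area_km2 - endpoint.initial_area_km2) / endpoint.n_years


def build_series(endpoint: DemandEndpoint) -> DemandSeries:
    """Build the yearly demand series by cumulative annual increments.

    The series starts exactly at the initial endpoint and each year adds the
    constant annual change, so the final year reproduces the final endpoint
    up to floating-point roundoff.
    """
    c = annual_change(endpoint)
    targets: dict[int, float] = {endpoint.initial_year: endpoint.initial_area_km2}
    prev = endpoint.initial_area_km2
    for year in range(endpoint.initial_year + 1, endpoint.final_year + 1):
        prev = prev + c
        targets[year] = prev
    return DemandSeries(class_id=endpoint.class_id, targets=targets)


#: National demand endpoints (km², 2000 -> 2050) for the three scenario
#: narratives: sustainable development (SSP1/RCP1.9), middle of the road
#: (SSP2/RCP4.5) and strong inequality (SSP3/RCP7.0).
BRAZIL_DEMAND_ENDPOINTS: dict[str, dict[str, tuple[float, float]]] = {
    "ssp1": {
        "forest_vegetation": (3_771_677, 4_232_402),
        "grassland_vegetation": (2_112_947, 1_517_633),
        "planted_pasture": (402_529, 445_974),
        "agriculture": (624_941, 328_444),
        "mosaic_of_occupation": (1_405_301, 1_822_044),
        "forestry": (55_983, 26_881),
    },
    "ssp2": {
        "forest_vegetation": (3_771_677, 2_975_314),
        "grassland_vegetation": (2_112_947, 1_012_637),
        "planted_pasture": (402_529, 670_850),
        "agriculture": (624_941, 856_018),
        "mosaic_of_occupation": (1_405_301, 2_788_498),
        "forestry": (55_983, 70_060),
    },
    "ssp3": {
        "forest_vegetation": (3_771_677, 2_846_765),
        "grassland_vegetation": (2_112_947, 772_878),
        "planted_pasture": (402_529, 714_860),
        "agriculture": (624_941, 1_077_091),
        "mosaic_of_occupation": (1_405_301, 2_873_629),
        "forestry": (55_983, 88_154),
    },
}


def scenario_endpoints(
    scenario: str, initial_year: int = 2000, final_year: int = 2050
) -> dict[str, DemandEndpoint]:
    """Endpoints for one of the built-in national scenarios."""
    key = scenario.lower()
    if key not in BRAZIL_DEMAND_ENDPOINTS:
        raise DemandError(
            f"unknown scenario {scenario!r}; choose from "
            f"{sorted(BRAZIL_DEMAND_ENDPOINTS)}"
        )
    table = BRAZIL_DEMAND_ENDPOINTS[key]
    return {
        cls: DemandEndpoint(cls, initial_year, final_year, a0, a1)
        for cls, (a0, a1) in table.items()
    }


def scenario_demand_table(
    endpoints: dict[str, DemandEndpoint],
) -> dict[str, DemandSeries]:
    """Build demand series for every dynamic class from its endpoint.

    Every dynamic class must have exactly one endpoint; all series share the
    same year span.
    """
    missing = [c for c in DYNAMIC_CLASSES if c not in endpoints]
    if missing:
        raise DemandError(f"missing demand endpoints for classes: {missing}")
    return {cls: build_series(endpoints[cls]) for cls in DYNAMIC_CLASSES}


def demand_frame(series: dict[str, DemandSeries]) -> pd.DataFrame:
    """Long-format DataFrame (year, class, area_km2) for CSV export."""
    rows = [
        {"year": y, "class": cls, "area_km2": s.targets[y]}
        for cls, s in series.items()
        for y in s.years
    ]
    return pd.DataFrame(rows).sort_values(["class", "year"]).reset_index(drop=True)
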