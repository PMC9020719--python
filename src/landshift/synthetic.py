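"""Synthetic study systems with a known data-generating process.

Generates complete, reproducible inputs for every pipeline stage without
any download: compositional landscapes on a regular lattice, driver fields
mimicking the four driver categories of the real database (agronomic,
agrarian structure, economic/distance-based, restrictive), restriction
masks, demand endpoint tables, and "observed" map pairs produced by
forward-running the scenario engine with known true parameters — ground
truth for calibration-recovery and validation tests.

Per-class latent suitability scores follow the spatial-lag process
z = (I − ρW)⁻¹(Xβ + ε); a temperature-controlled softmax maps the scores to
fractions that sum to the dynamic share of each cell (100 minus a fixed
``others`` percentage), so compositional invariants hold by construction
while driver monotonicity is preserved.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.ndimage import gaussian_filter

from .allocation import AllocationParams
from .demand import DemandEndpoint
from .grid import (
    DYNAMIC_CLASSES,
    OTHERS,
    CellGrid,
    SpatialWeights,
    aggregate_min_distance,
    build_weights,
)
from .potential import MaskRule, PotentialModel
from .scenario import RunResult, ScenarioConfig, run_scenario


@dataclass(frozen=True)
class LagParams:
    """True spatial-lag parameters for one class's latent score."""

    rho: float = 0.4
    beta: Mapping[str, float] = field(default_factory=dict)
    intercept: float = 0.0
    sigma: float = 0.1


@dataclass
class SyntheticSpec:
    """Recipe for a full synthetic study system.

    Driver recipes map a field name to a tuple ``(kind, params)`` with kind
    one of ``gradient`` (linear ramp plus noise), ``distance`` (km to the
    nearest of k random feature cells), or ``grf`` (smoothed Gaussian
    random field, standardized).  Defaults emulate the four driver
    categories: agronomic (water deficit), agrarian structure (large-farm
    share), economic (distances to roads and urban centres) and restrictive
    (protected-area blob mask).
    """

    n_rows: int = 50
    n_cols: int = 50
    seed: int = 0
    cell_side_km: float = 10.0
    others_pct: float = 7.0
    softmax_temperature: float = 1.0
    weights_scheme: str = "queen"
    driver_recipes: dict[str, tuple] = field(
        default_factory=lambda: {
            "water_deficit": ("grf", {"sigma": 4.0}),
            "suitability": ("gradient", {"axis": 1, "noise": 0.2}),
            "large_farms_share": ("grf", {"sigma": 6.0}),
            "dist_roads": ("distance", {"k": 6}),
            "dist_urban": ("distance", {"k": 3}),
        }
    )
    mask_recipes: dict[str, tuple] = field(
        default_factory=lambda: {"protected": ("blobs", {"sigma": 5.0, "quantile": 0.8})}
    )
    true_params: dict[str, LagParams] = field(default_factory=dict)
    #: mean share of the dynamic area per class; the default mirrors the
    #: national 2000 composition (forest-dominated, marginal forestry)
    class_shares: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.true_params:
            self.true_params = _default_true_params()
        if not self.class_shares:
            self.class_shares = _national_2000_shares()


def _national_2000_shares() -> dict[str, float]:
    areas = {
        "forest_vegetation": 3_771_677,
        "grassland_vegetation": 2_112_947,
        "planted_pasture": 402_529,
        "agriculture": 624_941,
        "mosaic_of_occupation": 1_405_301,
        "forestry": 55_983,
    }
    total = sum(areas.values())
    return {c: a / total for c, a in areas.items()}


def _default_true_params() -> dict[str, LagParams]:
    # Mild, class-specific driver loadings (drivers are standardized).  Per
    # driver the loadings sum to zero across classes, so the per-cell sum of
    # latent suitabilities — hence of class equilibria — stays compositionally
    # consistent: drivers redistribute land among classes rather than create
    # or destroy dynamic area.
    return {
        "forest_vegetation": LagParams(
            0.4, {"water_deficit": -0.3, "suitability": -0.15,
                  "dist_roads": 0.25, "dist_urban": 0.3}),
        "grassland_vegetation": LagParams(
            0.4, {"water_deficit": 0.3, "suitability": -0.2}),
        "planted_pasture": LagParams(
            0.4, {"suitability": 0.2, "large_farms_share": 0.25}),
        "agriculture": LagParams(
            0.4, {"suitability": 0.35, "dist_roads": -0.25}),
        "mosaic_of_occupation": LagParams(
            0.4, {"suitability": -0.35, "large_farms_share": -0.25,
                  "dist_urban": -0.3}),
        "forestry": LagParams(0.4, {"suitability": 0.15}),
    }


# ---------------------------------------------------------------------------
# field generators
# ---------------------------------------------------------------------------


def _standardize(a: np.ndarray) -> np.ndarray:
    s = a.std()
    return (a - a.mean()) / s if s > 0 else a - a.mean()


def gen_driver(
    kind: str, params: Mapping, shape: tuple[int, int], cell_side_km: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """One standardized driver field from a named recipe."""
    nr, nc = shape
    if kind == "gradient":
        axis = params.get("axis", 0)
        ramp = np.linspace(0, 1, shape[axis])
        base = ramp[:, None] * np.ones((1, nc)) if axis == 0 else np.ones((nr, 1)) * ramp[None, :]
        noise = params.get("noise", 0.0) * rng.standard_normal(shape)
        return _standardize(base + noise)
    if kind == "grf":
        raw = rng.standard_normal(shape)
        return _standardize(gaussian_filter(raw, params.get("sigma", 3.0), mode="nearest"))
    if kind == "distance":
        k = params.get("k", 5)
        mask = np.zeros(shape, dtype=bool)
        idx = rng.choice(nr * nc, size=min(k, nr * nc), replace=False)
        mask.ravel()[idx] = True
        dummy = CellGrid(
            nr, nc, {c: np.zeros(shape) for c in DYNAMIC_CLASSES + (OTHERS,)},
            cell_side_km=cell_side_km,
        )
        return _standardize(aggregate_min_distance(mask, dummy))
    raise ValueError(f"unknown driver recipe kind {kind!r}")


def gen_mask(
    kind: str, params: Mapping, shape: tuple[int, int], rng: np.random.Generator
) -> np.ndarray:
    """One [0, 1] restriction mask (random blobs by default)."""
    if kind == "blobs":
        raw = gaussian_filter(rng.standard_normal(shape), params.get("sigma", 5.0), mode="nearest")
        thr = np.quantile(raw, params.get("quantile", 0.8))
        return (raw >= thr).astype(float)
    raise ValueError(f"unknown mask recipe kind {kind!r}")


def gen_lag_response(
    drivers: Mapping[str, np.ndarray],
    W: SpatialWeights,
    params: LagParams,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw y = (I − ρW)⁻¹(Xβ + ε) on the lattice (the exact lag DGP)."""
    lo, hi = W.rho_bounds()
    if not lo < params.rho < hi:
        raise ValueError(f"rho={params.rho} outside admissible interval ({lo:.3f}, {hi:.3f})")
    shape = W.shape
    n = shape[0] * shape[1]
    xb = np.full(n, params.intercept)
    for name, b in params.beta.items():
        xb = xb + b * np.asarray(drivers[name], dtype=float).ravel()
    eps = params.sigma * rng.standard_normal(n)
    A = sp.eye(n, format="csc") - params.rho * W.matrix.tocsc()
    y = spla.spsolve(A, xb + eps)
    return y.reshape(shape)


# ---------------------------------------------------------------------------
# landscapes and observed pairs
# ---------------------------------------------------------------------------


def gen_landscape(spec: SyntheticSpec) -> CellGrid:
    """Generate a full synthetic landscape (byte-identical under one seed)."""
    rng = np.random.default_rng(spec.seed)
    shape = (spec.n_rows, spec.n_cols)
    drivers = {
        name: gen_driver(kind, p, shape, spec.cell_side_km, rng)
        for name, (kind, p) in spec.driver_recipes.items()
    }
    masks = {
        name: gen_mask(kind, p, shape, rng)
        for name, (kind, p) in spec.mask_recipes.items()
    }
    zero = {c: np.zeros(shape) for c in DYNAMIC_CLASSES + (OTHERS,)}
    grid = CellGrid(
        spec.n_rows, spec.n_cols, zero, cell_side_km=spec.cell_side_km,
        drivers=drivers, masks=masks, year=2000,
    )
    W = build_weights(grid, spec.weights_scheme)
    latents = np.stack(
        [
            gen_lag_response(drivers, W, spec.true_params[c], rng).ravel()
            for c in DYNAMIC_CLASSES
        ]
    )
    t = spec.softmax_temperature
    # per-class offsets anchor the softmax means at the target composition
    shares = np.array([spec.class_shares[c] for c in DYNAMIC_CLASSES])
    shares = shares / shares.sum()
    z = latents / t + np.log(shares)[:, None]
    z -= z.max(axis=0, keepdims=True)
    expz = np.exp(z)
    share = (100.0 - spec.others_pct) * expz / expz.sum(axis=0, keepdims=True)
    for i, c in enumerate(DYNAMIC_CLASSES):
        grid.fractions[c] = share[i].reshape(shape)
    grid.fractions[OTHERS] = np.full(shape, spec.others_pct)
    grid.check()
    return grid


def true_potential_models(
    spec: SyntheticSpec,
    equilibrium_fractions: Mapping[str, float] | None = None,
) -> dict[str, PotentialModel]:
    """Wrap the spec's true lag parameters as fitted-model objects.

    Coefficients are rescaled by the softmax mapping's dynamic share so the
    implied predictions live on the fraction scale; used to drive forward
    runs with known ground truth.

    ``equilibrium_fractions`` gives the mean cell fraction (in [0, 1]) at
    which each class's model is in spatial equilibrium (prediction equals
    current use on average); the default is equal shares of the dynamic
    area.  Anchoring these at the scenario's endpoint areas keeps demands
    attainable over a long run — in the real application the calibrated
    potential and the externally computed demand are mutually consistent
    by construction, and the synthetic system emulates that.
    """
    scale = (100.0 - spec.others_pct) / 100.0 / len(DYNAMIC_CLASSES)
    models = {}
    for c in DYNAMIC_CLASSES:
        p = spec.true_params[c]
        eq = (
            float(equilibrium_fractions[c])
            if equilibrium_fractions is not None
            else scale
        )
        models[c] = PotentialModel(
            class_id=c,
            driver_names=list(p.beta),
            intercept=eq * (1.0 - p.rho),
            coefficients={k: scale * v for k, v in p.beta.items()},
            rho=p.rho,
            sigma2=p.sigma**2,
            p_values={k: 0.0 for k in list(p.beta) + ["intercept", "rho"]},
            pseudo_r2=1.0,
            aic=float("nan"),
            log_likelihood=float("nan"),
            n_obs=spec.n_rows * spec.n_cols,
        )
    return models


def anchored_true_models(
    spec: SyntheticSpec,
    grid: CellGrid,
    endpoints: Mapping[str, DemandEndpoint],
    overshoot: float = 1.0,
) -> dict[str, PotentialModel]:
    """True models whose equilibria sit past the scenario endpoint areas.

    Each class's spatial equilibrium is anchored at the endpoint area plus
    ``overshoot`` times the demanded net change, so the landscape is still
    mid-transition at the end year and directional potential persists for
    the whole run — the regression keeps "pointing" the way the scenario
    moves, as a model calibrated on the observed transition would.  Since
    the endpoint table conserves total area, the overshoot cancels in the
    class sum and the equilibria remain compositionally consistent.
    """
    denom = grid.n_valid * grid.cell_area_km2
    eq = {}
    for c in DYNAMIC_CLASSES:
        e = endpoints[c]
        target = e.final_area_km2 + overshoot * (e.final_area_km2 - e.initial_area_km2)
        eq[c] = max(target, 0.1 * e.final_area_km2) / denom
    return true_potential_models(spec, equilibrium_fractions=eq)


def synthetic_endpoints(
    grid: CellGrid,
    change_ratios: Mapping[str, float] | None = None,
    initial_year: int = 2000,
    final_year: int = 2010,
) -> dict[str, DemandEndpoint]:
    """Demand endpoints anchored at the landscape's actual initial areas.

    ``change_ratios`` maps class -> final/initial area ratio; the defaults
    are mild class-specific trends.  Final areas are renormalized so the
    total dynamic area is conserved exactly (area neither appears nor
    disappears nationally).
    """
    if change_ratios is None:
        change_ratios = {
            "forest_vegetation": 0.95,
            "grassland_vegetation": 0.92,
            "planted_pasture": 1.10,
            "agriculture": 1.12,
            "mosaic_of_occupation": 1.08,
            "forestry": 1.10,
        }
    areas0 = {c: grid.class_area_km2(c) for c in DYNAMIC_CLASSES}
    finals = {c: areas0[c] * change_ratios.get(c, 1.0) for c in DYNAMIC_CLASSES}
    correction = sum(areas0.values()) / sum(finals.values())
    return {
        c: DemandEndpoint(c, initial_year, final_year, areas0[c], finals[c] * correction)
        for c in DYNAMIC_CLASSES
    }


def gen_observed_pair(
    spec: SyntheticSpec,
    models: Mapping[str, PotentialModel] | None = None,
    config: ScenarioConfig | None = None,
) -> tuple[CellGrid, CellGrid, RunResult]:
    """Forward-run the engine to make an (observed t0, observed tf) pair.

    The final map is produced by the scenario engine itself from known true
    models and demands, so the pair carries exact ground truth for
    calibration-recovery and validation experiments.
    """
    t0 = gen_landscape(spec)
    if config is None:
        config = ScenarioConfig(
            name=f"synthetic-{spec.seed}",
            endpoints=synthetic_endpoints(t0),
            allocation=AllocationParams(allow_nonconvergence=True),
            seed=spec.seed,
        )
    if models is None:
        models = anchored_true_models(spec, t0, config.endpoints)
    W = build_weights(t0, spec.weights_scheme)
    run = run_scenario(t0, config, models, W)
    return t0, run.final(), run


def default_scenario_config(
    grid: CellGrid,
    name: str = "synthetic-ssp2",
    change_ratios: Mapping[str, float] | None = None,
    initial_year: int = 2000,
    final_year: int = 2050,
    protection_level: float = 0.5,
) -> ScenarioConfig:
    """A ready-to-run scenario shaped like the national ones.

    Demand endpoints follow the landscape's initial areas with the given
    50-year change ratios; the protected-area mask damps anthropic
    expansion at the given level from the start year.  The default level
    of 0.5 reflects the middle-of-the-road narrative, where protections
    exist but are partially honoured; full protection (1.0) combined with
    demands that can only be met inside protected cells makes allocation
    infeasible by construction, which the engine reports as
    non-convergence.
    """
    if change_ratios is None:
        # relative 2000->2050 changes of the middle-of-the-road narrative
        change_ratios = {
            "forest_vegetation": 2_975_314 / 3_771_677,
            "grassland_vegetation": 1_012_637 / 2_112_947,
            "planted_pasture": 670_850 / 402_529,
            "agriculture": 856_018 / 624_941,
            "mosaic_of_occupation": 2_788_498 / 1_405_301,
            "forestry": 70_060 / 55_983,
        }
    endpoints = synthetic_endpoints(grid, change_ratios, initial_year, final_year)
    masks = [
        MaskRule(initial_year, "protected", {"anthropic": protection_level})
    ] if "protected" in grid.masks else []
    return ScenarioConfig(name=name, endpoints=endpoints, mask_schedule=masks)
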