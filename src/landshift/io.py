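"""Readers and writers: NetCDF map stacks, cell tables, configs, manifests.

Percent of cell area (0–100) is the on-disk unit for all class fields,
mirroring the published map dataset; internal computation converts to
[0, 1] fractions where needed.  NetCDF output has dimensions
(time, y, x), one variable per class, a ``units: percent`` attribute and a
free-text projection tag (default EPSG:5880, the projected national grid).
Projection handling is metadata-only; synthetic lattices are abstract.
"""

from __future__ import annotations

import datetime
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import xarray as xr
import yaml

from . import __version__
from .grid import ALL_CLASSES, CellGrid, GridError
from .potential import PotentialModel
from .scenario import RunResult, ScenarioConfig

_STAT_TERMS = ("sigma2", "pseudo_r2", "aic", "log_likelihood", "n_obs")


# ---------------------------------------------------------------------------
# NetCDF map stacks
# ---------------------------------------------------------------------------


def write_netcdf(run: RunResult, path: str | Path, projection: str = "EPSG:5880") -> Path:
    """Write a run's yearly class-percentage maps to a NetCDF file."""
    if not run.snapshots:
        raise ValueError("run has no snapshots")
    years = run.years
    g0 = run.snapshots[years[0]]
    data = {}
    for cls in ALL_CLASSES:
        stack = np.stack([run.snapshots[y].fractions[cls] for y in years])
        data[cls] = xr.DataArray(
            stack.astype(np.float64),
            dims=("time", "y", "x"),
            attrs={"units": "percent", "long_name": f"percent of cell under {cls}"},
        )
    data["valid"] = xr.DataArray(
        g0.valid.astype(np.int8), dims=("y", "x"), attrs={"units": "1"}
    )
    ds = xr.Dataset(
        data,
        coords={
            "time": np.array(years, dtype=np.int32),
            "y": (np.arange(g0.n_rows) + 0.5) * g0.cell_side_km,
            "x": (np.arange(g0.n_cols) + 0.5) * g0.cell_side_km,
        },
        attrs={
            "cell_side_km": g0.cell_side_km,
            "projection": projection,
            "source": f"landshift {__version__}",
            **{f"provenance_{k}": str(v) for k, v in run.provenance.items()},
        },
    )
    path = Path(path)
    ds.to_netcdf(path, engine="scipy")
    return path


def read_netcdf(path: str | Path) -> dict[int, CellGrid]:
    """Read a map stack written by :func:`write_netcdf` back into grids."""
    with xr.open_dataset(path, engine="scipy") as ds:
        ds = ds.load()
    cell_side = float(ds.attrs.get("cell_side_km", 10.0))
    valid = (
        ds["valid"].values.astype(bool)
        if "valid" in ds
        else np.ones(ds[ALL_CLASSES[0]].shape[1:], dtype=bool)
    )
    grids: dict[int, CellGrid] = {}
    years = [int(t) for t in ds["time"].values]
    for i, year in enumerate(years):
        fractions = {
            cls: ds[cls].values[i].astype(float) for cls in ALL_CLASSES if cls in ds
        }
        nr, nc = next(iter(fractions.values())).shape
        grids[year] = CellGrid(
            nr, nc, fractions, cell_side_km=cell_side, valid=valid.copy(), year=year
        )
    return grids


# ---------------------------------------------------------------------------
# cell tables (CSV)
# ---------------------------------------------------------------------------


def write_cell_table(grid: CellGrid, path: str | Path) -> Path:
    """Write a per-cell CSV table (cell_id, row, col, fractions, drivers, masks)."""
    nr, nc = grid.shape
    rows, cols = np.meshgrid(np.arange(nr), np.arange(nc), indexing="ij")
    data = {
        "cell_id": np.arange(grid.n_cells),
        "row": rows.ravel(),
        "col": cols.ravel(),
        "valid": grid.valid.ravel().astype(int),
        "year": grid.year,
        "cell_side_km": grid.cell_side_km,
    }
    for cls in ALL_CLASSES:
        data[cls] = grid.fractions[cls].ravel()
    for name, f in grid.drivers.items():
        data[f"driver_{name}"] = np.asarray(f).ravel()
    for name, f in grid.masks.items():
        data[f"mask_{name}"] = np.asarray(f).ravel()
    path = Path(path)
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.10g")
    return path


def read_cell_table(path: str | Path) -> CellGrid:
    """Read a cell table back; compositional violations are hard errors."""
    df = pd.read_csv(path)
    required = ["row", "col", *ALL_CLASSES]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise GridError(f"cell table {path} lacks required columns: {missing}")
    nr = int(df["row"].max()) + 1
    nc = int(df["col"].max()) + 1
    if len(df) != nr * nc:
        raise GridError(
            f"cell table has {len(df)} rows; expected {nr * nc} for a {nr}x{nc} grid"
        )
    df = df.sort_values(["row", "col"]).reset_index(drop=True)
    shape = (nr, nc)
    fractions = {cls: df[cls].to_numpy(float).reshape(shape) for cls in ALL_CLASSES}
    drivers = {
        c.removeprefix("driver_"): df[c].to_numpy(float).reshape(shape)
        for c in df.columns
        if c.startswith("driver_")
    }
    masks = {
        c.removeprefix("mask_"): df[c].to_numpy(float).reshape(shape)
        for c in df.columns
        if c.startswith("mask_")
    }
    valid = (
        df["valid"].to_numpy(int).reshape(shape).astype(bool)
        if "valid" in df.columns
        else None
    )
    grid = CellGrid(
        nr,
        nc,
        fractions,
        cell_side_km=float(df["cell_side_km"].iloc[0]) if "cell_side_km" in df else 10.0,
        drivers=drivers,
        masks=masks,
        valid=valid,
        year=int(df["year"].iloc[0]) if "year" in df else 2000,
    )
    grid.check()
    return grid


# ---------------------------------------------------------------------------
# fitted-model coefficient tables
# ---------------------------------------------------------------------------


def write_models_csv(models: Mapping[str, PotentialModel], path: str | Path) -> Path:
    """Human-readable coefficients file: class, term, estimate, p_value."""
    rows = []
    for cls, m in models.items():
        rows.append({"class": cls, "term": "intercept", "estimate": m.intercept,
                     "p_value": m.p_values.get("intercept")})
        for d in m.driver_names:
            rows.append({"class": cls, "term": d, "estimate": m.coefficients[d],
                         "p_value": m.p_values.get(d)})
        rows.append({"class": cls, "term": "rho", "estimate": m.rho,
                     "p_value": m.p_values.get("rho")})
        for stat in _STAT_TERMS:
            rows.append({"class": cls, "term": stat, "estimate": getattr(m, stat),
                         "p_value": np.nan})
    path = Path(path)
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def read_models_csv(path: str | Path) -> dict[str, PotentialModel]:
    df = pd.read_csv(path)
    models: dict[str, PotentialModel] = {}
    for cls, sub in df.groupby("class", sort=False):
        terms = dict(zip(sub["term"], sub["estimate"]))
        pvals = dict(zip(sub["term"], sub["p_value"]))
        drivers = [
            t for t in sub["term"]
            if t not in ("intercept", "rho") and t not in _STAT_TERMS
        ]
        models[str(cls)] = PotentialModel(
            class_id=str(cls),
            driver_names=drivers,
            intercept=float(terms["intercept"]),
            coefficients={d: float(terms[d]) for d in drivers},
            rho=float(terms["rho"]),
            sigma2=float(terms.get("sigma2", np.nan)),
            p_values={
                k: float(v) for k, v in pvals.items()
                if k not in _STAT_TERMS and pd.notna(v)
            },
            pseudo_r2=float(terms.get("pseudo_r2", np.nan)),
            aic=float(terms.get("aic", np.nan)),
            log_likelihood=float(terms.get("log_likelihood", np.nan)),
            n_obs=int(terms.get("n_obs", 0)),
        )
    return models


# ---------------------------------------------------------------------------
# scenario config files
# ---------------------------------------------------------------------------


def save_config(config: ScenarioConfig, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
    return path


def load_config(path: str | Path) -> ScenarioConfig:
    with open(path) as fh:
        return ScenarioConfig.from_dict(yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# run manifests
# ---------------------------------------------------------------------------


def file_checksum(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


@dataclass
class RunManifest:
    """Provenance record emitted alongside every CLI run."""

    command: str
    version: str = __version__
    config_hash: str | None = None
    inputs: dict[str, str] = field(default_factory=dict)
    outputs: dict[str, str] = field(default_factory=dict)
    started: str = ""
    finished: str = ""
    warnings: list[str] = field(default_factory=list)

    def start(self) -> "RunManifest":
        self.started = datetime.datetime.now(datetime.timezone.utc).isoformat()
        return self

    def finish(self) -> "RunManifest":
        self.finished = datetime.datetime.now(datetime.timezone.utc).isoformat()
        return self

    def add_input(self, path: str | Path) -> None:
        self.inputs[str(path)] = file_checksum(path)

    def add_output(self, path: str | Path) -> None:
        self.outputs[str(path)] = file_checksum(path)

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2, default=str)
        return path
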