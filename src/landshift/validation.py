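"""Multi-resolution map-comparison validation.

Simulated change maps are compared with observed ones per class on the
fractional fields, three ways:

* a multi-resolution similarity NS computed in growing sampling windows —
  at window 1 it scores per-cell agreement of the simulated versus observed
  change; coarser windows aggregate change over w×w blocks before
  comparing, separating location error from pattern error;
* a two-part fit decomposition — agreement over the whole map ("patterns")
  and restricted to cells where observed change exceeded a threshold
  ("modified areas");
* omission / commission errors — observed change the simulation missed,
  and simulated change that did not occur, as percent of study area.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np


class ValidationError(ValueError):
    """Dimension or parameter error in validation inputs."""


@dataclass
class ValidationReport:
    """Table of agreement metrics for one class (all in percent)."""

    class_id: str
    ns_by_window: dict[int, float] = field(default_factory=dict)
    ns_raw_by_window: dict[int, float] = field(default_factory=dict)
    fit_patterns: float = np.nan
    fit_modified_areas: float | None = None
    omission_pct: float = np.nan
    commission_pct: float = np.nan


def _check_shapes(*fields2d: np.ndarray) -> tuple[np.ndarray, ...]:
    arrs = [np.asarray(f, dtype=float) for f in fields2d]
    if len({a.shape for a in arrs}) != 1:
        raise ValidationError(
            f"fields do not share a grid: shapes {[a.shape for a in arrs]}"
        )
    return tuple(arrs)


def _block_sums(a: np.ndarray, w: int) -> np.ndarray:
    """Sum over w×w blocks; edge blocks may be partial (no cell discarded)."""
    nr, nc = a.shape
    pr = (-nr) % w
    pc = (-nc) % w
    if pr or pc:
        a = np.pad(a, ((0, pr), (0, pc)))
    return a.reshape((nr + pr) // w, w, (nc + pc) // w, w).sum(axis=(1, 3))


def multires_similarity(
    real_t0: np.ndarray,
    real_tf: np.ndarray,
    sim_tf: np.ndarray,
    windows: tuple[int, ...] = (1, 2, 4, 8),
    valid: np.ndarray | None = None,
    clamp: bool = True,
) -> dict[int, float]:
    """Similarity (percent) between simulated and observed change per window.

    Per window size w the grid is partitioned into w×w blocks (edge blocks
    partial); per block the observed change Δreal = Σ(real_tf − real_t0)
    and simulated change Δsim = Σ(sim_tf − real_t0) are aggregated and

        NS_w = (1 − Σ_j |Δsim_j − Δreal_j| / (2 Σ_j |Δreal_j|)) × 100.

    When no block shows observed change, NS is 100 if the simulation also
    shows none, else 0.  Raw values can fall below 0 when simulated change
    overshoots by more than twice the observed total; with ``clamp`` they
    are reported clamped to [0, 100] (use ``clamp=False`` for raw values).
    """
    r0, rf, sf = _check_shapes(real_t0, real_tf, sim_tf)
    if any(w < 1 for w in windows):
        raise ValidationError("window sizes must be >= 1")
    dreal = rf - r0
    dsim = sf - r0
    if valid is not None:
        v = np.asarray(valid, dtype=bool)
        dreal = np.where(v, dreal, 0.0)
        dsim = np.where(v, dsim, 0.0)
    out: dict[int, float] = {}
    for w in windows:
        br = _block_sums(dreal, w)
        bs = _block_sums(dsim, w)
        denom = 2.0 * np.abs(br).sum()
        if denom == 0.0:
            ns = 100.0 if np.abs(bs).sum() == 0.0 else 0.0
        else:
            ns = (1.0 - np.abs(bs - br).sum() / denom) * 100.0
        out[w] = float(np.clip(ns, 0.0, 100.0)) if clamp else float(ns)
    return out


def fit_decomposition(
    real_t0: np.ndarray,
    real_tf: np.ndarray,
    sim_tf: np.ndarray,
    change_threshold: float = 0.0,
    valid: np.ndarray | None = None,
) -> tuple[float, float | None]:
    """Map-level agreement over all cells and over observed-change cells.

    ``fit_patterns`` scores agreement of the simulated final map with the
    observed final map over every valid cell; ``fit_modified_areas`` is the
    same statistic restricted to cells whose observed change exceeds the
    threshold (percent of cell).  With no such cell the modified-area fit
    is undefined and reported as None with a warning.
    """
    if change_threshold < 0:
        raise ValidationError("change_threshold must be >= 0")
    r0, rf, sf = _check_shapes(real_t0, real_tf, sim_tf)
    v = (
        np.ones(r0.shape, dtype=bool)
        if valid is None
        else np.asarray(valid, dtype=bool)
    )

    def agreement(mask: np.ndarray) -> float:
        denom = 2.0 * max(rf[mask].sum(), 1e-300)
        return float(np.clip((1.0 - np.abs(sf[mask] - rf[mask]).sum() / denom) * 100.0, 0.0, 100.0))

    fit_patterns = agreement(v)
    changed = v & (np.abs(rf - r0) > change_threshold)
    if not changed.any():
        warnings.warn("no cell exceeds the change threshold; modified-area fit undefined")
        return fit_patterns, None
    return fit_patterns, agreement(changed)


def omission_commission(
    real_t0: np.ndarray,
    real_tf: np.ndarray,
    sim_tf: np.ndarray,
    change_threshold: float = 0.0,
    valid: np.ndarray | None = None,
) -> tuple[float, float]:
    """Missed and spurious change as percent of total study area.

    Per cell, omission is the positive part of (|Δreal| − |Δsim|) — observed
    change magnitude the simulation failed to produce — and commission the
    positive part of (|Δsim| − |Δreal|); both are summed over valid cells
    and divided by the study area.  Changes at or below the threshold are
    ignored.
    """
    if change_threshold < 0:
        raise ValidationError("change_threshold must be >= 0")
    r0, rf, sf = _check_shapes(real_t0, real_tf, sim_tf)
    v = (
        np.ones(r0.shape, dtype=bool)
        if valid is None
        else np.asarray(valid, dtype=bool)
    )
    dreal = np.abs(rf - r0)[v]
    dsim = np.abs(sf - r0)[v]
    dreal = np.where(dreal > change_threshold, dreal, 0.0)
    dsim = np.where(dsim > change_threshold, dsim, 0.0)
    n = max(v.sum(), 1)
    omission = float(np.clip(dreal - dsim, 0.0, None).sum() / n)
    commission = float(np.clip(dsim - dreal, 0.0, None).sum() / n)
    return omission, commission


def validate_class(
    real_t0: np.ndarray,
    real_tf: np.ndarray,
    sim_tf: np.ndarray,
    class_id: str = "",
    windows: tuple[int, ...] = (1, 2, 4, 8),
    change_threshold: float = 0.0,
    valid: np.ndarray | None = None,
) -> ValidationReport:
    """Full agreement report for one class (percent-of-cell fields)."""
    report = ValidationReport(class_id=class_id)
    report.ns_by_window = multires_similarity(
        real_t0, real_tf, sim_tf, windows, valid=valid, clamp=True
    )
    report.ns_raw_by_window = multires_similarity(
        real_t0, real_tf, sim_tf, windows, valid=valid, clamp=False
    )
    report.fit_patterns, report.fit_modified_areas = fit_decomposition(
        real_t0, real_tf, sim_tf, change_threshold, valid=valid
    )
    report.omission_pct, report.commission_pct = omission_commission(
        real_t0, real_tf, sim_tf, change_threshold, valid=valid
    )
    return report
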