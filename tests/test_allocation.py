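"""Iterative demand-constrained allocation with per-cell class competition."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from landshift.allocation import (
    AllocationError,
    AllocationParams,
    allocate_year,
    rebalance_cell,
)
from landshift.grid import ALL_CLASSES, DYNAMIC_CLASSES, OTHERS
from landshift.potential import PotentialSurface

from conftest import make_uniform_grid


def flat_potentials(grid, values: dict[str, float]):
    return {
        c: PotentialSurface(c, grid.year + 1, np.full(grid.shape, values.get(c, 0.0)))
        for c in DYNAMIC_CLASSES
    }


def areas(grid):
    return {c: grid.class_area_km2(c) for c in DYNAMIC_CLASSES}


class TestRebalanceCell:
    def test_balanced_swap_unchanged(self):
        fr = {c: 15.0 for c in DYNAMIC_CLASSES} | {OTHERS: 10.0}
        deltas = {"forest_vegetation": 10.0, "agriculture": -10.0}
        out = rebalance_cell(fr, deltas)
        assert out["forest_vegetation"] == pytest.approx(10.0)
        assert out["agriculture"] == pytest.approx(-10.0)
        assert sum(out.values()) == pytest.approx(0.0)

    def test_excess_gains_scaled_proportionally(self):
        fr = {c: 15.0 for c in DYNAMIC_CLASSES} | {OTHERS: 10.0}
        deltas = {"planted_pasture": 10.0, "agriculture": 10.0,
                  "grassland_vegetation": -5.0}
        out = rebalance_cell(fr, deltas)
        assert out["planted_pasture"] == pytest.approx(2.5)
        assert out["agriculture"] == pytest.approx(2.5)
        assert out["grassland_vegetation"] == pytest.approx(-5.0)

    def test_all_zero_deltas_identity(self):
        fr = {c: 15.0 for c in DYNAMIC_CLASSES} | {OTHERS: 10.0}
        out = rebalance_cell(fr, {})
        assert all(v == 0.0 for v in out.values())

    def test_loss_clipped_at_available_fraction(self):
        fr = {c: 15.0 for c in DYNAMIC_CLASSES} | {OTHERS: 10.0}
        fr["forestry"] = 2.0
        fr["forest_vegetation"] = 28.0
        out = rebalance_cell(fr, {"forestry": -10.0, "agriculture": 10.0})
        assert out["forestry"] == pytest.approx(-2.0)
        assert out["agriculture"] == pytest.approx(2.0)

    @settings(max_examples=100, deadline=None)
    @given(
        data=st.lists(
            st.tuples(st.floats(0, 20, allow_nan=False),
                      st.floats(-15, 15, allow_nan=False)),
            min_size=6, max_size=6,
        )
    )
    def test_output_feasible_and_conservative(self, data):
        """Adjusted deltas sum to zero and never push a fraction out of range."""
        fr_vals = [f for f, _ in data]
        total = sum(fr_vals)
        if total < 1e-6:
            return
        scale = 90.0 / total
        fr = {c: f * scale for c, (f, _) in zip(DYNAMIC_CLASSES, data)}
        fr[OTHERS] = 10.0
        deltas = {c: d for c, (_, d) in zip(DYNAMIC_CLASSES, data)}
        out = rebalance_cell(fr, deltas)
        assert sum(out.values()) == pytest.approx(0.0, abs=1e-9)
        for c in DYNAMIC_CLASSES:
            newv = fr[c] + out[c]
            assert -1e-9 <= newv <= 90.0 + 1e-9


class TestAllocateYear:
    def test_equilibrium_demand_converges_immediately(self, uniform_grid):
        demand = areas(uniform_grid)
        pots = flat_potentials(uniform_grid, {c: 0.3 for c in DYNAMIC_CLASSES})
        out, report = allocate_year(uniform_grid, pots, demand)
        assert report.converged and report.iterations == 1
        for c in ALL_CLASSES:
            np.testing.assert_array_equal(out.fractions[c], uniform_grid.fractions[c])

    def test_uniform_transfer_distributed_uniformly(self):
        """Symmetric potentials and headroom spread the change evenly."""
        g = make_uniform_grid(10, 10)
        demand = areas(g)
        shift = 0.02 * demand["agriculture"]
        demand["agriculture"] += shift
        demand["grassland_vegetation"] -= shift
        pots = flat_potentials(g, {"agriculture": 0.5, "grassland_vegetation": -0.5})
        out, report = allocate_year(g, pots, demand)
        assert report.converged
        agri = out.fractions["agriculture"]
        assert np.ptp(agri) < 1e-9  # identical gain in every cell
        assert out.class_area_km2("agriculture") == pytest.approx(
            demand["agriculture"], abs=0.005 * g.total_area_km2
        )

    def test_infeasible_growth_raises_with_report(self, uniform_grid):
        demand = areas(uniform_grid)
        shift = 0.05 * demand["forestry"]
        demand["forestry"] += shift
        demand["agriculture"] -= shift
        # forestry demanded to grow but its potential is negative everywhere
        pots = flat_potentials(
            uniform_grid, {"forestry": -0.5, "agriculture": -0.5}
        )
        params = AllocationParams(max_iterations=50)
        with pytest.raises(AllocationError) as exc:
            allocate_year(uniform_grid, pots, demand, params)
        assert not exc.value.report.converged
        assert exc.value.report.gaps_km2["forestry"] < 0

    def test_nonconvergence_accepted_with_flag(self, uniform_grid):
        demand = areas(uniform_grid)
        shift = 0.05 * demand["forestry"]
        demand["forestry"] += shift
        demand["agriculture"] -= shift
        pots = flat_potentials(uniform_grid, {"forestry": -0.5})
        params = AllocationParams(max_iterations=20, allow_nonconvergence=True)
        with pytest.warns(UserWarning, match="did not converge"):
            out, report = allocate_year(uniform_grid, pots, demand, params)
        assert not report.converged

    def test_demand_total_mismatch_rejected(self, uniform_grid):
        demand = areas(uniform_grid)
        demand["agriculture"] *= 2  # total no longer conserved
        pots = flat_potentials(uniform_grid, {})
        with pytest.raises(ValueError, match="demand total"):
            allocate_year(uniform_grid, pots, demand)

    def test_others_fraction_bit_identical(self):
        rng = np.random.default_rng(5)
        g = make_uniform_grid(8, 8)
        demand = areas(g)
        shift = 0.01 * demand["forest_vegetation"]
        demand["mosaic_of_occupation"] += shift
        demand["forest_vegetation"] -= shift
        pots = flat_potentials(g, {"mosaic_of_occupation": 0.4,
                                   "forest_vegetation": -0.4})
        for c in DYNAMIC_CLASSES:
            pots[c].values += 0.05 * rng.standard_normal(g.shape)
        out, _ = allocate_year(g, pots, demand)
        assert np.array_equal(out.fractions[OTHERS], g.fractions[OTHERS])

    def test_cell_sums_conserved_after_allocation(self):
        rng = np.random.default_rng(6)
        g = make_uniform_grid(8, 8)
        demand = areas(g)
        shift = 0.02 * demand["agriculture"]
        demand["agriculture"] += shift
        demand["grassland_vegetation"] -= shift
        pots = flat_potentials(g, {"agriculture": 0.3,
                                   "grassland_vegetation": -0.3})
        for c in DYNAMIC_CLASSES:
            pots[c].values += 0.1 * rng.standard_normal(g.shape)
        out, report = allocate_year(g, pots, demand)
        assert report.converged
        total = sum(out.fractions[c] for c in ALL_CLASSES)
        np.testing.assert_allclose(total, 100.0, atol=1e-6)

    def test_raising_potential_never_reduces_local_gain(self):
        """Monotone response of a growing class to its own potential."""
        g = make_uniform_grid(6, 6)
        demand = areas(g)
        shift = 0.02 * demand["agriculture"]
        demand["agriculture"] += shift
        demand["grassland_vegetation"] -= shift
        rng = np.random.default_rng(7)
        base = {
            "agriculture": 0.2 + 0.1 * rng.random(g.shape),
            "grassland_vegetation": -0.5 * np.ones(g.shape),
        }
        pots = flat_potentials(g, {})
        for c, v in base.items():
            pots[c] = PotentialSurface(c, 2001, np.asarray(v))
        out1, _ = allocate_year(g, pots, demand)
        gain1 = out1.fractions["agriculture"][3, 3] - g.fractions["agriculture"][3, 3]
        pots["agriculture"] = PotentialSurface(
            "agriculture", 2001, base["agriculture"].copy()
        )
        pots["agriculture"].values[3, 3] *= 2.0
        out2, _ = allocate_year(g, pots, demand)
        gain2 = out2.fractions["agriculture"][3, 3] - g.fractions["agriculture"][3, 3]
        assert gain2 >= gain1 - 1e-12

    def test_anthropic_cap_respected(self):
        g = make_uniform_grid(5, 5)
        demand = areas(g)
        shift = 0.03 * demand["agriculture"]
        demand["agriculture"] += shift
        demand["forest_vegetation"] -= shift
        pots = flat_potentials(g, {"agriculture": 0.6, "forest_vegetation": -0.6})
        cap = 61.0  # initial anthropic share is 60%
        out, report = allocate_year(
            g, pots, demand,
            AllocationParams(anthropic_cap=cap, allow_nonconvergence=True,
                             max_iterations=100),
        )
        from landshift.grid import ANTHROPIC_CLASSES

        anth = sum(out.fractions[c] for c in ANTHROPIC_CLASSES)
        assert anth.max() <= cap + 1e-9

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            AllocationParams(max_error=0.0)
        with pytest.raises(ValueError):
            AllocationParams(itf_gain=3.0)
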