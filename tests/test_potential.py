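"""Spatial-lag potential component: screening, estimation, selection, surfaces."""

import numpy as np
import pytest

from landshift.grid import build_weights
from landshift.potential import (
    CollinearityError,
    MaskRule,
    PotentialError,
    PotentialSurface,
    apply_restrictions,
    compute_potential,
    fit_spatial_lag,
    select_model,
    spearman_screen,
)
from landshift.synthetic import LagParams, gen_lag_response

from conftest import make_uniform_grid


class TestSpearmanScreen:
    def test_identical_fields_leave_one(self):
        rng = np.random.default_rng(0)
        a = rng.random(400)
        kept = spearman_screen({"a": a, "b": a.copy()})
        assert len(kept) == 1

    def test_independent_noise_fields_both_retained(self):
        rng = np.random.default_rng(1)
        kept = spearman_screen({"a": rng.random(400), "b": rng.random(400)})
        assert sorted(kept) == ["a", "b"]

    def test_single_candidate_retained_unconditionally(self):
        assert spearman_screen({"only": np.arange(9.0)}) == ["only"]

    def test_constant_field_warns_and_survives(self):
        rng = np.random.default_rng(2)
        with pytest.warns(UserWarning, match="constant"):
            kept = spearman_screen(
                {"flat": np.ones(50), "x": rng.random(50)}, threshold=0.6
            )
        assert sorted(kept) == ["flat", "x"]

    def test_retained_pairs_all_below_threshold(self):
        rng = np.random.default_rng(3)
        base = rng.random(500)
        cands = {
            "a": base,
            "b": base + 0.05 * rng.random(500),  # nearly a duplicate of a
            "c": rng.random(500),
            "d": -base + 0.05 * rng.random(500),  # nearly -a
        }
        kept = spearman_screen(cands, threshold=0.6)
        from scipy.stats import spearmanr

        for i, ni in enumerate(kept):
            for nj in kept[i + 1:]:
                rho = spearmanr(cands[ni], cands[nj]).statistic
                assert abs(rho) <= 0.6


class TestFitSpatialLag:
    def test_reduces_to_ols_when_rho_is_zero(self, landscape, landscape_weights):
        """With no spatial process the ML fit collapses onto least squares."""
        rng = np.random.default_rng(10)
        g, W = landscape, landscape_weights
        X = np.column_stack([
            np.ones(g.n_cells),
            g.drivers["suitability"].ravel(),
            g.drivers["water_deficit"].ravel(),
        ])
        y = (X @ np.array([0.5, 1.0, -2.0])
             + 1e-4 * rng.standard_normal(g.n_cells)).reshape(g.shape)
        m = fit_spatial_lag(y, g.drivers, W,
                            driver_names=["suitability", "water_deficit"])
        beta_ols = np.linalg.lstsq(X, y.ravel(), rcond=None)[0]
        assert abs(m.rho) < 1e-4
        np.testing.assert_allclose(m.beta(), beta_ols, atol=1e-4)

    def test_recovers_moderate_spatial_dependence(self, landscape, landscape_weights):
        """Single replicate of the ρ = 0.5 recovery experiment."""
        rng = np.random.default_rng(11)
        p = LagParams(rho=0.5, beta={"suitability": 1.0, "water_deficit": 2.0},
                      intercept=0.3, sigma=0.1)
        y = gen_lag_response(landscape.drivers, landscape_weights, p, rng)
        m = fit_spatial_lag(y, landscape.drivers, landscape_weights,
                            driver_names=["suitability", "water_deficit"])
        assert m.rho == pytest.approx(0.5, abs=0.05)
        assert m.coefficients["suitability"] == pytest.approx(1.0, rel=0.05)
        assert m.coefficients["water_deficit"] == pytest.approx(2.0, rel=0.05)
        assert m.p_values["suitability"] < 0.05
        assert m.aic == pytest.approx(2 * (len(m.driver_names) + 3)
                                      - 2 * m.log_likelihood)

    def test_loglik_at_optimum_dominates_ols_submodel(self, small_landscape,
                                                      small_weights):
        rng = np.random.default_rng(12)
        p = LagParams(rho=0.4, beta={"suitability": 1.0}, sigma=0.2)
        y = gen_lag_response(small_landscape.drivers, small_weights, p, rng)
        m = fit_spatial_lag(y, small_landscape.drivers, small_weights,
                            driver_names=["suitability"])
        # profile likelihood at rho=0 (the nested OLS model)
        idx = small_weights.valid.ravel()
        yv = y.ravel()[idx]
        X = np.column_stack([np.ones(idx.sum()),
                             small_landscape.drivers["suitability"].ravel()[idx]])
        e = yv - X @ np.linalg.lstsq(X, yv, rcond=None)[0]
        n = len(yv)
        ll0 = -0.5 * n * (np.log(2 * np.pi * (e @ e) / n) + 1)
        assert m.log_likelihood >= ll0 - 1e-9

    def test_loglik_matches_dense_brute_force(self, small_landscape, small_weights):
        """Oracle equivalence: dense slogdet likelihood over a ρ grid."""
        rng = np.random.default_rng(13)
        p = LagParams(rho=0.3, beta={"suitability": 0.8, "dist_roads": -0.5},
                      sigma=0.15)
        g, W = small_landscape, small_weights
        y = gen_lag_response(g.drivers, W, p, rng)
        m = fit_spatial_lag(y, g.drivers, W,
                            driver_names=["suitability", "dist_roads"])
        # independent dense implementation of the concentrated likelihood
        Wd = W.matrix.toarray()
        yv = y.ravel()
        X = np.column_stack([np.ones(g.n_cells),
                             g.drivers["suitability"].ravel(),
                             g.drivers["dist_roads"].ravel()])
        n = g.n_cells

        def dense_conc_ll(rho):
            z = yv - rho * (Wd @ yv)
            b = np.linalg.lstsq(X, z, rcond=None)[0]
            e = z - X @ b
            s2 = (e @ e) / n
            sign, logdet = np.linalg.slogdet(np.eye(n) - rho * Wd)
            assert sign > 0
            return -0.5 * n * (np.log(2 * np.pi * s2) + 1) + logdet

        # fitted optimum reproduces the dense value at the fitted rho ...
        assert m.log_likelihood == pytest.approx(dense_conc_ll(m.rho), abs=1e-6)
        # ... and no grid point beats it
        grid = np.linspace(-0.9, 0.95, 75)
        assert m.log_likelihood >= max(dense_conc_ll(r) for r in grid) - 1e-6

    def test_collinear_design_names_offenders(self, small_landscape, small_weights):
        g = small_landscape
        drivers = dict(g.drivers)
        drivers["dup"] = drivers["suitability"] * 2.0
        y = g.fractions["agriculture"] / 100.0
        with pytest.raises(CollinearityError, match="dup|suitability"):
            fit_spatial_lag(y, drivers, small_weights,
                            driver_names=["suitability", "dup"])


class TestSelectModel:
    def test_single_candidate_returned(self, small_landscape, small_weights):
        rng = np.random.default_rng(14)
        p = LagParams(rho=0.3, beta={"suitability": 1.0}, sigma=0.1)
        y = gen_lag_response(small_landscape.drivers, small_weights, p, rng)
        m = select_model("agriculture", y, small_landscape.drivers,
                         [["suitability"]], small_weights)
        assert m.driver_names == ["suitability"]
        assert m.p_compliant

    def test_noise_driver_loses_on_aic(self, small_landscape, small_weights):
        """A specification with an extra pure-noise driver should not win."""
        rng = np.random.default_rng(15)
        drivers = dict(small_landscape.drivers)
        drivers["noise"] = rng.standard_normal(small_landscape.shape)
        p = LagParams(rho=0.3, beta={"suitability": 1.0}, sigma=0.1)
        y = gen_lag_response(drivers, small_weights, p, rng)
        m = select_model("agriculture", y, drivers,
                         [["suitability"], ["suitability", "noise"]],
                         small_weights)
        assert m.driver_names == ["suitability"]

    def test_all_fail_p_filter_returns_flagged_model(self, small_landscape,
                                                     small_weights):
        rng = np.random.default_rng(17)
        drivers = dict(small_landscape.drivers)
        drivers["noise1"] = rng.standard_normal(small_landscape.shape)
        drivers["noise2"] = rng.standard_normal(small_landscape.shape)
        y = rng.standard_normal(small_landscape.shape)  # unrelated response
        with pytest.warns(UserWarning, match="non-compliant"):
            m = select_model("forestry", y, drivers, [["noise1"], ["noise2"]],
                             small_weights)
        assert not m.p_compliant

    def test_never_returns_p_violating_model_when_one_passes(
        self, small_landscape, small_weights
    ):
        rng = np.random.default_rng(17)
        drivers = dict(small_landscape.drivers)
        drivers["noise"] = rng.standard_normal(small_landscape.shape)
        p = LagParams(rho=0.3, beta={"suitability": 1.0}, sigma=0.1)
        y = gen_lag_response(drivers, small_weights, p, rng)
        m = select_model("agriculture", y, drivers,
                         [["noise"], ["suitability"]], small_weights)
        assert all(m.p_values[d] < 0.05 for d in m.driver_names)


class TestComputePotential:
    def _model(self, rho=0.0, intercept=0.0, coefs=None):
        from landshift.potential import PotentialModel

        coefs = coefs or {}
        return PotentialModel(
            class_id="agriculture", driver_names=list(coefs),
            intercept=intercept, coefficients=coefs, rho=rho, sigma2=0.01,
            p_values={}, pseudo_r2=1.0, aic=0.0, log_likelihood=0.0, n_obs=16,
        )

    def test_equilibrium_prediction_gives_zero_surface(self):
        g = make_uniform_grid(4, 4)
        W = build_weights(g)
        # rho=1·Wy reproduces the uniform field; intercept 0
        m = self._model(rho=1.0)
        # uniform landscape: W y == y, so yhat == y
        surf = compute_potential(m, g, W)
        np.testing.assert_allclose(surf.values, 0.0, atol=1e-12)

    def test_prediction_above_headroom_clamps_to_one(self):
        g = make_uniform_grid(3, 3)
        g.drivers["push"] = np.ones((3, 3))
        m = self._model(intercept=1.3, coefs={"push": 0.2})  # yhat = 1.5
        surf = compute_potential(m, g, W=build_weights(g))
        np.testing.assert_allclose(surf.values, 1.0)

    def test_zero_rho_surface_is_xbeta_minus_current(self):
        g = make_uniform_grid(3, 3)
        rng = np.random.default_rng(18)
        g.drivers["x"] = rng.random((3, 3))
        m = self._model(intercept=0.1, coefs={"x": 0.5})
        surf = compute_potential(m, g, build_weights(g))
        expected = np.clip(0.1 + 0.5 * g.drivers["x"]
                           - g.fractions["agriculture"] / 100.0, -1, 1)
        np.testing.assert_allclose(surf.values, expected)

    def test_missing_driver_rejected(self):
        g = make_uniform_grid(2, 2)
        m = self._model(coefs={"absent": 1.0})
        with pytest.raises(PotentialError, match="absent"):
            compute_potential(m, g, build_weights(g))

    def test_values_always_within_unit_band(self, landscape, landscape_weights):
        m = self._model(rho=0.9, intercept=5.0, coefs={"suitability": 3.0})
        surf = compute_potential(m, landscape, landscape_weights)
        assert surf.values.min() >= -1.0 and surf.values.max() <= 1.0


class TestApplyRestrictions:
    def _surface(self, values):
        return PotentialSurface("agriculture", 2025, np.asarray(values, float))

    def test_full_protection_zeroes_positive_potential(self):
        surf = self._surface([[0.5, -0.4]])
        masks = {"pa": np.array([[1.0, 1.0]])}
        out = apply_restrictions(
            surf, masks, [MaskRule(2000, "pa", {"anthropic": 1.0})], 2025
        )
        assert out.values[0, 0] == 0.0
        assert out.values[0, 1] == -0.4  # regeneration unaffected

    def test_zero_protection_is_identity(self):
        surf = self._surface([[0.5, -0.4]])
        masks = {"pa": np.array([[1.0, 1.0]])}
        out = apply_restrictions(
            surf, masks, [MaskRule(2000, "pa", {"anthropic": 0.0})], 2025
        )
        np.testing.assert_allclose(out.values, surf.values)

    def test_unrestricted_class_untouched(self):
        surf = PotentialSurface("forest_vegetation", 2025, np.array([[0.5]]))
        masks = {"pa": np.array([[1.0]])}
        out = apply_restrictions(
            surf, masks, [MaskRule(2000, "pa", {"anthropic": 1.0})], 2025
        )
        assert out.values[0, 0] == 0.5

    def test_protection_drop_raises_masked_potential(self):
        """Weakening protection mid-run releases expansion potential."""
        surf = self._surface([[0.6]])
        masks = {"pa": np.array([[1.0]])}
        schedule = [
            MaskRule(2000, "pa", {"anthropic": 1.0}),
            MaskRule(2030, "pa", {"anthropic": 0.4}),
        ]
        before = apply_restrictions(surf, masks, schedule, 2029).values[0, 0]
        after = apply_restrictions(surf, masks, schedule, 2030).values[0, 0]
        assert after > before
        assert after == pytest.approx(0.6 * 0.6)

    def test_mask_outside_unit_interval_rejected(self):
        surf = self._surface([[0.5]])
        masks = {"pa": np.array([[1.5]])}
        with pytest.raises(PotentialError, match="outside"):
            apply_restrictions(
                surf, masks, [MaskRule(2000, "pa", {"anthropic": 1.0})], 2025
            )
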