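"""Cohort growth, allocation, self-thinning and ring bookkeeping."""

import math

import numpy as np
import pytest

from ringdemog.demography import (
    AllometryParams,
    Cohort,
    NppParams,
    Patch,
    SimulatorConfig,
    allocate,
    allometric_crown_area,
    allometric_height,
    annual_npp,
    canopy_closure_year,
    grow_year,
    ring_density_for_year,
    self_thin,
    simulate_stand,
    solve_allocation,
    stem_density_summaries,
)
from ringdemog.response import DensityResponse, flat_response_for_density
from ringdemog.synth import DEFAULT_RANGE_RESPONSE

AL = AllometryParams()
STATIC = SimulatorConfig(mode="static")


class TestAllometry:
    def test_zero_diameter(self):
        assert allometric_height(0.0) == 0.0

    def test_reference_height(self):
        # independent evaluation: 40 * exp(0.67 * ln 0.25)
        expected = 40.0 * math.exp(0.67 * math.log(0.25))
        assert allometric_height(0.25) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(15.81, abs=0.03)

    def test_crown_area_capped(self):
        assert allometric_crown_area(5.0) == AL.ca_max

    def test_negative_diameter_rejected(self):
        with pytest.raises(ValueError):
            allometric_height(-0.1)


class TestRingDensityForYear:
    def test_static_ignores_temperature(self):
        for t in (5.0, 10.0, 15.0):
            assert ring_density_for_year(t, STATIC) == 186.0

    def test_flat_dynamic_matches_static(self):
        cfg = SimulatorConfig(mode="dynamic", response=flat_response_for_density(186.0))
        for t in (-5.0, 11.5, 30.0):
            assert ring_density_for_year(t, cfg) == 186.0

    def test_midpoint_closed_form(self):
        resp = DensityResponse(a=240.0, b=350.0, c=0.8, d=11.5)
        cfg = SimulatorConfig(mode="dynamic", response=resp)
        expected = 0.7 * 139.0 + 0.3 * (resp.a + resp.b) / 2.0
        assert ring_density_for_year(resp.d, cfg) == pytest.approx(expected)


class TestAnnualNpp:
    def _patch(self, c_leaf=1.0, n=0.02):
        cohort = Cohort.plant(STATIC, n, 186.0)
        cohort.c_leaf = c_leaf
        return cohort, Patch(cohorts=[cohort])

    def test_zero_leaf_carbon_zero_npp(self):
        cohort, patch = self._patch(c_leaf=0.0)
        assert annual_npp(cohort, patch, 12.0, STATIC) == 0.0

    def test_shading_reduces_per_tree_npp(self):
        cohort, patch = self._patch(n=0.02)
        dense_cohort, dense = self._patch(n=0.08)  # same leaf area per tree, higher LAI
        assert annual_npp(dense_cohort, dense, 12.0, STATIC) < annual_npp(cohort, patch, 12.0, STATIC)

    def test_temperature_optimum_is_maximal(self):
        cohort, patch = self._patch()
        at_opt = annual_npp(cohort, patch, STATIC.npp_params.t_opt, STATIC)
        for t in (-5.0, 5.0, 20.0, 30.0):
            assert annual_npp(cohort, patch, t, STATIC) <= at_opt


class TestAllocate:
    def _cohort(self):
        return Cohort.plant(STATIC, 0.02, 186.0, diameter=0.1)

    def test_zero_growth_zero_ring(self):
        cohort = self._cohort()
        state = (cohort.diameter, cohort.c_leaf, cohort.c_root, cohort.c_sap)
        ring = allocate(cohort, 0.0, 186.0, AL)
        assert ring.width == 0.0 and ring.volume == 0.0 and ring.carbon == 0.0
        assert (cohort.diameter, cohort.c_leaf, cohort.c_root, cohort.c_sap) == state

    def test_carbon_balance(self):
        cohort = self._cohort()
        growth = 5.0
        before = cohort.c_leaf + cohort.c_root + cohort.c_sap
        allocate(cohort, growth, 186.0, AL)
        after = cohort.c_leaf + cohort.c_root + cohort.c_sap
        assert after - before == pytest.approx(growth, rel=1e-9)

    def test_denser_wood_buys_less_diameter(self):
        widths = {}
        for rho in (150.0, 250.0):
            cohort = self._cohort()
            ring = allocate(cohort, 5.0, rho, AL)
            widths[rho] = ring.width
        assert widths[250.0] < widths[150.0]

    def test_bisection_agrees_with_grid_search(self):
        # brute-force oracle: scan diameter increments at 1e-6 resolution and
        # keep the one whose total cost is closest to the carbon supplied
        cohort = self._cohort()
        growth, rho = 5.0, 200.0
        d0, h0, a0, l0, r0 = cohort.diameter, cohort.height, cohort.sap_area, cohort.c_leaf, cohort.c_root

        def cost(dd):
            dn = d0 + dd
            hn = AL.k_height * dn**AL.k_height_exp
            dv = 0.25 * math.pi * (dn * dn * hn - d0 * d0 * h0)
            sap = a0 + 0.25 * math.pi * (dn * dn - d0 * d0)
            leaf_t = AL.k_latosa * sap / AL.sla
            return rho * dv + max(leaf_t - l0, 0.0) + max(AL.root_leaf_ratio * leaf_t - r0, 0.0)

        grid = np.arange(0.0, 0.05, 1e-6)
        costs = np.array([cost(g) for g in grid])
        oracle = grid[np.argmin(np.abs(costs - growth))]
        ring = allocate(cohort, growth, rho, AL)
        assert 2.0 * ring.width == pytest.approx(oracle, abs=2e-6)

    def test_infeasible_growth_goes_to_leaves_and_roots(self):
        cohort = self._cohort()
        cohort.c_leaf *= 0.1  # large leaf deficit
        cohort.c_root *= 0.1
        tiny = 1e-6
        ring = allocate(cohort, tiny, 186.0, AL)
        assert ring.width == 0.0
        # the carbon still ends up in the compartments
        assert cohort.c_leaf + cohort.c_root == pytest.approx(
            0.1 * Cohort.plant(STATIC, 0.02, 186.0, diameter=0.1).c_leaf * 2 + tiny, rel=1e-6
        )

    def test_negative_growth_rejected(self):
        with pytest.raises(ValueError):
            allocate(self._cohort(), -1.0, 186.0, AL)


class TestGrowYear:
    def test_flat_dynamic_equals_static_exactly(self):
        flat = SimulatorConfig(mode="dynamic", response=flat_response_for_density(186.0))
        ps, pd_ = [], []
        for cfg, store in ((STATIC, ps), (flat, pd_)):
            cohort = Cohort.plant(cfg, 0.02, float(ring_density_for_year(12.0, cfg)))
            patch = Patch(cohorts=[cohort])
            for t in (10.0, 12.0, 14.0, 9.0, 13.0):
                grow_year(patch, t, cfg)
            store.extend([cohort.diameter, cohort.height, cohort.n_per_m2, cohort.cwood, cohort.c_leaf])
        assert ps == pd_

    def test_tree_count_never_increases(self):
        cohort = Cohort.plant(STATIC, 0.02, 186.0)
        patch = Patch(cohorts=[cohort])
        counts = []
        for t in np.linspace(10, 14, 30):
            grow_year(patch, float(t), STATIC)
            counts.append(cohort.n_per_m2)
        assert all(b <= a for a, b in zip(counts, counts[1:]))

    def test_canopy_fraction_bounded_after_each_year(self):
        cohort = Cohort.plant(STATIC, 0.05, 186.0, diameter=0.3)
        patch = Patch(cohorts=[cohort])
        for t in np.linspace(11, 13, 40):
            diag = grow_year(patch, float(t), STATIC)
            assert diag["canopy_fraction"] <= 1.0 + 1e-12

    def test_conservation_reported(self):
        cohort = Cohort.plant(STATIC, 0.02, 186.0)
        patch = Patch(cohorts=[cohort])
        diag = grow_year(patch, 12.0, STATIC)
        assert diag["conservation_err"] <= 1e-9


class TestSelfThin:
    def _patch_with_fraction(self, target):
        cohort = Cohort.plant(STATIC, 1.0, 186.0, diameter=0.3)
        cohort.n_per_m2 = target / cohort.crown_area
        return Patch(cohorts=[cohort])

    def test_below_capacity_unchanged(self):
        patch = self._patch_with_fraction(0.8)
        n = patch.cohorts[0].n_per_m2
        self_thin(patch)
        assert patch.cohorts[0].n_per_m2 == n

    def test_overfull_scaled_back_to_one(self):
        patch = self._patch_with_fraction(1.25)
        n = patch.cohorts[0].n_per_m2
        self_thin(patch)
        assert patch.cohorts[0].n_per_m2 == pytest.approx(0.8 * n)
        assert patch.canopy_fraction == pytest.approx(1.0)

    def test_exactly_full_unchanged(self):
        patch = self._patch_with_fraction(1.0)
        n = patch.cohorts[0].n_per_m2
        self_thin(patch)
        assert patch.cohorts[0].n_per_m2 == n


class TestStemDensitySummaries:
    def _cohort_with_rings(self, specs):
        cohort = Cohort.plant(STATIC, 0.02, specs[0][1])
        cohort.rings.clear()
        from ringdemog.demography import RingRecord

        for i, (vol, rho) in enumerate(specs):
            cohort.rings.append(RingRecord(year=i, width=0.001, density=rho, volume=vol, carbon=rho * vol))
        return cohort

    def test_uniform_rings(self):
        c = self._cohort_with_rings([(1.0, 150.0), (2.0, 150.0)])
        out = stem_density_summaries(c)
        assert out["swd"] == out["sapwood_density"] == pytest.approx(150.0)

    def test_volume_weighted_mean(self):
        c = self._cohort_with_rings([(1.0, 150.0), (3.0, 190.0)])
        assert stem_density_summaries(c)["swd"] == pytest.approx(180.0)

    def test_window_clamped_to_available_rings(self):
        c = self._cohort_with_rings([(1.0, 150.0), (3.0, 190.0)])
        out = stem_density_summaries(c, window=10)
        assert out["sapwood_density"] == pytest.approx(180.0)

    def test_no_rings_rejected(self):
        c = self._cohort_with_rings([(1.0, 150.0)])
        c.rings.clear()
        with pytest.raises(ValueError):
            stem_density_summaries(c)


class TestCanopyClosureYear:
    def test_first_crossing(self):
        assert canopy_closure_year([0.2, 0.7, 1.1, 1.0]) == 3

    def test_never_reached(self):
        assert canopy_closure_year([0.2, 0.7, 0.9]) is None

    def test_exact_boundary_counts(self):
        assert canopy_closure_year([0.5, 1.0, 1.2]) == 2

    def test_custom_year_labels(self):
        assert canopy_closure_year([0.5, 1.1], years=[1900, 1901]) == 1901


class TestGeometricClosure:
    def test_ring_widths_and_carbon_close(self):
        cfg = SimulatorConfig(mode="dynamic", response=DEFAULT_RANGE_RESPONSE)
        cohort = Cohort.plant(cfg, 0.02, float(ring_density_for_year(12.0, cfg)))
        patch = Patch(cohorts=[cohort])
        rng = np.random.default_rng(3)
        for t in rng.normal(13.0, 1.0, 60):
            grow_year(patch, float(t), cfg)
        assert sum(r.width for r in cohort.rings) == pytest.approx(cohort.diameter / 2.0, rel=1e-9)
        assert sum(r.carbon for r in cohort.rings) == pytest.approx(cohort.c_sap + cohort.c_heart, rel=1e-9)
        for r in cohort.rings:
            assert r.carbon == pytest.approx(r.density * r.volume, rel=1e-12, abs=1e-300)


class TestStatureDensityTradeOff:
    def test_height_decreases_with_constant_ring_density(self):
        finals = []
        for rho in (150.0, 186.0, 220.0):
            cohort = Cohort.plant(STATIC, 0.0001, rho)
            for _ in range(50):
                allocate(cohort, 2.0, rho, AL)  # fixed annual growth carbon
            finals.append((cohort.height, cohort.diameter))
        heights = [h for h, _ in finals]
        diams = [d for _, d in finals]
        assert heights[0] > heights[1] > heights[2]
        assert diams[0] > diams[1] > diams[2]


class TestEngineMatchesObjectLayer:
    def test_lane_engine_reproduces_patch_loop(self):
        cfg = SimulatorConfig(mode="dynamic", response=DEFAULT_RANGE_RESPONSE)
        rng = np.random.default_rng(11)
        t_jas = rng.normal(12.5, 1.0, 40)

        rec = simulate_stand(t_jas, cfg)

        cohort = Cohort.plant(cfg, 0.02, float(ring_density_for_year(t_jas[0], cfg)))
        patch = Patch(cohorts=[cohort])
        for y, t in enumerate(t_jas):
            grow_year(patch, float(t), cfg)
            assert rec["diameter_m"][y] == pytest.approx(cohort.diameter, rel=1e-12)
            assert rec["height_m"][y] == pytest.approx(cohort.height, rel=1e-12)
            assert rec["trees_ha"][y] == pytest.approx(cohort.n_per_m2 * 10_000, rel=1e-12)
            assert rec["cwood_per_tree_kgC"][y] == pytest.approx(cohort.cwood, rel=1e-12)
        summ = stem_density_summaries(cohort, cfg.sapwood_density_window)
        assert rec["swd_kgC_m3"][-1] == pytest.approx(summ["swd"], rel=1e-12)
        assert rec["sapwood_density_kgC_m3"][-1] == pytest.approx(summ["sapwood_density"], rel=1e-12)


class TestSolveAllocationVectorised:
    def test_lanes_are_independent(self):
        # solving two lanes together must equal solving them separately
        D = np.array([0.1, 0.25])
        H = AL.k_height * D**AL.k_height_exp
        A = 0.25 * np.pi * D**2
        L = AL.k_latosa * A / AL.sla
        R = L.copy()
        g = np.array([3.0, 8.0])
        rho = np.array([180.0, 210.0])
        together = solve_allocation(D, H, A, L, R, g, rho, AL)
        for i in range(2):
            alone = solve_allocation(D[i], H[i], A[i], L[i], R[i], g[i], rho[i], AL)
            for k in range(5):
                assert together[k][i] == pytest.approx(alone[k][0], rel=1e-12)
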