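"""Hazard-ratio models, attributable deaths, YLL and CI propagation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from airburden.grid import GriddedField
from airburden.health import (CI_MEMBERS, GEMMParams, O3Params,
                              attributable_deaths, combine_totals,
                              compute_burden, gemm_hr, net_burden, o3_hr,
                              years_of_life_lost)
from airburden.synth import ADULT_AGE_GROUPS
from conftest import make_tables


class TestGEMMHazardRatio:
    def test_unity_at_and_below_counterfactual(self):
        for c in (0.0, 1.0, 2.4):
            assert gemm_hr(c, theta=0.14, alpha=1.6, mu=15.5, nu=36.8) == 1.0

    def test_scalar_formula_evaluation(self):
        # z=10, logistic weight exactly 1/2 at mu: exp(0.1*ln(11)*0.5)
        hr = gemm_hr(12.4, theta=0.1, alpha=1.0, mu=10.0, nu=5.0)
        np.testing.assert_allclose(hr, np.exp(0.1 * np.log(11.0) * 0.5), rtol=1e-12)
        assert round(hr, 4) == 1.1274

    def test_negative_concentration_refused(self):
        with pytest.raises(ValueError):
            gemm_hr(-1.0, theta=0.1, alpha=1.0, mu=10.0, nu=5.0)

    def test_monotone_in_concentration_dense_scan(self):
        c = np.linspace(0, 300, 5000)
        hr = gemm_hr(c, theta=0.143, alpha=1.6, mu=15.5, nu=36.8)
        assert np.all(np.diff(hr) >= 0)
        assert hr.min() >= 1.0

    @given(st.floats(0, 500), st.floats(0.01, 0.5))
    @settings(deadline=None, max_examples=100)
    def test_monotone_in_theta(self, c, se):
        theta = 0.14
        lo = gemm_hr(c, theta - 1.96 * se if theta > 1.96 * se else 1e-6,
                     1.6, 15.5, 36.8)
        hi = gemm_hr(c, theta + 1.96 * se, 1.6, 15.5, 36.8)
        assert lo <= gemm_hr(c, theta, 1.6, 15.5, 36.8) <= hi


class TestO3HazardRatio:
    @pytest.mark.parametrize("y", [0.0, 20.0, 26.7])
    def test_unity_at_and_below_threshold(self, y):
        assert o3_hr(y, eta=0.0131) == 1.0

    def test_scalar_formula_evaluation(self):
        hr = o3_hr(36.7, eta=0.0131)
        np.testing.assert_allclose(hr, np.exp(0.131), rtol=1e-12)
        assert round(hr, 4) == 1.1400

    def test_params_validation(self):
        with pytest.raises(ValueError):
            O3Params(eta=0.001)  # below the low bound
        p = O3Params()
        assert p.eta_for("low") < p.eta_for("central") < p.eta_for("high")


class TestAttributableDeaths:
    def test_no_excess_risk_no_deaths(self):
        assert attributable_deaths(1e6, 0.01, 1.0) == 0.0

    def test_arithmetic_example(self):
        # AF = (1.25-1)/1.25 = 0.2 of the 1000 baseline deaths
        np.testing.assert_allclose(
            attributable_deaths(100000, 0.01, 1.25), 200.0, rtol=1e-12)

    def test_never_exceeds_stratum_deaths(self):
        rng = np.random.default_rng(0)
        pop = rng.uniform(0, 1e6, 100)
        bmr = rng.uniform(0, 0.3, 100)
        hr = 1 + rng.exponential(2.0, 100)
        m = attributable_deaths(pop, bmr, hr)
        assert np.all(m < pop * bmr + 1e-9)
        assert np.all(m >= 0)

    def test_yll_is_deaths_times_myll(self):
        assert years_of_life_lost(200.0, 12.0) == 2400.0
        assert years_of_life_lost(0.0, 12.0) == 0.0


class TestGriddedBurden:
    def test_matches_per_cell_scalar_loop(self, small_grid, uniform_population,
                                          single_region_mask, uniform_tables):
        """Vectorized gridded burden equals an explicit scalar loop."""
        bmr, myll = uniform_tables
        rng = np.random.default_rng(1)
        conc = rng.uniform(0, 80, small_grid.shape)
        exposure = GriddedField(small_grid, conc, units="ug/m3")
        gemm = GEMMParams.synthetic_default()
        res = compute_burden(exposure, uniform_population, bmr, myll,
                             single_region_mask, gemm=gemm, pollutant="pm25")

        pop_cell = uniform_population.counts.values[0, 0]
        expect = np.zeros(small_grid.shape)
        for i in range(small_grid.shape[0]):
            for j in range(small_grid.shape[1]):
                for age in ADULT_AGE_GROUPS:
                    p = gemm.row("NCD+LRI", age)
                    hr = gemm_hr(conc[i, j], p["theta"], p["alpha"], p["mu"], p["nu"])
                    frac = uniform_population.age_fractions[age]
                    expect[i, j] += pop_cell * frac * 0.01 * (hr - 1) / hr
        np.testing.assert_allclose(res.deaths["central"].sum(axis=0), expect,
                                   rtol=1e-12, atol=1e-12)

    def test_uniform_field_closed_form(self, small_grid, uniform_population,
                                       single_region_mask, uniform_tables):
        """On a uniform exposure field the total equals the analytic
        POP_total x BMR x AF sum over age groups."""
        bmr, myll = uniform_tables
        c_star = 35.0
        exposure = GriddedField(small_grid, np.full(small_grid.shape, c_star),
                                units="ug/m3")
        gemm = GEMMParams.synthetic_default()
        res = compute_burden(exposure, uniform_population, bmr, myll,
                             single_region_mask, gemm=gemm, pollutant="pm25")
        expect = 0.0
        for age in ADULT_AGE_GROUPS:
            p = gemm.row("NCD+LRI", age)
            hr = gemm_hr(c_star, p["theta"], p["alpha"], p["mu"], p["nu"])
            expect += 1e8 * uniform_population.age_fractions[age] * 0.01 * (hr - 1) / hr
        np.testing.assert_allclose(res.total_deaths("central"), expect, rtol=1e-9)

    def test_ci_ordering_and_degenerate_se(self, small_grid, uniform_population,
                                           single_region_mask, uniform_tables):
        bmr, myll = uniform_tables
        exposure = GriddedField(small_grid,
                                np.random.default_rng(2).uniform(0, 60, small_grid.shape),
                                units="ug/m3")
        res = compute_burden(exposure, uniform_population, bmr, myll,
                             single_region_mask, pollutant="pm25")
        assert res.total_deaths("low") <= res.total_deaths("central") <= res.total_deaths("high")
        # zero standard error collapses the CI
        gemm = GEMMParams.synthetic_default()
        gemm.table["se_theta"] = 0.0
        res0 = compute_burden(exposure, uniform_population, bmr, myll,
                              single_region_mask, gemm=gemm, pollutant="pm25")
        assert res0.total_deaths("low") == res0.total_deaths("central") == res0.total_deaths("high")

    def test_o3_burden_and_eta_recovery(self, small_grid, uniform_population,
                                        single_region_mask, uniform_tables):
        """Single-stratum O3 burden inverts back to the generating slope."""
        bmr, myll = uniform_tables
        y = 46.7
        exposure = GriddedField(small_grid, np.full(small_grid.shape, y),
                                units="ppbv")
        res = compute_burden(exposure, uniform_population, bmr, myll,
                             single_region_mask, pollutant="o3",
                             ages=["80+"])
        pop80 = 1e8 * uniform_population.age_fractions["80+"]
        frac = res.total_deaths("central") / (pop80 * 0.01)
        eta_rec = np.log(1.0 / (1.0 - frac)) / (y - 26.7)
        np.testing.assert_allclose(eta_rec, O3Params().eta, rtol=1e-9)

    def test_yll_consistent_with_deaths(self, small_grid, uniform_population,
                                        single_region_mask):
        bmr, myll = make_tables(bmr_rate=0.02, myll_years=9.0)
        exposure = GriddedField(small_grid, np.full(small_grid.shape, 50.0),
                                units="ug/m3")
        res = compute_burden(exposure, uniform_population, bmr, myll,
                             single_region_mask, pollutant="pm25")
        np.testing.assert_allclose(res.total_yll("central"),
                                   9.0 * res.total_deaths("central"), rtol=1e-12)


class TestNetBurden:
    def test_case_equals_off_nets_zero(self):
        t = {"low": 1.0, "central": 2.0, "high": 3.0}
        assert net_burden(t, t) == {"low": 0.0, "central": 0.0, "high": 0.0}

    def test_off_at_counterfactual_nets_full_case(self, small_grid,
                                                  uniform_population,
                                                  single_region_mask,
                                                  uniform_tables):
        bmr, myll = uniform_tables
        case = GriddedField(small_grid, np.full(small_grid.shape, 40.0),
                            units="ug/m3")
        off = GriddedField(small_grid, np.full(small_grid.shape, 2.4),
                           units="ug/m3")
        b_case = compute_burden(case, uniform_population, bmr, myll,
                                single_region_mask, pollutant="pm25")
        b_off = compute_burden(off, uniform_population, bmr, myll,
                               single_region_mask, pollutant="pm25")
        net = net_burden(b_case.totals(), b_off.totals())
        assert b_off.total_deaths("central") == 0.0
        np.testing.assert_allclose(net["central"], b_case.total_deaths("central"),
                                   rtol=1e-12)

    def test_combined_totals_add_memberwise(self):
        pm = {"low": 1.0, "central": 2.0, "high": 4.0}
        o3 = {"low": 0.5, "central": 1.0, "high": 2.0}
        assert combine_totals(pm, o3) == {"low": 1.5, "central": 3.0, "high": 6.0}
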