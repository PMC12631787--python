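"""Coupled leaf gas-exchange and energy-balance model."""

import numpy as np
import pandas as pd
import pytest

import leafacclim as la
from leafacclim._constants import saturation_vapor_pressure
from leafacclim.spac import (
    _energy_residual,
    _gross_rate,
    arrhenius,
    peak_temperature,
)
from tests_helpers import constant_met_frame


class TestPeakedArrhenius:
    @pytest.mark.parametrize("ha,hd,ds", [(71.513, 200.0, 650.0),
                                          (50.0, 150.0, 490.0)])
    def test_normalization_at_25(self, ha, hd, ds):
        assert la.peaked_arrhenius(37.0, 25.0, ha, hd, ds) == pytest.approx(
            37.0, rel=1e-12)

    def test_peak_location_matches_grid_argmax(self):
        ha, hd, ds = 71.513, 200.0, 650.0
        grid = np.arange(0.0, 60.0, 0.001)
        vals = la.peaked_arrhenius(1.0, grid, ha, hd, ds)
        t_grid = grid[np.argmax(vals)]
        assert peak_temperature(ha, hd, ds) == pytest.approx(t_grid,
                                                             abs=0.002)

    def test_no_peak_rejected(self):
        with pytest.raises(ValueError, match="hd > ha"):
            la.peaked_arrhenius(1.0, 25.0, 200.0, 100.0, 650.0)

    def test_peak_shifts_up_with_growth_temperature(self):
        peaks = [
            peak_temperature(71.513, 200.0,
                             la.acclimate_entropy(tg, "vcmax"))
            for tg in np.arange(10.0, 35.0, 5.0)
        ]
        assert np.all(np.diff(peaks) > 0)


class TestAcclimateEntropy:
    def test_zero_slope_constant(self):
        coef = {"vcmax": (650.0, 0.0)}
        assert la.acclimate_entropy(10.0, "vcmax", coef) == \
            la.acclimate_entropy(30.0, "vcmax", coef) == 650.0

    def test_negative_slope_decreasing(self):
        vals = la.acclimate_entropy(np.array([10.0, 20.0, 30.0]), "jmax")
        assert np.all(np.diff(vals) < 0)

    def test_unknown_process_rejected(self):
        with pytest.raises(KeyError):
            la.acclimate_entropy(15.0, "rubisco")


class TestLimitingRate:
    def test_dark_limit(self, default_params):
        b, which = la.limiting_rate(280.0, 25.0, 0.0, default_params,
                                    ds_v=650.0, ds_j=650.0)
        assert b == pytest.approx(0.0, abs=1e-12)
        assert which == "rubp"

    def test_high_light_low_ci_rubisco_limited(self, default_params):
        _, which = la.limiting_rate(120.0, 25.0, 2000.0, default_params,
                                    ds_v=650.0, ds_j=650.0)
        assert which == "rubisco"

    def test_continuity_at_crossover(self, default_params):
        from scipy.optimize import brentq

        kw = dict(t_leaf=25.0, ppfd=600.0, params=default_params,
                  ds_v=650.0, ds_j=650.0)
        gap = lambda ci: (
            la.limiting_rate(ci, kw["t_leaf"], kw["ppfd"], kw["params"],
                             kw["ds_v"], kw["ds_j"])[0]
        )
        # find the ci where the two limitation terms swap
        which_at = lambda ci: la.limiting_rate(
            ci, 25.0, 600.0, default_params, 650.0, 650.0)[1]
        lo, hi = 60.0, 1500.0
        if which_at(lo) == which_at(hi):
            pytest.skip("no crossover in range for these parameters")
        while hi - lo > 1e-9:
            mid = 0.5 * (lo + hi)
            if which_at(mid) == which_at(lo):
                lo = mid
            else:
                hi = mid
        assert abs(gap(lo) - gap(hi)) < 1e-6


class TestGsMaxEq4:
    def test_zero_numerator(self):
        # choose rd so that B(ci - gamma) == rd (D ci + E)
        ci, ca, gamma, b = 280.0, 400.0, 42.0, 10.0
        d_c, e_c, f_c = 0.0, 50.0, -200.0
        rd = b * (ci - gamma) / (d_c * ci + e_c)
        assert la.gs_max_eq4(ci, ca, gamma, b, rd, d_c, e_c, f_c) == 0.0

    def test_numerator_homogeneity(self):
        args = dict(ci=280.0, ca=400.0, gamma=42.0, d_const=0.0,
                    e_metric=50.0, f_const=-200.0)
        g1 = la.gs_max_eq4(b_rate=10.0, rd=0.5, **args)
        g2 = la.gs_max_eq4(b_rate=20.0, rd=1.0, **args)
        assert g2 == pytest.approx(2 * g1, rel=1e-12)

    def test_matches_independent_formula(self):
        rng = np.random.default_rng(4)
        for _ in range(200):
            ci = rng.uniform(100, 380)
            ca, gamma = 400.0, rng.uniform(30, 80)
            b, rd = rng.uniform(1, 30), rng.uniform(0.1, 2.0)
            d_c, e_c, f_c = rng.uniform(0, 2), rng.uniform(10, 100), \
                rng.uniform(-400, -150)
            expected = max(
                (b * (ci - gamma) - rd * (d_c * ci + e_c))
                / ((e_c + f_c) * (ci - ca)), 0.0)
            got = la.gs_max_eq4(ci, ca, gamma, b, rd, d_c, e_c, f_c)
            assert got == pytest.approx(expected, abs=1e-12)

    def test_singularity_at_ca(self):
        with pytest.raises(ZeroDivisionError):
            la.gs_max_eq4(400.0, 400.0, 42.0, 10.0, 0.5)


class TestHydraulicGs:
    def test_zero_demand_limit(self, default_params):
        gs, psi = la.hydraulic_gs(0.2, -0.3, 0.0, default_params)
        cost = 1.0 / (1.0 + (-0.3 / default_params.psi50)
                      ** default_params.shape)
        assert psi == pytest.approx(-0.3, abs=1e-12)
        assert gs == pytest.approx(0.2 * cost, abs=1e-8)

    def test_well_watered_saturation(self, default_params):
        gs, _ = la.hydraulic_gs(0.2, -1e-6, 0.1, default_params)
        assert gs == pytest.approx(0.2, rel=0.02)

    def test_fixed_point_matches_dense_scan(self, default_params):
        gs_max, psi_soil, vpd = 0.3, -0.4, 2.5
        gs, psi = la.hydraulic_gs(gs_max, psi_soil, vpd, default_params)
        grid = np.linspace(default_params.gmin, gs_max, 30001)
        e = 1.6 * grid * vpd / 101.325
        psi_g = psi_soil - e / default_params.kmax_plant
        cost = 1.0 / (1.0 + (psi_g / default_params.psi50)
                      ** default_params.shape)
        resid = np.abs(gs_max * cost - grid)
        best = grid[np.argmin(resid)]
        assert gs == pytest.approx(best, abs=1e-4)

    def test_never_below_gmin(self, default_params):
        gs, _ = la.hydraulic_gs(0.001, -3.0, 5.0, default_params)
        assert gs >= default_params.gmin

    def test_preconditions(self, default_params):
        with pytest.raises(ValueError):
            la.hydraulic_gs(0.2, 0.5, 1.0, default_params)
        with pytest.raises(ValueError):
            la.hydraulic_gs(0.2, -0.5, -1.0, default_params)


class TestRespirationAtTl:
    def test_reference_identity(self):
        assert la.respiration_at_tl(25.0, 0.73, 2.4) == 0.73

    def test_one_decade(self):
        assert la.respiration_at_tl(35.0, 0.4, 2.0) == pytest.approx(0.8)

    def test_half_decade(self):
        assert la.respiration_at_tl(30.0, 0.4, 2.0) == pytest.approx(
            0.4 * np.sqrt(2), rel=1e-12)

    def test_preconditions(self):
        with pytest.raises(ValueError):
            la.respiration_at_tl(25.0, -0.1, 2.0)


class TestLeafEnergyBalance:
    def test_no_forcing_equilibrium(self, default_params):
        tl = la.leaf_energy_balance(20.0, 0.0, 70.0, 1.0, 0.0,
                                    default_params)
        assert tl == pytest.approx(20.0, abs=1e-6)

    def test_radiation_load_warms_leaf(self, default_params):
        tl = la.leaf_energy_balance(20.0, 1000.0, 70.0, 1.0, 0.0,
                                    default_params)
        assert tl > 20.0

    def test_transpiration_cools(self, default_params):
        tl_dry = la.leaf_energy_balance(25.0, 800.0, 50.0, 1.0, 0.0,
                                        default_params)
        tl_wet = la.leaf_energy_balance(25.0, 800.0, 50.0, 1.0, 0.4,
                                        default_params)
        assert tl_wet < tl_dry

    def test_matches_dense_grid_root(self, default_params):
        t_air, ppfd, rh, wind, gs = 25.0, 900.0, 55.0, 1.5, 0.15
        tl = la.leaf_energy_balance(t_air, ppfd, rh, wind, gs,
                                    default_params)
        grid = np.arange(t_air - 5.0, t_air + 15.0, 0.001)
        ea = rh / 100 * saturation_vapor_pressure(t_air)
        resid, _ = _energy_residual(grid, t_air, ppfd, ea, wind, gs,
                                    default_params, 101.325)
        best = grid[np.argmin(np.abs(resid))]
        assert tl == pytest.approx(best, abs=0.01)

    def test_residual_below_tolerance(self, default_params):
        t_air, ppfd, rh, wind, gs = 28.0, 1200.0, 45.0, 0.8, 0.2
        tl = la.leaf_energy_balance(t_air, ppfd, rh, wind, gs,
                                    default_params)
        ea = rh / 100 * saturation_vapor_pressure(t_air)
        resid, _ = _energy_residual(tl, t_air, ppfd, ea, wind, gs,
                                    default_params, 101.325)
        assert abs(float(resid)) < 0.01

    def test_preconditions(self, default_params):
        with pytest.raises(ValueError):
            la.leaf_energy_balance(20.0, 0.0, 0.0, 1.0, 0.1, default_params)
        with pytest.raises(ValueError):
            la.leaf_energy_balance(20.0, 0.0, 70.0, 1.0, -0.1,
                                   default_params)


class TestSolveLeafState:
    def test_nocturnal_closure(self, default_params):
        met = constant_met_frame(1, tair=18.0, ppfd=0.0)
        st = la.solve_leaf_state(met.iloc[0], default_params)
        assert st.converged
        assert st.gs == default_params.gmin
        assert st.a_gross == 0.0
        assert st.a_net == pytest.approx(-st.rd, abs=1e-9)

    def test_carbon_closure_and_diffusion_consistency(self, day_met,
                                                      default_params):
        states = la.solve_leaf_states(day_met, default_params)
        assert states["converged"].all()
        closure = states["a_gross"] - states["rd"] - states["a_net"]
        assert np.abs(closure).max() < 1e-9
        # diffusion-implied A_net equals the biochemical value
        day = day_met["ppfd_umol_m2_s"] > 0
        gs = states.loc[day, "gs"]
        ci = states.loc[day, "ci"]
        diff_anet = gs * (day_met.loc[day, "co2_ppm"] - ci) / 1.6
        assert np.abs(diff_anet - states.loc[day, "a_net"]).max() < 1e-6

    def test_energy_residual_when_converged(self, day_met, default_params):
        states = la.solve_leaf_states(day_met, default_params)
        ea = day_met["rh_pct"] / 100 * saturation_vapor_pressure(
            day_met["tair_C"])
        resid, _ = _energy_residual(
            states["t_leaf"].to_numpy(), day_met["tair_C"].to_numpy(),
            day_met["ppfd_umol_m2_s"].to_numpy(), ea.to_numpy(),
            day_met["wind_m_s"].to_numpy(), states["gs"].to_numpy(),
            default_params, 101.325)
        assert np.abs(resid[states["converged"]]).max() < 0.01

    def test_determinism(self, day_met, default_params):
        a = la.solve_leaf_states(day_met, default_params)
        b = la.solve_leaf_states(day_met, default_params)
        pd.testing.assert_frame_equal(a, b)

    def test_vpd_monotonicity_of_gs_at_fixed_leaf_temperature(
            self, default_params):
        """Holding everything else fixed, drier air never opens stomata
        further (through the coupled energy balance a drier, cooler leaf may
        legitimately assimilate more; the invariant is ceteris paribus)."""
        gs = [la.hydraulic_gs(0.2, -0.3, vpd, default_params)[0]
              for vpd in (0.0, 0.5, 1.5, 3.0, 5.0)]
        assert np.all(np.diff(gs) <= 1e-12)

    def test_ppfd_monotonicity_of_limiting_rate(self, default_params):
        """At fixed leaf temperature and C_i, more light never lowers the
        limiting carboxylation rate."""
        b = [la.limiting_rate(280.0, 25.0, q, default_params,
                              ds_v=650.0, ds_j=650.0)[0]
             for q in (0.0, 100.0, 400.0, 900.0, 1800.0)]
        assert np.all(np.diff(b) >= -1e-12)

    def test_acclimation_off_equals_on_at_reference(self, day_met,
                                                    default_params):
        ref = 15.2
        off = la.solve_leaf_states(day_met, default_params,
                                   acclimation="off",
                                   species="trachycarpus_fortunei",
                                   t_growth_ref=ref)
        on = la.solve_leaf_states(day_met, default_params, acclimation="on",
                                  species="trachycarpus_fortunei",
                                  t_growth=ref, t_growth_ref=ref)
        pd.testing.assert_frame_equal(off, on)

    def test_coupled_ci_matches_2d_scan_oracle(self, default_params):
        """Independent dense (C_i, T_L) scan finds the same intersection."""
        met = constant_met_frame(1, tair=24.0, ppfd=900.0, rh=60.0)
        st = la.solve_leaf_state(met.iloc[0], default_params,
                                 acclimation="off",
                                 species="trachycarpus_fortunei")
        p = default_params
        ds_v = la.acclimate_entropy(15.2, "vcmax")
        ds_j = la.acclimate_entropy(15.2, "jmax")
        r25 = la.acclimated_r25("trachycarpus_fortunei", 15.2)
        q10 = la.acclimated_q10("trachycarpus_fortunei", 15.2)

        tl_grid = np.arange(st.t_leaf - 1.5, st.t_leaf + 1.5, 0.01)
        ci_grid = np.arange(st.ci - 40.0, st.ci + 40.0, 0.1)
        best = (np.inf, None, None)
        ea = 0.6 * saturation_vapor_pressure(24.0)
        for tl in tl_grid:
            gamma = arrhenius(p.gamma_star25, tl, p.ha_gamma_star)
            kc = arrhenius(p.kc25, tl, p.ha_kc)
            ko = arrhenius(p.ko25, tl, p.ha_ko)
            km = kc * (1 + p.o2_mmol / ko)
            vcmax = la.peaked_arrhenius(p.vcmax25, tl, p.ha_v, p.hd, ds_v)
            jmax = la.peaked_arrhenius(p.jmax25, tl, p.ha_j, p.hd, ds_j)
            from leafacclim.spac import _electron_transport

            j = _electron_transport(900.0, jmax, p.theta_j, p.alpha_j)
            rd = r25 * q10 ** ((tl - 25) / 10)
            w = _gross_rate(ci_grid, vcmax, j, gamma, km)
            gs_implied = 1.6 * (w - rd) / (400.0 - ci_grid)
            vpd_leaf = max(saturation_vapor_pressure(tl) - ea, 0.0)
            e_flux = 1.6 * gs_implied * vpd_leaf / 101.325
            psi = -0.05 - e_flux / p.kmax_plant
            cost = 1.0 / (1.0 + (psi / p.psi50) ** p.shape)
            gs4 = np.maximum(
                (w * (ci_grid - gamma) - rd * (p.eq4_d * ci_grid + p.eq4_e))
                / ((p.eq4_e + p.eq4_f) * (ci_grid - 400.0)), 0.0)
            r1 = cost * gs4 - gs_implied  # stomatal optimality residual
            resid_eb, _ = _energy_residual(tl, 24.0, 900.0, ea, 1.0,
                                           gs_implied, p, 101.325)
            score = np.abs(r1) + np.abs(resid_eb) / 50.0
            k = int(np.argmin(score))
            if score[k] < best[0]:
                best = (float(score[k]), float(ci_grid[k]), float(tl))
        _, ci_best, tl_best = best
        assert st.ci == pytest.approx(ci_best, abs=0.2)
        assert st.t_leaf == pytest.approx(tl_best, abs=0.02)

    def test_invalid_acclimation_flag(self, day_met, default_params):
        with pytest.raises(ValueError):
            la.solve_leaf_states(day_met, default_params, acclimation="auto")


class TestSpeciesParams:
    @pytest.mark.parametrize("bad", [dict(vcmax25=-1.0), dict(q10=0.0),
                                     dict(hd=40.0), dict(absorptance=1.5),
                                     dict(psi50=1.0)])
    def test_invariants_enforced(self, bad):
        with pytest.raises(ValueError):
            la.SpeciesParams(**bad)


class TestLeafGasExchangeModel:
    def test_sklearn_params_roundtrip(self, default_params):
        model = la.LeafGasExchangeModel(params=default_params,
                                        acclimation="off")
        cloned = model.set_params(**model.get_params())
        assert cloned.get_params()["acclimation"] == "off"

    def test_predict_matches_function_surface(self, day_met, default_params):
        model = la.LeafGasExchangeModel(params=default_params)
        out = model.predict(day_met)
        direct = la.solve_leaf_states(day_met, default_params)
        pd.testing.assert_frame_equal(out, direct)
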