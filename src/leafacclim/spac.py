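"""Coupled leaf gas-exchange and energy-balance model (SPAC leaf level).

At every meteorological step the model solves, self-consistently,

* the biochemical CO2 demand — Farquhar-type limiting rate
  ``B = min(W_c, W_j)`` with peaked-Arrhenius temperature responses of
  V_C,max and J_max (entropy terms optionally acclimated to growth
  temperature) and Q10 dark respiration evaluated at leaf temperature;
* the stomatal optimum ``g_s,max`` from the closed-form expression
  ``g_s,max = [B(C_i − Γ) − R_d(D C_i + E)] / [(E + F)(C_i − C_a)]``,
  down-regulated by a sigmoidal hydraulic cost of leaf water potential;
* the CO2 diffusion constraint ``A_net = g_s (C_a − C_i) / 1.6``;
* a leaf energy balance (shortwave + longwave + sensible + latent) that
  returns the leaf temperature consistent with the stomatal conductance.

The nesting mirrors the two-level iteration the model family uses: an outer
damped fixed point on leaf temperature T_L wraps an inner solution of
(C_i, g_s, A_net); convergence is declared when successive T_L differ by less
than 0.01 °C.  All inner root-finding is bracketed bisection, vectorized over
meteorological steps, so a full year at 30-min resolution solves in seconds.

Note on the diffusion sign convention: the constraint is implemented as
``A_net = g_s (C_a − C_i) / 1.6`` with R_d subtracted inside the biochemical
rate.  The alternative reading ``A_net = g_s (C_a − C_i) + R_d`` (no
diffusivity ratio, respiration added) is available behind
``eq3_printed_sign=True`` for auditing, but is not physically consistent and
is off by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from . import defaults as dflt
from ._constants import (
    CP_MOLAR_AIR,
    H2O_CO2_DIFF_RATIO,
    J_PER_UMOL_PAR,
    LAMBDA_VAP,
    P_ATM_KPA,
    R_GAS,
    STEFAN_BOLTZMANN,
    T0_K,
    TREF_K,
    saturation_vapor_pressure,
)
from .acclimation import acclimated_q10, acclimated_r25

GS_CAP = 2.0  # mol m-2 s-1, upper bracket for the stomatal optimum search
LEAF_EMISSIVITY = 0.97
SW_TO_PAR = 2.0  # total shortwave ~ 2x PAR energy flux


@dataclass
class SpeciesParams:
    """Physiological and biophysical parameters of one species.

    Rates are µmol m-2 s-1 at 25 °C, energies kJ mol-1, entropies
    J mol-1 K-1, conductances mol m-2 s-1, water potentials MPa.
    """

    vcmax25: float = 50.0
    jmax25: float = 100.0
    r25: float = 0.8
    q10: float = 2.2
    gmin: float = 0.005
    ha_v: float = dflt.HA_VCMAX
    ha_j: float = dflt.HA_JMAX
    hd: float = dflt.HD_DEACT
    ds_v: float | None = None   # None -> from growth-temperature acclimation
    ds_j: float | None = None
    gamma_star25: float = dflt.GAMMA_STAR_25
    ha_gamma_star: float = dflt.HA_GAMMA_STAR
    kc25: float = dflt.KC_25
    ha_kc: float = dflt.HA_KC
    ko25: float = dflt.KO_25
    ha_ko: float = dflt.HA_KO
    o2_mmol: float = dflt.O2_MMOL
    theta_j: float = dflt.J_CURVATURE_THETA
    alpha_j: float = dflt.J_QUANTUM_YIELD
    eq4_d: float = dflt.EQ4_D
    eq4_e: float = dflt.EQ4_E
    eq4_f: float = dflt.EQ4_F
    kmax_plant: float = 0.012   # mol m-2 s-1 MPa-1 soil-to-leaf
    psi50: float = -2.5
    shape: float = 4.0
    leaf_area_total: float = 0.35  # m2 per plant
    lrr: float = 9.0               # leaf area / pot upper surface
    leaf_width: float = 0.05       # m
    absorptance: float = 0.85

    def __post_init__(self):
        # fields may carry per-step arrays (e.g. batched calibration), so
        # validation is written array-safe
        for name in ("vcmax25", "jmax25", "r25", "q10", "gmin", "kmax_plant"):
            if np.any(np.asarray(getattr(self, name)) <= 0):
                raise ValueError(f"{name} must be positive")
        if np.any(np.asarray(self.hd) <= np.asarray(self.ha_v)) or \
                np.any(np.asarray(self.hd) <= np.asarray(self.ha_j)):
            raise ValueError("deactivation energy hd must exceed ha")
        if np.any(np.asarray(self.absorptance) <= 0) or \
                np.any(np.asarray(self.absorptance) > 1):
            raise ValueError("absorptance must be in (0, 1]")
        if np.any(np.asarray(self.psi50) >= 0):
            raise ValueError("psi50 must be negative")


@dataclass
class LeafState:
    """Converged coupled solution at one meteorological step."""

    t_leaf: float
    gs: float
    ci: float
    a_net: float
    a_gross: float
    rd: float
    transpiration: float  # mmol m-2 s-1
    psi_leaf: float
    converged: bool
    iterations: int


# ---------------------------------------------------------------------------
# temperature responses


def arrhenius(k25, t_c, ha_kj):
    """Simple Arrhenius scaling of a rate from 25 °C to ``t_c``."""
    tk = np.asarray(t_c, dtype=float) + T0_K
    return k25 * np.exp(ha_kj * 1000.0 * (tk - TREF_K) / (TREF_K * R_GAS * tk))


def peaked_arrhenius(k25, t_leaf, ha, hd, ds):
    """Peaked Arrhenius response normalized to ``k25`` at 25 °C.

    ``ha``/``hd`` in kJ mol-1, ``ds`` in J mol-1 K-1.  Rises with activation
    energy ``ha`` and is pulled down above the peak temperature set by the
    deactivation term (``hd``, ``ds``).
    """
    ha = np.asarray(ha, dtype=float)
    hd_j = np.asarray(hd, dtype=float) * 1000.0
    if np.any(np.asarray(hd) <= ha):
        raise ValueError("peaked Arrhenius requires hd > ha (no peak otherwise)")
    tk = np.asarray(t_leaf, dtype=float) + T0_K
    ds = np.asarray(ds, dtype=float)
    rise = np.exp(ha * 1000.0 * (tk - TREF_K) / (TREF_K * R_GAS * tk))
    deact = (1.0 + np.exp((TREF_K * ds - hd_j) / (TREF_K * R_GAS))) / (
        1.0 + np.exp((tk * ds - hd_j) / (tk * R_GAS))
    )
    return k25 * rise * deact


def peak_temperature(ha, hd, ds):
    """Closed-form peak (°C) of the peaked Arrhenius response."""
    ha_j, hd_j = ha * 1000.0, hd * 1000.0
    tk = hd_j / (ds - R_GAS * np.log(ha_j / (hd_j - ha_j)))
    return tk - T0_K


def acclimate_entropy(t_growth, process: str, coefficients=None):
    """Entropy term ΔS (J mol-1 K-1) as a linear function of growth temperature.

    ``process`` is 'vcmax' or 'jmax'; ``coefficients`` maps process to
    (intercept, slope) and defaults to the packaged general coefficients.
    """
    table = dflt.ENTROPY_COEFFICIENTS if coefficients is None else coefficients
    if process not in table:
        raise KeyError(f"unknown process {process!r}; known: {sorted(table)}")
    intercept, slope = table[process]
    return intercept + slope * np.asarray(t_growth, dtype=float)


def respiration_at_tl(t_leaf, r25, q10):
    """Q10 dark respiration evaluated at leaf temperature."""
    r25 = np.asarray(r25, dtype=float)
    q10 = np.asarray(q10, dtype=float)
    if np.any(r25 <= 0) or np.any(q10 <= 0):
        raise ValueError("r25 and q10 must be positive")
    return r25 * q10 ** ((np.asarray(t_leaf, dtype=float) - 25.0) / 10.0)


# ---------------------------------------------------------------------------
# biochemistry


def _electron_transport(ppfd, jmax, theta, alpha):
    """Non-rectangular hyperbola of incident PPFD (smaller root)."""
    q = alpha * np.asarray(ppfd, dtype=float)
    s = q + jmax
    disc = np.sqrt(np.maximum(s * s - 4.0 * theta * q * jmax, 0.0))
    return (s - disc) / (2.0 * theta)


def _gross_rate(ci, vcmax, jmax_j, gamma_star, km):
    """min(W_c, W_j), unclipped so the rate is continuous below Γ*."""
    wc = vcmax * (ci - gamma_star) / (ci + km)
    wj = jmax_j * (ci - gamma_star) / (4.0 * ci + 8.0 * gamma_star)
    return np.minimum(wc, wj)


def limiting_rate(ci, t_leaf, ppfd, params: SpeciesParams,
                  ds_v=None, ds_j=None):
    """CO2-uptake limiting rate B (µmol m-2 s-1) and active limitation.

    Returns ``(B, which)`` with ``which`` in {'rubisco', 'rubp'}: the minimum
    of the Rubisco-limited and electron-transport (RuBP-regeneration) limited
    carboxylation terms at temperature-adjusted V_C,max and J_max.
    """
    if np.any(np.asarray(ci) <= 0):
        raise ValueError("ci must be positive")
    ds_v = params.ds_v if ds_v is None else ds_v
    ds_j = params.ds_j if ds_j is None else ds_j
    if ds_v is None or ds_j is None:
        raise ValueError("entropy terms unset: pass ds_v/ds_j or set them on params")
    gamma = arrhenius(params.gamma_star25, t_leaf, params.ha_gamma_star)
    kc = arrhenius(params.kc25, t_leaf, params.ha_kc)
    ko = arrhenius(params.ko25, t_leaf, params.ha_ko)
    km = kc * (1.0 + params.o2_mmol / ko)
    vcmax = peaked_arrhenius(params.vcmax25, t_leaf, params.ha_v, params.hd, ds_v)
    jmax = peaked_arrhenius(params.jmax25, t_leaf, params.ha_j, params.hd, ds_j)
    j = _electron_transport(ppfd, jmax, params.theta_j, params.alpha_j)
    ci = np.asarray(ci, dtype=float)
    wc = vcmax * (ci - gamma) / (ci + km)
    wj = j * (ci - gamma) / (4.0 * ci + 8.0 * gamma)
    b = np.minimum(wc, wj)
    which = np.where(wc <= wj, "rubisco", "rubp")
    if b.ndim == 0:
        return float(b), str(which)
    return b, which


def gs_max_eq4(ci, ca, gamma, b_rate, rd, d_const=None, e_metric=None,
               f_const=None):
    """Closed-form stomatal optimum, floored at zero.

    ``g_s,max = [B(C_i − Γ) − R_d(D C_i + E)] / [(E + F)(C_i − C_a)]``.
    """
    d_const = dflt.EQ4_D if d_const is None else d_const
    e_metric = dflt.EQ4_E if e_metric is None else e_metric
    f_const = dflt.EQ4_F if f_const is None else f_const
    ci = np.asarray(ci, dtype=float)
    denom = (e_metric + f_const) * (ci - ca)
    if np.any(denom == 0):
        raise ZeroDivisionError("gs_max_eq4 singular at ci == ca")
    num = b_rate * (ci - gamma) - rd * (d_const * ci + e_metric)
    out = np.maximum(num / denom, 0.0)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# hydraulics


def _hydraulic_cost(psi, psi50, shape):
    """Sigmoidal vulnerability cost in (0, 1]; 0.5 at psi50."""
    return 1.0 / (1.0 + (np.asarray(psi, dtype=float) / psi50) ** shape)


def hydraulic_gs(gs_max, psi_soil, vpd_leaf, params: SpeciesParams,
                 pressure_kpa=P_ATM_KPA, max_iter=80, tol=1e-12):
    """Down-regulate g_s,max by the hydraulic cost of leaf water potential.

    Solves the fixed point of  E = 1.6 g_s VPD_leaf / P,
    ψ_leaf = ψ_soil − E / K,  g_s = g_s,max · cost(ψ_leaf)  by damped
    iteration (soil-to-leaf conductance K held at its well-watered maximum;
    the vulnerability sigmoid acts through the stomatal cost).  Returns
    ``(gs, psi_leaf)``; gs never falls below gmin.
    """
    vpd_leaf = np.asarray(vpd_leaf, dtype=float)
    if np.any(vpd_leaf < 0):
        raise ValueError("vpd_leaf must be >= 0")
    if np.any(np.asarray(psi_soil) > 0):
        raise ValueError("psi_soil must be <= 0")
    gs_max = np.asarray(gs_max, dtype=float)
    gs = gs_max * _hydraulic_cost(psi_soil, params.psi50, params.shape)
    for _ in range(max_iter):
        e_flux = H2O_CO2_DIFF_RATIO * gs * vpd_leaf / pressure_kpa
        psi = psi_soil - e_flux / params.kmax_plant
        target = gs_max * _hydraulic_cost(psi, params.psi50, params.shape)
        step = target - gs
        gs = gs + 0.5 * step
        if np.max(np.abs(step)) < tol:
            break
    gs = np.maximum(gs, params.gmin)
    e_flux = H2O_CO2_DIFF_RATIO * gs * vpd_leaf / pressure_kpa
    psi = psi_soil - e_flux / params.kmax_plant
    if gs.ndim == 0:
        return float(gs), float(psi)
    return gs, psi


# ---------------------------------------------------------------------------
# energy balance


def _boundary_layer_conductances(wind, leaf_width):
    """Forced-convection one-sided heat and water conductances (mol m-2 s-1)."""
    u = np.maximum(np.asarray(wind, dtype=float), 0.1)
    gbh = 1.4 * 0.135 * np.sqrt(u / leaf_width)
    gbw = 1.4 * 0.147 * np.sqrt(u / leaf_width)
    return gbh, gbw


def _energy_residual(t_leaf, t_air, ppfd, ea_kpa, wind, gs,
                     params: SpeciesParams, pressure_kpa):
    """Net energy flux into the leaf (W m-2); zero at balance."""
    gbh, gbw = _boundary_layer_conductances(wind, params.leaf_width)
    rabs = params.absorptance * np.asarray(ppfd, dtype=float) \
        * J_PER_UMOL_PAR * SW_TO_PAR
    tl_k = np.asarray(t_leaf, dtype=float) + T0_K
    ta_k = np.asarray(t_air, dtype=float) + T0_K
    lw_net = 2.0 * LEAF_EMISSIVITY * STEFAN_BOLTZMANN * (ta_k**4 - tl_k**4)
    sensible = 2.0 * CP_MOLAR_AIR * gbh * (np.asarray(t_leaf) - np.asarray(t_air))
    gs_w = H2O_CO2_DIFF_RATIO * np.maximum(np.asarray(gs, dtype=float), 0.0)
    g_tot = np.where(gs_w > 0, gs_w * gbw / (gs_w + gbw), 0.0)
    e_mol = g_tot * np.maximum(
        saturation_vapor_pressure(t_leaf) - ea_kpa, 0.0
    ) / pressure_kpa
    latent = LAMBDA_VAP * e_mol
    return rabs + lw_net - sensible - latent, e_mol


def leaf_energy_balance(t_air, ppfd, rh, wind, gs, params: SpeciesParams,
                        pressure_kpa=P_ATM_KPA, n_bisect=42):
    """Leaf temperature (°C) closing the energy balance for given g_s.

    Absorbed shortwave plus incoming longwave (surroundings at air
    temperature) balance emitted longwave, sensible and latent heat; the root
    is bracketed in [t_air − 20, t_air + 25] and found by bisection to a
    residual well below 0.01 W m-2.
    """
    rh = np.asarray(rh, dtype=float)
    if np.any(rh <= 0) or np.any(rh > 100):
        raise ValueError("rh must be in (0, 100]")
    if np.any(np.asarray(gs) < 0):
        raise ValueError("gs must be >= 0")
    t_air = np.asarray(t_air, dtype=float)
    ea = rh / 100.0 * saturation_vapor_pressure(t_air)

    lo = t_air - 20.0
    hi = t_air + 25.0
    f_lo, _ = _energy_residual(lo, t_air, ppfd, ea, wind, gs, params,
                               pressure_kpa)
    for _ in range(n_bisect):
        mid = 0.5 * (lo + hi)
        f_mid, _ = _energy_residual(mid, t_air, ppfd, ea, wind, gs, params,
                                    pressure_kpa)
        same = (f_mid > 0) == (f_lo > 0)
        lo = np.where(same, mid, lo)
        f_lo = np.where(same, f_mid, f_lo)
        hi = np.where(same, hi, mid)
    out = 0.5 * (lo + hi)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# coupled solution


def _solve_inner(t_leaf, t_air, ppfd, rh, co2, pressure, psi_soil,
                 params: SpeciesParams, r25, q10, ds_v, ds_j,
                 eq3_printed_sign=False,
                 n_gs_bisect=24, n_ci_bisect=48, n_ci_coarse=30, n_grid=17):
    """Inner (C_i, g_s, A_net) solution at fixed leaf temperature (vectorized)."""
    gamma = arrhenius(params.gamma_star25, t_leaf, params.ha_gamma_star)
    kc = arrhenius(params.kc25, t_leaf, params.ha_kc)
    ko = arrhenius(params.ko25, t_leaf, params.ha_ko)
    km = kc * (1.0 + params.o2_mmol / ko)
    vcmax = peaked_arrhenius(params.vcmax25, t_leaf, params.ha_v, params.hd, ds_v)
    jmax = peaked_arrhenius(params.jmax25, t_leaf, params.ha_j, params.hd, ds_j)
    j = _electron_transport(ppfd, jmax, params.theta_j, params.alpha_j)
    rd = respiration_at_tl(t_leaf, r25, q10)

    ea = rh / 100.0 * saturation_vapor_pressure(t_air)
    vpd_leaf = np.maximum(saturation_vapor_pressure(t_leaf) - ea, 0.0)
    gross = lambda ci: _gross_rate(ci, vcmax, j, gamma, km)

    def ci_at_gs(gs, iters=n_ci_bisect):
        """Root of g_s(C_a − C_i)/1.6 = B(C_i) − R_d (bracket guaranteed)."""
        lo = np.full_like(t_leaf, 1e-3)
        hi = co2 + H2O_CO2_DIFF_RATIO * rd / np.maximum(gs, 1e-9) + 10.0
        if eq3_printed_sign:
            f = lambda ci: gs * (co2 - ci) + rd - (gross(ci) - rd)
        else:
            f = lambda ci: gs * (co2 - ci) / H2O_CO2_DIFF_RATIO - (gross(ci) - rd)
        f_lo = f(lo)
        for _ in range(iters):
            mid = 0.5 * (lo + hi)
            f_mid = f(mid)
            same = (f_mid > 0) == (f_lo > 0)
            lo = np.where(same, mid, lo)
            f_lo = np.where(same, f_mid, f_lo)
            hi = np.where(same, hi, mid)
        return 0.5 * (lo + hi)

    # unregulated stomatal optimum: the self-consistent solution of
    # F0(gs) = gs_max_eq4(ci*(gs)) − gs.  The closed form grows without
    # bound as C_i → C_a, so F0 is negative at the cuticular floor, crosses
    # upward in the physiological range and stays positive; the lowest
    # crossing above gmin is taken, and gmin when no crossing exists (night,
    # CO2 starvation, or strong respiratory burden).
    def consistency(gs):
        ci = ci_at_gs(gs, n_ci_coarse)
        return gs_max_eq4(ci, co2, gamma, gross(ci), rd, params.eq4_d,
                          params.eq4_e, params.eq4_f) - gs

    gmin_lo = float(np.min(params.gmin))
    grid = np.geomspace(gmin_lo, GS_CAP, n_grid)
    f_grid = np.stack([consistency(np.full_like(t_leaf, g)) for g in grid])
    pos = f_grid > 0
    up = ~pos[:-1] & pos[1:]            # − -> + transition between nodes
    has_up = up.any(axis=0)
    idx_up = np.where(has_up, np.argmax(up, axis=0), 0)
    lo_g = grid[idx_up]
    hi_g = grid[idx_up + 1]
    f_lo = np.take_along_axis(f_grid, idx_up[None, :], axis=0)[0]
    for _ in range(n_gs_bisect):
        mid = 0.5 * (lo_g + hi_g)
        f_mid = consistency(mid)
        same = (f_mid > 0) == (f_lo > 0)
        lo_g = np.where(same, mid, lo_g)
        f_lo = np.where(same, f_mid, f_lo)
        hi_g = np.where(same, hi_g, mid)
    gs_opt = 0.5 * (lo_g + hi_g)
    # no crossing: all-negative means the optimum sits below the cuticular
    # floor (take gmin); all-positive means it saturates above the cap
    gs_opt = np.where(has_up, gs_opt,
                      np.where(pos[0], GS_CAP, params.gmin))
    # the closed form diverges as C_i → C_a, creating a spurious root with
    # near-zero drawdown once the physical lobe vanishes (hot leaves, large
    # R_d); roots within 20 ppm of C_a are rejected and stomata close
    ci_opt = ci_at_gs(np.maximum(gs_opt, gmin_lo), n_ci_coarse)
    gs_opt = np.where(ci_opt > co2 - 20.0, params.gmin, gs_opt)
    gs_opt = np.maximum(gs_opt, params.gmin)
    night = np.asarray(ppfd) <= 0
    gs_max = np.where(night, params.gmin, gs_opt)

    # hydraulic down-regulation of the fixed optimum, then the final C_i
    gs, psi_leaf = hydraulic_gs(gs_max, psi_soil, vpd_leaf, params, pressure)
    gs = np.where(night, params.gmin, gs)
    e_flux = H2O_CO2_DIFF_RATIO * gs * vpd_leaf / pressure
    psi_leaf = psi_soil - e_flux / params.kmax_plant
    ci = ci_at_gs(gs)
    a_gross = np.maximum(gross(ci), 0.0)
    a_net = a_gross - rd
    return gs, ci, a_net, a_gross, rd, psi_leaf, vpd_leaf


def solve_leaf_states(met: pd.DataFrame, params: SpeciesParams,
                      psi_soil: float = -0.05, acclimation: str = "off",
                      t_growth=None, species: str | None = None,
                      r25_coefficients=None, q10_coefficients=None,
                      entropy_coefficients=None, t_growth_ref: float = 15.2,
                      eq3_printed_sign: bool = False,
                      max_outer: int = 50, tl_tol: float = 0.01,
                      solver_opts: dict | None = None,
                      ) -> pd.DataFrame:
    """Solve the coupled leaf state for every met record (vectorized).

    ``met`` needs columns tair_C, rh_pct, ppfd_umol_m2_s, wind_m_s, co2_ppm,
    pressure_kPa.  With ``acclimation='on'``, R_25 / Q_10 follow the
    species-specific linear acclimation lines and ΔS the growth-temperature
    coefficients, all evaluated at ``t_growth`` (scalar or per-record array:
    the 2-week antecedent mean air temperature).  With ``acclimation='off'``
    the same functions are evaluated at the frozen reference growth
    temperature ``t_growth_ref`` — so 'off' equals 'on' evaluated at the
    reference conditions.  Explicit ``params.ds_v``/``ds_j`` and
    ``params.r25``/``q10`` are used directly when no species is given.
    """
    if acclimation not in ("on", "off"):
        raise ValueError("acclimation must be 'on' or 'off'")
    tair = met["tair_C"].to_numpy(float)
    rh = met["rh_pct"].to_numpy(float)
    ppfd = met["ppfd_umol_m2_s"].to_numpy(float)
    wind = met["wind_m_s"].to_numpy(float) if "wind_m_s" in met else np.full_like(tair, 1.0)
    co2 = met["co2_ppm"].to_numpy(float) if "co2_ppm" in met else np.full_like(tair, 400.0)
    pressure = met["pressure_kPa"].to_numpy(float) if "pressure_kPa" in met \
        else np.full_like(tair, P_ATM_KPA)

    if acclimation == "on":
        if t_growth is None:
            raise ValueError("acclimation='on' requires t_growth")
        tg = np.broadcast_to(np.asarray(t_growth, dtype=float), tair.shape)
    else:
        tg = np.full_like(tair, float(t_growth_ref))

    if species is not None:
        r25 = acclimated_r25(species, tg, r25_coefficients)
        q10 = acclimated_q10(species, tg, q10_coefficients)
    else:
        r25 = np.full_like(tair, params.r25)
        q10 = np.full_like(tair, params.q10)
    ds_v = params.ds_v if params.ds_v is not None and species is None \
        else acclimate_entropy(tg, "vcmax", entropy_coefficients)
    ds_j = params.ds_j if params.ds_j is not None and species is None \
        else acclimate_entropy(tg, "jmax", entropy_coefficients)
    ds_v = np.broadcast_to(np.asarray(ds_v, dtype=float), tair.shape)
    ds_j = np.broadcast_to(np.asarray(ds_j, dtype=float), tair.shape)

    solver_opts = dict(solver_opts or {})
    eb_bisect = solver_opts.pop("eb_bisect", 42)
    t_leaf = tair.copy()
    converged = np.zeros(tair.shape, dtype=bool)
    iterations = np.zeros(tair.shape, dtype=int)
    gs = np.full(tair.shape, np.min(params.gmin))
    prev_delta = None
    max_fp = min(max_outer, 20)
    for it in range(max_fp):
        gs, ci, a_net, a_gross, rd, psi_leaf, vpd_leaf = _solve_inner(
            t_leaf, tair, ppfd, rh, co2, pressure, psi_soil, params,
            r25, q10, ds_v, ds_j, eq3_printed_sign, **solver_opts)
        tl_new = leaf_energy_balance(tair, ppfd, rh, wind, gs, params,
                                     pressure, n_bisect=eb_bisect)
        delta = tl_new - t_leaf
        just = (np.abs(delta) < tl_tol) & ~converged
        iterations[just] = it + 1
        converged |= np.abs(delta) < tl_tol
        if converged.all():
            break
        # Aitken-accelerated fixed point: estimate the contraction ratio of
        # the T_L map from successive corrections and extrapolate; falls back
        # to 0.5 damping on the first pass or when the ratio is unreliable
        if prev_delta is None:
            step = 0.5 * delta
        else:
            with np.errstate(divide="ignore", invalid="ignore"):
                lam = np.where(np.abs(prev_delta) > 1e-12,
                               delta / prev_delta, 0.0)
            lam = np.clip(lam, -0.9, 0.95)
            step = np.clip(delta / (1.0 - lam), -8.0, 8.0)
        prev_delta = delta
        t_leaf = np.where(converged, tl_new, t_leaf + step)

    # phase 2: the T_L map can jump where the stomatal optimum changes
    # branch, defeating any fixed-point scheme; solve the stragglers by
    # bracketed bisection on G(T_L) = EB(g_s(T_L)) − T_L, which is
    # deterministic and cannot limit-cycle
    if not converged.all():
        bad = np.flatnonzero(~converged)

        def subset(a):
            a = np.asarray(a)
            return a[bad] if a.ndim > 0 and a.shape == tair.shape else a

        p_sub = params
        array_fields = {
            f.name: subset(getattr(params, f.name))
            for f in fields(params)
            if np.ndim(getattr(params, f.name)) > 0
        }
        if array_fields:
            p_sub = replace(params, **array_fields)
        args_sub = (subset(tair), subset(ppfd), subset(rh), subset(co2),
                    subset(pressure))
        rq_sub = (subset(r25), subset(q10), subset(ds_v), subset(ds_j))
        wind_sub = subset(wind)

        def g_residual(tl_sub):
            gs_s, *_ = _solve_inner(
                tl_sub, args_sub[0], args_sub[1], args_sub[2], args_sub[3],
                args_sub[4], psi_soil, p_sub, *rq_sub, eq3_printed_sign,
                **solver_opts)
            tl_eb = leaf_energy_balance(args_sub[0], args_sub[1],
                                        args_sub[2], wind_sub, gs_s, p_sub,
                                        args_sub[4], n_bisect=eb_bisect)
            return tl_eb - tl_sub

        lo = args_sub[0] - 20.0
        hi = args_sub[0] + 25.0
        f_lo = g_residual(lo)
        for k in range(34):
            mid = 0.5 * (lo + hi)
            f_mid = g_residual(mid)
            same = (f_mid > 0) == (f_lo > 0)
            lo = np.where(same, mid, lo)
            f_lo = np.where(same, f_mid, f_lo)
            hi = np.where(same, hi, mid)
        tl_sub = 0.5 * (lo + hi)
        resid = g_residual(tl_sub)
        t_leaf[bad] = tl_sub
        converged[bad] = np.abs(resid) < tl_tol
        iterations[bad] = max_outer
    # final pass: gas exchange at the converged T_L, then one exact
    # energy-balance solve with the final g_s so the reported pair
    # (t_leaf, gs) closes the balance to the bisection tolerance
    gs, ci, a_net, a_gross, rd, psi_leaf, vpd_leaf = _solve_inner(
        t_leaf, tair, ppfd, rh, co2, pressure, psi_soil, params,
        r25, q10, ds_v, ds_j, eq3_printed_sign, **solver_opts)
    t_leaf = leaf_energy_balance(tair, ppfd, rh, wind, gs, params, pressure,
                                 n_bisect=eb_bisect)
    ea = rh / 100.0 * saturation_vapor_pressure(tair)
    _, e_mol = _energy_residual(t_leaf, tair, ppfd, ea, wind, gs, params,
                                pressure)
    return pd.DataFrame({
        "t_leaf": t_leaf, "gs": gs, "ci": ci, "a_net": a_net,
        "a_gross": a_gross, "rd": rd, "transpiration": e_mol * 1000.0,
        "psi_leaf": psi_leaf, "converged": converged,
        "iterations": iterations,
    }, index=met.index)


def solve_leaf_state(met_record, params: SpeciesParams, psi_soil: float = -0.05,
                     acclimation: str = "off", t_growth=None,
                     species: str | None = None, **kwargs) -> LeafState:
    """Solve one meteorological step; scalar convenience wrapper."""
    if isinstance(met_record, pd.Series):
        met = met_record.to_frame().T
    elif isinstance(met_record, dict):
        met = pd.DataFrame([met_record])
    else:
        met = pd.DataFrame(met_record).head(1)
    states = solve_leaf_states(met, params, psi_soil=psi_soil,
                               acclimation=acclimation, t_growth=t_growth,
                               species=species, **kwargs)
    row = states.iloc[0]
    return LeafState(
        t_leaf=float(row["t_leaf"]), gs=float(row["gs"]), ci=float(row["ci"]),
        a_net=float(row["a_net"]), a_gross=float(row["a_gross"]),
        rd=float(row["rd"]), transpiration=float(row["transpiration"]),
        psi_leaf=float(row["psi_leaf"]), converged=bool(row["converged"]),
        iterations=int(row["iterations"]),
    )


class LeafGasExchangeModel(BaseEstimator):
    """Scikit-learn style wrapper: parameters in, per-step leaf states out.

    ``predict(met, t_growth=...)`` returns the per-step state table from
    :func:`solve_leaf_states`.  ``get_params``/``set_params`` expose every
    constructor argument, so the model slots into sklearn model selection and
    the DE-MC calibrator.
    """

    def __init__(self, params: SpeciesParams | None = None,
                 species: str | None = None, acclimation: str = "off",
                 psi_soil: float = -0.05, t_growth_ref: float = 15.2,
                 eq3_printed_sign: bool = False):
        self.params = params
        self.species = species
        self.acclimation = acclimation
        self.psi_soil = psi_soil
        self.t_growth_ref = t_growth_ref
        self.eq3_printed_sign = eq3_printed_sign

    def _resolved_params(self) -> SpeciesParams:
        return self.params if self.params is not None else SpeciesParams()

    def fit(self, X=None, y=None):
        """No-op: the model is fully specified by its parameters."""
        self.params_ = self._resolved_params()
        return self

    def predict(self, met: pd.DataFrame, t_growth=None) -> pd.DataFrame:
        return solve_leaf_states(
            met, self._resolved_params(), psi_soil=self.psi_soil,
            acclimation=self.acclimation, t_growth=t_growth,
            species=self.species, t_growth_ref=self.t_growth_ref,
            eq3_printed_sign=self.eq3_printed_sign,
        )

    def with_params(self, **updates) -> "LeafGasExchangeModel":
        """Copy of the model with selected SpeciesParams fields replaced."""
        new = replace(self._resolved_params(), **updates)
        return LeafGasExchangeModel(
            params=new, species=self.species, acclimation=self.acclimation,
            psi_soil=self.psi_soil, t_growth_ref=self.t_growth_ref,
            eq3_printed_sign=self.eq3_printed_sign,
        )
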