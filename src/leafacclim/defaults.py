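"""Versioned default parameter sets.

Three groups of defaults live here:

* ``SPECIES_TRUTH`` — the generating truth used by :mod:`leafacclim.synthetic`
  for the three study species (the invasive windmill palm *Trachycarpus
  fortunei* and the native evergreen holly *Ilex aquifolium* and deciduous
  small-leaved linden *Tilia cordata*).  Trait values at a given 2-week
  antecedent air temperature follow linear acclimation lines
  ``trait = intercept + slope * T_antecedent``.
* ``SITES`` — the five transplant sites spanning mean annual air temperatures
  of 8.4–21.8 °C (cold alpine to semi-arid), each under 70 % shading.
* Biochemical/kinetic constants for the coupled leaf model, with literature
  provenance recorded next to each value.

Everything here is a default: all values are overridable through the
corresponding dataclass constructors or the YAML pipeline configuration.
"""

from __future__ import annotations

# --- R_25 acclimation lines (µmol m-2 s-1 as a function of the 2-week
#     antecedent air temperature, °C). Species-specific.
R25_ACCLIMATION = {
    "trachycarpus_fortunei": (0.50, -0.0037),
    "ilex_aquifolium": (1.42, -0.0293),
    "tilia_cordata": (1.36, -0.0317),
}

# Floor applied when extrapolating the R_25 lines to hot antecedent
# temperatures (the holly/linden lines cross zero near 43–48 °C).
R25_FLOOR = 0.01  # µmol m-2 s-1

# Q_10 acclimation: only the palm shifts Q_10 with antecedent temperature; the
# printed evidence gives the sign but no equation, so the palm slope is a
# documented placeholder. Natives carry slope 0.
Q10_ACCLIMATION = {
    "trachycarpus_fortunei": (2.34, -0.02),  # slope is a placeholder value
    "ilex_aquifolium": (2.2, 0.0),
    "tilia_cordata": (2.2, 0.0),
}

# --- Species generating truth for the synthetic transplant experiment.
# Intercepts are anchored so that each line passes through the species mean
# trait value at the gradient-mean antecedent temperature of 17 °C:
# e.g. palm T_opt: 21.3 = intercept + 0.60 * 17.
# Curvature b is set from the species-mean A_opt and thermal breadth T_80 via
# b = 0.8 * A_opt / T_80**2 (the breadth closed form inverted).
SPECIES_TRUTH_TABLE = {
    "trachycarpus_fortunei": dict(
        topt_intercept=11.1, topt_slope=0.60,       # mean T_opt 21.3 °C
        aopt_intercept=0.14, aopt_slope=0.16,       # mean A_opt 2.86
        t80_intercept=7.87, t80_slope=0.19,         # mean T_80 11.1 °C
        r25_intercept=0.50, r25_slope=-0.0037,
        q10_intercept=2.34, q10_slope=-0.02,
        curvature_b=0.0186,
        obs_noise_sd_a=0.2, obs_noise_sd_r=0.03,
    ),
    "ilex_aquifolium": dict(
        topt_intercept=13.35, topt_slope=0.55,      # mean T_opt 22.7 °C
        aopt_intercept=2.27, aopt_slope=0.19,       # mean A_opt 5.5
        t80_intercept=13.9, t80_slope=0.0,          # no breadth acclimation
        r25_intercept=1.42, r25_slope=-0.0293,
        q10_intercept=2.2, q10_slope=0.0,
        curvature_b=0.0228,
        obs_noise_sd_a=0.2, obs_noise_sd_r=0.03,
    ),
    "tilia_cordata": dict(
        topt_intercept=18.29, topt_slope=0.33,      # mean T_opt 23.9 °C
        aopt_intercept=6.96, aopt_slope=0.0,        # A_opt not acclimating
        t80_intercept=15.2, t80_slope=0.0,
        r25_intercept=1.36, r25_slope=-0.0317,
        q10_intercept=2.2, q10_slope=0.0,
        curvature_b=0.0241,
        obs_noise_sd_a=0.2, obs_noise_sd_r=0.03,
    ),
}

# --- Five transplant sites; mean annual air temperature of the measured
# period, coldest to warmest. All sites share the 70 % shading infrastructure.
SITE_TABLE = {
    "cold": dict(mean_annual_tair=8.4, seasonal_amplitude=9.0),
    "temperate": dict(mean_annual_tair=13.3, seasonal_amplitude=8.5),
    "sub_mediterranean": dict(mean_annual_tair=15.2, seasonal_amplitude=8.5),
    "mediterranean": dict(mean_annual_tair=17.7, seasonal_amplitude=8.0),
    "semi_arid": dict(mean_annual_tair=21.8, seasonal_amplitude=7.0),
}
REFERENCE_SITE = "sub_mediterranean"
SHADING_FRACTION = 0.70

# --- Peaked-Arrhenius kinetics of V_C,max and J_max.
# Entropy terms acclimate linearly to growth temperature with the general
# coefficients of Kattge & Knorr (2007) Plant Cell Environ 30:1176 (their
# Table 3): ΔS_v = 668.39 − 1.07 T_g, ΔS_j = 659.70 − 0.75 T_g [J mol-1 K-1,
# T_g in °C]; Ha_v = 71.513 kJ mol-1, Ha_j = 49.884 kJ mol-1, Hd = 200 kJ mol-1.
ENTROPY_COEFFICIENTS = {
    "vcmax": (668.39, -1.07),
    "jmax": (659.70, -0.75),
}
HA_VCMAX = 71.513  # kJ mol-1
HA_JMAX = 49.884   # kJ mol-1
HD_DEACT = 200.0   # kJ mol-1

# --- Rubisco kinetics and CO2 compensation point, Bernacchi et al. (2001)
# Plant Cell Environ 24:253. Values at 25 °C with Arrhenius activation
# energies (kJ mol-1); O2 mole fraction 210 mmol mol-1.
GAMMA_STAR_25 = 42.75   # µmol mol-1
HA_GAMMA_STAR = 37.83
KC_25 = 404.9           # µmol mol-1
HA_KC = 79.43
KO_25 = 278.4           # mmol mol-1
HA_KO = 36.38
O2_MMOL = 210.0

# Electron transport: non-rectangular hyperbola of absorbed PPFD.
J_CURVATURE_THETA = 0.90
J_QUANTUM_YIELD = 0.30   # mol e- per mol photons incident, effective

# --- Stomatal-optimum formula constants (D, E, F).
# g_s,max = [B(C_i − Γ) − R_d(D C_i + E)] / [(E + F)(C_i − C_a)].
# D, E, F are effective constants: their source definitions are not public,
# so they default to values placing the interior stomatal optimum in the
# observed 0.05–0.3 mol m-2 s-1 range (E + F < 0 makes g_s,max positive for
# C_i < C_a) and they are the first candidates for DE-MC calibration.
EQ4_D = 0.0
EQ4_E = 50.0
EQ4_F = -200.0
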