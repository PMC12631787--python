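"""Physical constants and small psychrometric helpers.

All temperatures cross module boundaries in degrees Celsius and are converted
to Kelvin only inside Arrhenius-type expressions.
"""

import numpy as np

R_GAS = 8.314  # J mol-1 K-1
T0_K = 273.15
TREF_C = 25.0
TREF_K = TREF_C + T0_K

MOLAR_MASS_C = 12.011  # g mol-1
STEFAN_BOLTZMANN = 5.670374419e-8  # W m-2 K-4
CP_MOLAR_AIR = 29.2  # J mol-1 K-1, molar heat capacity of dry air
LAMBDA_VAP = 44100.0  # J mol-1, latent heat of vaporization of water (~25 C)
J_PER_UMOL_PAR = 0.2175  # W s umol-1, energy content of PAR quanta (1/4.6)
P_ATM_KPA = 101.325
H2O_CO2_DIFF_RATIO = 1.6  # stomatal diffusivity ratio water:CO2


def saturation_vapor_pressure(t_c):
    """Saturation vapor pressure (kPa) via the Tetens formula."""
    t_c = np.asarray(t_c, dtype=float)
    return 0.61078 * np.exp(17.27 * t_c / (t_c + 237.3))


def vpd_from_rh(t_c, rh_pct):
    """Vapor pressure deficit (kPa) of air at temperature ``t_c`` and RH %."""
    es = saturation_vapor_pressure(t_c)
    return es * (1.0 - np.asarray(rh_pct, dtype=float) / 100.0)
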