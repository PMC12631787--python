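import numpy as np
import pandas as pd
import pytest

import leafacclim as la


@pytest.fixture
def default_params():
    return la.SpeciesParams()


@pytest.fixture
def midday_met():
    """Single clear mid-day meteorological record."""
    return pd.DataFrame({
        "timestamp": [pd.Timestamp("2023-07-01 12:00")],
        "tair_C": [25.0], "rh_pct": [60.0], "ppfd_umol_m2_s": [1200.0],
        "wind_m_s": [1.0], "co2_ppm": [400.0], "pressure_kPa": [101.325],
    })


@pytest.fixture
def day_met():
    """One synthetic summer day at 30-min steps, moderate shading."""
    site = la.SiteConfig(site_id="ref", mean_annual_tair=20.0,
                         seasonal_amplitude=0.0, diurnal_amplitude=8.0,
                         noise_sd_tair=0.0, shading_fraction=0.3)
    return la.generate_met_series(site, start_date="2023-07-01", n_days=1,
                                  step_minutes=30, seed=0)
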