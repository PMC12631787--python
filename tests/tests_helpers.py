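"""Shared helpers for the test suite."""

import pandas as pd


def constant_met_frame(n_steps, tair=20.0, ppfd=0.0, rh=70.0,
                       step_minutes=30, start="2023-01-01"):
    ts = pd.date_range(start, periods=n_steps, freq=f"{step_minutes}min")
    return pd.DataFrame({
        "timestamp": ts, "tair_C": float(tair), "rh_pct": float(rh),
        "ppfd_umol_m2_s": float(ppfd), "wind_m_s": 1.0, "co2_ppm": 400.0,
        "pressure_kPa": 101.325,
    })
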