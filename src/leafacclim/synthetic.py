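"""Synthetic transplant-experiment data with known generating truth.

Emulates the statistical structure the analysis chain assumes: five sites
spanning mean annual air temperatures of 8.4–21.8 °C under 70 % shading,
three species with distinct trait means, six measurement campaigns of 4–10
individuals, diurnal assimilation–temperature curves at 5–6 time points
spanning roughly 12–35 °C, and linear acclimation of every trait to the mean
air temperature of the two weeks preceding each campaign.

All per-campaign generating parameters are *linear in the antecedent
temperature* by construction, so downstream recovery of the acclimation
slopes is a well-posed inference problem with a known answer.  Every function
takes a seed (or ``numpy.random.Generator``); per-individual substreams are
spawned from it, so any subset of the data is reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import defaults as dflt
from ._constants import P_ATM_KPA, saturation_vapor_pressure

MET_COLUMNS = ["timestamp", "tair_C", "rh_pct", "ppfd_umol_m2_s",
               "wind_m_s", "co2_ppm", "pressure_kPa"]
GASEX_COLUMNS = ["site", "species", "individual", "campaign", "timestamp",
                 "mode", "tleaf_C", "anet_umol_m2_s", "ppfd", "vpd_kPa",
                 "co2_ppm"]


@dataclass
class SiteConfig:
    """Meteorological configuration of one transplant site."""

    site_id: str
    mean_annual_tair: float          # °C
    seasonal_amplitude: float = 8.5  # °C, half-range of the annual sinusoid
    diurnal_amplitude: float = 8.0   # °C, day-night range
    noise_sd_tair: float = 1.5       # °C
    shading_fraction: float = dflt.SHADING_FRACTION
    daylength_hours: float = 12.0
    rh_mean: float = 70.0            # % at the site mean temperature
    co2_ambient: float = 400.0       # ppm
    ppfd_max: float = 1800.0         # µmol m-2 s-1, unshaded clear-sky peak
    wind_mean: float = 1.0           # m s-1

    def __post_init__(self):
        if not 0 <= self.shading_fraction < 1:
            raise ValueError("shading_fraction must be in [0, 1)")
        if self.seasonal_amplitude < 0 or self.diurnal_amplitude < 0:
            raise ValueError("amplitudes must be >= 0")
        if not 0 < self.rh_mean <= 100:
            raise ValueError("rh_mean must be in (0, 100]")


@dataclass
class SpeciesTruth:
    """Generating truth: linear trait acclimation to antecedent temperature."""

    species_id: str
    topt_intercept: float
    topt_slope: float
    aopt_intercept: float
    aopt_slope: float
    t80_intercept: float
    t80_slope: float
    r25_intercept: float
    r25_slope: float
    q10_intercept: float
    q10_slope: float
    curvature_b: float
    obs_noise_sd_a: float = 0.2
    obs_noise_sd_r: float = 0.03

    def __post_init__(self):
        if self.curvature_b <= 0:
            raise ValueError("curvature_b must be positive")
        if self.q10_intercept <= 1:
            raise ValueError("Q10 intercept must exceed 1")

    def generating_traits(self, antecedent_tair) -> dict:
        """Noise-free per-campaign trait values at an antecedent temperature.

        The parabola curvature is tied to the optimum and the breadth,
        ``b = 0.8 A_opt / T_80²``, so that the generated curves carry exactly
        the configured linear T_80 acclimation; ``curvature_b`` is used only
        when no breadth line is configured (t80_intercept <= 0).
        """
        t = np.asarray(antecedent_tair, dtype=float)
        traits = {
            "t_opt": self.topt_intercept + self.topt_slope * t,
            "a_opt": self.aopt_intercept + self.aopt_slope * t,
            "t80": self.t80_intercept + self.t80_slope * t,
            "r25": np.maximum(self.r25_intercept + self.r25_slope * t,
                              dflt.R25_FLOOR),
            "q10": np.maximum(self.q10_intercept + self.q10_slope * t, 1.0),
        }
        if np.any(traits["a_opt"] <= 0):
            raise ValueError("generating A_opt <= 0 in the configured range")
        if self.t80_intercept > 0:
            if np.any(traits["t80"] <= 0):
                raise ValueError("generating T_80 <= 0 in the configured range")
            traits["b"] = 0.8 * traits["a_opt"] / traits["t80"] ** 2
        else:
            traits["b"] = np.broadcast_to(
                np.asarray(self.curvature_b, dtype=float), t.shape
            ) if t.shape else float(self.curvature_b)
        return traits


@dataclass
class CampaignDesign:
    """Layout of the measurement campaigns."""

    n_campaigns: int = 6
    months: tuple = (5, 7, 9, 17, 19, 21)  # month index from start (2 seasons)
    n_individuals: int = 10
    n_timepoints_per_day: int = 6
    tair_range: tuple = (12.0, 35.0)

    def __post_init__(self):
        if self.n_timepoints_per_day not in (5, 6):
            raise ValueError("n_timepoints_per_day must be 5 or 6")
        if self.tair_range[0] >= self.tair_range[1]:
            raise ValueError("tair_range must be (min, max) with min < max")


def default_species_truth(species_id: str) -> SpeciesTruth:
    """Packaged generating truth for one of the three study species."""
    if species_id not in dflt.SPECIES_TRUTH_TABLE:
        raise KeyError(f"unknown species {species_id!r}; "
                       f"known: {sorted(dflt.SPECIES_TRUTH_TABLE)}")
    return SpeciesTruth(species_id=species_id,
                        **dflt.SPECIES_TRUTH_TABLE[species_id])


def default_sites() -> list[SiteConfig]:
    """The five transplant sites, coldest to warmest."""
    return [SiteConfig(site_id=k, **v) for k, v in dflt.SITE_TABLE.items()]


# ---------------------------------------------------------------------------
# meteorological drivers


def generate_met_series(site: SiteConfig, start_date="2022-10-15",
                        n_days: int = 365, step_minutes: int = 30,
                        seed=0) -> pd.DataFrame:
    """Half-hourly (by default) meteorological driver series for one site.

    Air temperature is a seasonal plus diurnal sinusoid around the site mean
    with additive Gaussian noise; PPFD is a clear-sky half-sine over the
    daylight window scaled by (1 − shading_fraction) and zero at night; RH is
    anti-correlated with temperature through a fixed site dew point (vapor
    pressure pinned at ``rh_mean`` % of saturation at the site mean
    temperature).  Sinusoid phases peak in mid-July / mid-afternoon.
    """
    if n_days < 1:
        raise ValueError("n_days must be >= 1")
    if 1440 % step_minutes != 0:
        raise ValueError("step_minutes must divide a day (1440)")
    rng = np.random.default_rng(seed)
    steps_per_day = 1440 // step_minutes
    n = n_days * steps_per_day
    timestamps = pd.date_range(start=pd.Timestamp(start_date), periods=n,
                               freq=f"{step_minutes}min", tz="UTC")
    doy = timestamps.dayofyear.to_numpy(float)
    hour = (timestamps.hour + timestamps.minute / 60.0).to_numpy(float)

    seasonal = site.seasonal_amplitude * np.cos(2 * np.pi * (doy - 196.0) / 365.0)
    diurnal = -0.5 * site.diurnal_amplitude * np.cos(2 * np.pi * (hour - 2.0) / 24.0)
    noise = rng.normal(0.0, site.noise_sd_tair, size=n)
    tair = site.mean_annual_tair + seasonal + diurnal + noise

    sunrise = 12.0 - site.daylength_hours / 2.0
    phase = (hour - sunrise) / site.daylength_hours
    ppfd = np.where((phase > 0) & (phase < 1),
                    site.ppfd_max * np.sin(np.pi * np.clip(phase, 0, 1)),
                    0.0) * (1.0 - site.shading_fraction)

    ea = site.rh_mean / 100.0 * saturation_vapor_pressure(site.mean_annual_tair)
    rh = np.clip(100.0 * ea / saturation_vapor_pressure(tair), 5.0, 100.0)

    return pd.DataFrame({
        "timestamp": timestamps,
        "tair_C": tair,
        "rh_pct": rh,
        "ppfd_umol_m2_s": ppfd,
        "wind_m_s": np.full(n, site.wind_mean),
        "co2_ppm": np.full(n, site.co2_ambient),
        "pressure_kPa": np.full(n, P_ATM_KPA),
    })


# ---------------------------------------------------------------------------
# gas-exchange observations


def _campaign_timestamps(met: pd.DataFrame, design: CampaignDesign):
    """Mid-morning campaign dates, one per configured month index."""
    ts = pd.to_datetime(met["timestamp"])
    start = ts.iloc[0]
    dates = []
    for m in design.months[: design.n_campaigns]:
        at = (start + pd.DateOffset(months=int(m))).normalize() + pd.Timedelta(hours=9)
        if at > ts.iloc[-1]:
            raise ValueError(f"campaign month index {m} falls outside the met series")
        dates.append(at)
    return dates


def generate_response_observations(truth: SpeciesTruth, design: CampaignDesign,
                                   met: pd.DataFrame, mode: str = "light",
                                   seed=0, site_id: str = "site",
                                   ) -> pd.DataFrame:
    """Per-individual gas-exchange curves for every campaign, driven by met.

    For each campaign the generating T_opt/A_opt/R_25/Q_10 are evaluated on
    the species acclimation lines at the 2-week antecedent mean temperature
    taken from ``met``; observed points are the generating curve at
    ``n_timepoints_per_day`` measurement temperatures spanning ``tair_range``
    plus Gaussian noise.  Light-mode points carry saturating PPFD (1500) and
    dark-mode points PPFD 0.
    """
    from .acclimation import antecedent_mean_tair  # local: avoid cycle

    if mode not in ("light", "dark"):
        raise ValueError("mode must be 'light' or 'dark'")
    rng = np.random.default_rng(seed)
    dates = _campaign_timestamps(met, design)
    lo, hi = design.tair_range
    rows = []
    for c_idx, at in enumerate(dates, start=1):
        antecedent = antecedent_mean_tair(met, at)
        traits = truth.generating_traits(antecedent)
        for ind in range(1, design.n_individuals + 1):
            sub = rng.spawn(1)[0]
            base = np.linspace(lo, hi, design.n_timepoints_per_day)
            temps = base + sub.uniform(-1.0, 1.0, size=base.size)
            if mode == "light":
                mean = traits["a_opt"] - traits["b"] * (
                    temps - traits["t_opt"]) ** 2
                obs = mean + sub.normal(0.0, truth.obs_noise_sd_a, temps.size)
                ppfd, vpd = 1500.0, 1.2
            else:
                mean = traits["r25"] * traits["q10"] ** ((temps - 25.0) / 10.0)
                obs = mean + sub.normal(0.0, truth.obs_noise_sd_r, temps.size)
                obs = np.maximum(obs, 1e-4)  # respiration fluxes stay positive
                ppfd, vpd = 0.0, 1.0
            for t_i, y_i in zip(temps, obs):
                rows.append(dict(
                    site=site_id, species=truth.species_id, individual=ind,
                    campaign=c_idx, timestamp=at, mode=mode,
                    tleaf_C=float(t_i), anet_umol_m2_s=float(y_i), ppfd=ppfd,
                    vpd_kPa=vpd, co2_ppm=400.0,
                    antecedent_tair_C=float(antecedent),
                ))
    return pd.DataFrame(rows)


def generate_campaign_curves(truth: SpeciesTruth, n_campaigns: int = 30,
                             antecedent_range=(8.0, 25.0),
                             n_timepoints: int = 6,
                             tair_range=(12.0, 35.0), mode: str = "light",
                             noise_sd: float | None = None, seed=0,
                             ) -> pd.DataFrame:
    """Condensed recovery design: campaigns laid out directly on an
    antecedent-temperature grid.

    Campaign antecedent temperatures are evenly spaced over
    ``antecedent_range`` (the span the pooled transplant gradient produces);
    one curve per campaign.  This is the design used for slope-recovery
    checks, where the met-driver machinery would only add noise to a known
    regressor.
    """
    if mode not in ("light", "dark"):
        raise ValueError("mode must be 'light' or 'dark'")
    rng = np.random.default_rng(seed)
    antecedents = np.linspace(*antecedent_range, n_campaigns)
    if noise_sd is None:
        noise_sd = truth.obs_noise_sd_a if mode == "light" else truth.obs_noise_sd_r
    rows = []
    for c_idx, ant in enumerate(antecedents, start=1):
        traits = truth.generating_traits(ant)
        temps = np.linspace(*tair_range, n_timepoints) + rng.uniform(
            -1.0, 1.0, n_timepoints)
        if mode == "light":
            mean = traits["a_opt"] - traits["b"] * (temps - traits["t_opt"]) ** 2
            ppfd = 1500.0
        else:
            mean = traits["r25"] * traits["q10"] ** ((temps - 25.0) / 10.0)
            ppfd = 0.0
        obs = mean + rng.normal(0.0, noise_sd, temps.size)
        if mode == "dark":
            obs = np.maximum(obs, 1e-4)
        for t_i, y_i in zip(temps, obs):
            rows.append(dict(
                site="grid", species=truth.species_id, individual=1,
                campaign=c_idx, timestamp=pd.NaT, mode=mode,
                tleaf_C=float(t_i), anet_umol_m2_s=float(y_i), ppfd=ppfd,
                vpd_kPa=1.0, co2_ppm=400.0, antecedent_tair_C=float(ant),
            ))
    return pd.DataFrame(rows)


def generate_diurnal_anet(params, met: pd.DataFrame, noise_sd: float = 0.5,
                          seed=0, species=None, acclimation="off",
                          t_growth=None) -> pd.DataFrame:
    """Diurnal A_net observations: forward model plus Gaussian noise.

    Runs the coupled leaf model over ``met`` and adds observation noise —
    the calibration fixture with known truth.  Columns: timestamp,
    anet_obs_umol_m2_s, anet_true_umol_m2_s.
    """
    from .spac import solve_leaf_states  # local import: avoid cycle

    rng = np.random.default_rng(seed)
    states = solve_leaf_states(met, params, acclimation=acclimation,
                               t_growth=t_growth, species=species)
    if not states["converged"].all():
        bad = int((~states["converged"]).sum())
        raise RuntimeError(f"forward model failed to converge at {bad} steps")
    true = states["a_net"].to_numpy()
    obs = true + rng.normal(0.0, noise_sd, size=true.size)
    return pd.DataFrame({
        "timestamp": met["timestamp"].to_numpy(),
        "anet_obs_umol_m2_s": obs,
        "anet_true_umol_m2_s": true,
    })
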