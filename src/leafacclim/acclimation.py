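"""Trait acclimation to antecedent air temperature.

Thermal acclimation is quantified by regressing campaign-level fitted traits
(T_opt, A_opt, T_80, R_25, Q_10) on the mean air temperature of the two weeks
preceding each measurement campaign (ordinary least squares).  The fitted
species-specific lines — most importantly the R_25 lines used inside the
simulator — are exposed through :func:`acclimated_r25` / :func:`acclimated_q10`.
A thin two-way ANOVA + Tukey HSD summary stage covers the species x climate
trait comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .defaults import Q10_ACCLIMATION, R25_ACCLIMATION, R25_FLOOR

VALID_TRAITS = ("t_opt", "a_opt", "t80", "r25", "q10")


@dataclass
class AcclimationModel:
    """OLS fit of one trait against antecedent air temperature."""

    trait: str
    species: str
    intercept: float
    slope: float
    r_squared: float
    p_value: float
    n: int
    stderr_slope: float = np.nan
    stderr_intercept: float = np.nan

    def predict(self, antecedent_tair):
        return self.intercept + self.slope * np.asarray(antecedent_tair, float)


# ---------------------------------------------------------------------------
# antecedent temperature


def antecedent_mean_tair(met: pd.DataFrame, at, window_days: int = 14) -> float:
    """Mean air temperature over the closed-open window [at − window, at).

    ``met`` is a met-driver table with ``timestamp`` and ``tair_C`` columns at
    a regular step.  A coverage gap larger than one step inside the window is
    rejected with the missing span reported.
    """
    at = pd.Timestamp(at)
    ts = pd.to_datetime(met["timestamp"])
    tz = getattr(ts.dtype, "tz", None)
    if tz is not None and at.tzinfo is None:
        at = at.tz_localize(tz)
    start = at - pd.Timedelta(days=window_days)
    mask = (ts >= start) & (ts < at)
    sel = met.loc[mask]
    if sel.empty:
        raise ValueError(f"no met coverage in [{start}, {at})")
    tsel = ts[mask]
    step = tsel.diff().dropna().min()
    if pd.isna(step):
        raise ValueError("window contains a single record; cannot check coverage")
    gaps = tsel.diff()
    if (gaps > step).any():
        i = int(np.argmax((gaps > step).to_numpy()))
        raise ValueError(
            f"met coverage gap inside window: missing span after {tsel.iloc[i - 1]}"
        )
    if tsel.iloc[0] - start > step or at - tsel.iloc[-1] > step:
        raise ValueError(f"met does not cover the full window [{start}, {at})")
    return float(sel["tair_C"].mean())


# ---------------------------------------------------------------------------
# trait ~ antecedent temperature regression


class TraitAcclimationRegression(BaseEstimator):
    """OLS of a trait on antecedent air temperature (scikit-learn style).

    Fitted attributes: ``slope_``, ``intercept_``, ``r_squared_``,
    ``p_value_`` (two-sided, slope = 0), ``stderr_slope_``, ``n_``.
    """

    def fit(self, X, y):
        x = np.asarray(X, dtype=float).ravel()
        t = np.asarray(y, dtype=float).ravel()
        keep = np.isfinite(x) & np.isfinite(t)
        x, t = x[keep], t[keep]
        if x.size < 3:
            raise ValueError("need at least 3 paired finite values")
        if np.ptp(x) == 0:
            raise ValueError("zero variance in antecedent temperature")
        res = sm.OLS(t, sm.add_constant(x)).fit()
        self.intercept_ = float(res.params[0])
        self.slope_ = float(res.params[1])
        self.r_squared_ = float(res.rsquared)
        self.p_value_ = float(res.pvalues[1])
        self.stderr_intercept_ = float(res.bse[0])
        self.stderr_slope_ = float(res.bse[1])
        self.n_ = int(x.size)
        return self

    def predict(self, X):
        check_is_fitted(self, "slope_")
        return self.intercept_ + self.slope_ * np.asarray(X, float).ravel()


def regress_trait(trait_values, antecedent_temps, trait: str,
                  species: str = "") -> AcclimationModel:
    """OLS slope/intercept/R²/p of one trait against antecedent temperature."""
    if trait not in VALID_TRAITS:
        raise ValueError(f"unknown trait {trait!r}; expected one of {VALID_TRAITS}")
    est = TraitAcclimationRegression().fit(antecedent_temps, trait_values)
    return AcclimationModel(
        trait=trait, species=species,
        intercept=est.intercept_, slope=est.slope_,
        r_squared=est.r_squared_, p_value=est.p_value_, n=est.n_,
        stderr_slope=est.stderr_slope_, stderr_intercept=est.stderr_intercept_,
    )


def fit_acclimation_models(fits: pd.DataFrame,
                           traits=VALID_TRAITS) -> pd.DataFrame:
    """Regress every available trait on antecedent temperature per species.

    ``fits`` is the per-individual-campaign fit table from
    :func:`leafacclim.response_curves.fit_curves_table` with an
    ``antecedent_tair_C`` column.  The regression unit is the campaign mean
    per species (sites pooled, recorded upstream as metadata), matching the
    campaign-averaged analysis.  Flagged fits are excluded; exclusion counts
    are reported in the ``n_excluded`` column.
    """
    rows = []
    for species, sub in fits.groupby("species"):
        ok = sub[sub["flag"] == "ok"]
        n_excluded = len(sub) - len(ok)
        group_cols = [c for c in ("site", "campaign") if c in ok.columns]
        camp = ok.groupby(group_cols, as_index=False).mean(numeric_only=True)
        for trait in traits:
            if trait not in camp.columns or camp[trait].notna().sum() < 3:
                continue
            model = regress_trait(
                camp[trait], camp["antecedent_tair_C"], trait, species
            )
            rows.append(dict(
                trait=trait, species=species, intercept=model.intercept,
                slope=model.slope, r2=model.r_squared, p=model.p_value,
                n=model.n, stderr_slope=model.stderr_slope,
                stderr_intercept=model.stderr_intercept, n_excluded=n_excluded,
            ))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# species acclimation functions used by the simulator


def acclimated_r25(species: str, antecedent_tair, coefficients=None,
                   floor: float = R25_FLOOR):
    """R_25 (µmol m-2 s-1) from the species-specific linear acclimation line.

    ``coefficients`` maps species to (intercept, slope); defaults to the
    packaged lines.  The result is clamped at a positive floor so that
    extrapolation to very hot antecedent temperatures never yields negative
    respiration.
    """
    table = R25_ACCLIMATION if coefficients is None else coefficients
    if species not in table:
        raise KeyError(f"unknown species {species!r}; known: {sorted(table)}")
    intercept, slope = table[species]
    value = intercept + slope * np.asarray(antecedent_tair, dtype=float)
    return np.maximum(value, floor) if value.ndim else float(max(value, floor))


def acclimated_q10(species: str, antecedent_tair, coefficients=None,
                   floor: float = 1.0):
    """Q_10 from the species acclimation line (slope 0 for non-acclimating
    species), floored at 1 (respiration never decreases with warming)."""
    table = Q10_ACCLIMATION if coefficients is None else coefficients
    if species not in table:
        raise KeyError(f"unknown species {species!r}; known: {sorted(table)}")
    intercept, slope = table[species]
    value = intercept + slope * np.asarray(antecedent_tair, dtype=float)
    return np.maximum(value, floor) if value.ndim else float(max(value, floor))


# ---------------------------------------------------------------------------
# ANOVA summary stage


def trait_anova(fits: pd.DataFrame, trait: str) -> dict:
    """Two-way ANOVA (species x climate) with Tukey HSD post-hoc tables.

    Requires >=2 species and >=2 sites with >=2 replicates per cell; empty
    design cells are rejected naming the missing cell.  Returns a dict with
    the ANOVA table (as records) and per-factor Tukey summaries.
    """
    if trait not in fits.columns:
        raise ValueError(f"trait column {trait!r} missing from fits table")
    data = fits[["species", "site", trait]].dropna().rename(columns={trait: "y"})
    species = sorted(data["species"].unique())
    sites = sorted(data["site"].unique())
    if len(species) < 2 or len(sites) < 2:
        raise ValueError("need >=2 species and >=2 sites")
    counts = data.groupby(["species", "site"]).size()
    for sp in species:
        for st in sites:
            if counts.get((sp, st), 0) < 2:
                raise ValueError(f"design cell ({sp}, {st}) has <2 replicates")

    model = smf.ols("y ~ C(species) * C(site)", data=data).fit()
    if model.ssr < 1e-12:  # zero residual variance: F undefined
        anova_records = [
            {"term": t, "F": np.nan, "p": np.nan,
             "note": "zero residual variance"}
            for t in ("C(species)", "C(site)", "C(species):C(site)")
        ]
    else:
        table = sm.stats.anova_lm(model, typ=2)
        anova_records = [
            {"term": idx, "F": float(row["F"]), "p": float(row["PR(>F)"]),
             "df": float(row["df"]), "sum_sq": float(row["sum_sq"])}
            for idx, row in table.iterrows() if idx != "Residual"
        ]
    out = {"trait": trait, "anova": anova_records}
    for factor in ("species", "site"):
        if data.groupby(factor)["y"].var().max() < 1e-12 and len(
            data["y"].unique()
        ) == 1:
            out[f"tukey_{factor}"] = []
            continue
        tuk = pairwise_tukeyhsd(data["y"], data[factor])
        header = tuk.summary().data[0]
        out[f"tukey_{factor}"] = [
            dict(zip(header, row)) for row in tuk.summary().data[1:]
        ]
    return out
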