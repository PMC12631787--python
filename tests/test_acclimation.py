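"""Antecedent temperature, trait regressions and the ANOVA summary stage."""

import numpy as np
import pandas as pd
import pytest

import leafacclim as la
from tests_helpers import constant_met_frame


class TestAntecedentMean:
    def test_constant_series(self):
        met = constant_met_frame(15 * 48, tair=20.0)
        assert la.antecedent_mean_tair(met, "2023-01-15") == 20.0

    def test_alternating_days_symmetry(self):
        met = constant_met_frame(15 * 48)
        day = pd.to_datetime(met["timestamp"]).dt.dayofyear
        met["tair_C"] = np.where(day % 2 == 0, 10.0, 30.0)
        assert la.antecedent_mean_tair(met, "2023-01-15") == pytest.approx(
            20.0)

    def test_linear_ramp(self):
        met = constant_met_frame(14 * 48)
        met["tair_C"] = np.linspace(10, 24, 14 * 48)
        at = met["timestamp"].iloc[-1] + pd.Timedelta(minutes=30)
        assert la.antecedent_mean_tair(met, at) == pytest.approx(17.0,
                                                                 abs=1e-9)

    def test_window_exactness_vs_manual_slice(self):
        rng = np.random.default_rng(0)
        met = constant_met_frame(20 * 48)
        met["tair_C"] = rng.normal(15, 5, len(met))
        at = pd.Timestamp("2023-01-18")
        manual = met[(met["timestamp"] >= at - pd.Timedelta(days=14))
                     & (met["timestamp"] < at)]["tair_C"].mean()
        assert la.antecedent_mean_tair(met, at) == pytest.approx(manual,
                                                                 abs=1e-12)

    def test_gap_rejected_with_span(self):
        met = constant_met_frame(15 * 48)
        met = met.drop(index=range(300, 330)).reset_index(drop=True)
        with pytest.raises(ValueError, match="gap"):
            la.antecedent_mean_tair(met, "2023-01-15")

    def test_short_coverage_rejected(self):
        met = constant_met_frame(5 * 48)
        with pytest.raises(ValueError):
            la.antecedent_mean_tair(met, "2023-01-15")


class TestRegressTrait:
    def test_exact_line(self):
        x = np.array([1.0, 2, 3, 4, 5])
        m = la.regress_trait(2 + 0.6 * x, x, "t_opt")
        assert m.slope == pytest.approx(0.6, abs=1e-12)
        assert m.intercept == pytest.approx(2.0, abs=1e-12)
        assert m.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_slope_recovery_under_generator_noise(self):
        truth = la.default_species_truth("trachycarpus_fortunei")
        obs = la.generate_campaign_curves(truth, n_campaigns=30, seed=11)
        fits = la.fit_curves_table(obs, group_cols=("site", "campaign"))
        m = la.regress_trait(fits["t_opt"], fits["antecedent_tair_C"],
                             "t_opt")
        assert abs(m.slope - truth.topt_slope) < 2 * m.stderr_slope + 0.02

    def test_shuffled_pairing_loses_significance(self):
        rng = np.random.default_rng(21)
        x = np.linspace(8, 25, 30)
        y = 10 + 0.6 * x + rng.normal(0, 1.0, 30)
        n_null = sum(
            la.regress_trait(rng.permutation(y), x, "t_opt").p_value > 0.05
            for _ in range(100)
        )
        assert n_null >= 90

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            la.regress_trait([1.0, 2, 3], [5.0, 5, 5], "t_opt")
        with pytest.raises(ValueError, match="unknown trait"):
            la.regress_trait([1.0, 2, 3], [1.0, 2, 3], "bogus")


class TestAcclimationFunctions:
    def test_palm_line_at_intercept_reference(self):
        assert la.acclimated_r25("trachycarpus_fortunei", 0.0) == 0.50

    def test_linden_line_at_20C(self):
        assert la.acclimated_r25("tilia_cordata", 20.0) == pytest.approx(
            1.36 - 0.0317 * 20, abs=1e-12)

    def test_holly_line_slope(self):
        r15 = la.acclimated_r25("ilex_aquifolium", 15.0)
        r16 = la.acclimated_r25("ilex_aquifolium", 16.0)
        assert r16 - r15 == pytest.approx(-0.0293, abs=1e-12)

    def test_floor_on_hot_extrapolation(self):
        assert la.acclimated_r25("tilia_cordata", 60.0) == 0.01

    def test_zero_slope_config(self):
        coef = {"x": (0.7, 0.0)}
        assert la.acclimated_r25("x", 5.0, coef) == \
            la.acclimated_r25("x", 35.0, coef) == 0.7

    def test_unknown_species_rejected(self):
        with pytest.raises(KeyError):
            la.acclimated_r25("quercus_robur", 15.0)

    def test_generator_consistency(self):
        """The simulator's R_25 matches the generating truth exactly."""
        truth = la.default_species_truth("ilex_aquifolium")
        for ant in (8.0, 15.0, 25.0):
            expected = truth.generating_traits(ant)["r25"]
            assert la.acclimated_r25("ilex_aquifolium", ant) == pytest.approx(
                float(expected), abs=1e-12)


def balanced_fits(effects_sp=(0.0, 2.0), effects_site=(0.0, 0.5, 1.0),
                  noise=0.3, n_rep=4, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for i, sp in enumerate(["sp_a", "sp_b"][: len(effects_sp)]):
        for j, st in enumerate(["s1", "s2", "s3"][: len(effects_site)]):
            for _ in range(n_rep):
                rows.append(dict(
                    species=sp, site=st,
                    t_opt=20 + effects_sp[i] + effects_site[j]
                    + rng.normal(0, noise)))
    return pd.DataFrame(rows)


class TestTraitAnova:
    def test_matches_from_scratch_sums_of_squares(self):
        fits = balanced_fits()
        out = la.trait_anova(fits, "t_opt")
        f_by_term = {r["term"]: r["F"] for r in out["anova"]}

        # textbook balanced two-way ANOVA from cell means
        y = fits["t_opt"].to_numpy()
        cells = fits.groupby(["species", "site"])["t_opt"]
        grand = y.mean()
        n_rep = 4
        sp_means = fits.groupby("species")["t_opt"].mean()
        site_means = fits.groupby("site")["t_opt"].mean()
        ss_a = n_rep * 3 * ((sp_means - grand) ** 2).sum()
        ss_b = n_rep * 2 * ((site_means - grand) ** 2).sum()
        cell_means = cells.mean()
        ss_cells = n_rep * ((cell_means - grand) ** 2).sum()
        ss_ab = ss_cells - ss_a - ss_b
        ss_err = ((y - cells.transform("mean").to_numpy()) ** 2).sum()
        df_err = len(y) - 6
        assert f_by_term["C(species)"] == pytest.approx(
            (ss_a / 1) / (ss_err / df_err), rel=1e-9)
        assert f_by_term["C(site)"] == pytest.approx(
            (ss_b / 2) / (ss_err / df_err), rel=1e-9)
        assert f_by_term["C(species):C(site)"] == pytest.approx(
            (ss_ab / 2) / (ss_err / df_err), rel=1e-9)

    def test_separated_species_highly_significant(self):
        fits = balanced_fits(effects_sp=(0.0, 50.0))
        out = la.trait_anova(fits, "t_opt")
        p = {r["term"]: r["p"] for r in out["anova"]}["C(species)"]
        assert p < 1e-3

    def test_identical_observations_reported_degenerate(self):
        fits = balanced_fits(noise=0.0, effects_sp=(0.0, 0.0),
                             effects_site=(0.0, 0.0, 0.0))
        out = la.trait_anova(fits, "t_opt")
        assert all(np.isnan(r["F"]) or r["F"] == 0 for r in out["anova"])

    def test_empty_cell_named(self):
        fits = balanced_fits()
        fits = fits[~((fits.species == "sp_b") & (fits.site == "s3"))]
        with pytest.raises(ValueError, match=r"sp_b.*s3"):
            la.trait_anova(fits, "t_opt")

    def test_tukey_tables_present(self):
        out = la.trait_anova(balanced_fits(), "t_opt")
        assert out["tukey_species"] and out["tukey_site"]


class TestFitAcclimationModels:
    def test_species_models_near_truth(self):
        truth = la.default_species_truth("ilex_aquifolium")
        obs = la.generate_campaign_curves(truth, n_campaigns=30, mode="dark",
                                          n_timepoints=5, seed=2)
        fits = la.fit_curves_table(obs, group_cols=("site", "species",
                                                    "campaign"))
        models = la.fit_acclimation_models(fits, traits=("r25", "q10"))
        r25 = models[models.trait == "r25"].iloc[0]
        assert abs(r25["slope"] - truth.r25_slope) < 2 * r25["stderr_slope"]
        assert r25["n"] == 30
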