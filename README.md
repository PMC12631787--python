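# leafacclim

Thermal acclimation of leaf gas exchange, from raw temperature-response
curves to annual carbon budgets.

Young trees adjust their photosynthetic and respiratory physiology to the
temperature they have recently experienced.  `leafacclim` implements the full
analysis chain used to quantify that adjustment in transplant experiments
along a climate gradient (here modelled after an invasive windmill palm,
*Trachycarpus fortunei*, and two native broadleaves, *Ilex aquifolium* and
*Tilia cordata*, grown at five European sites spanning 8.4–21.8 °C mean
annual air temperature):

1. **Temperature-response fitting** (`response_curves`).  Net assimilation
   measured over the diurnal temperature range is fitted with a parabola

       A_i = A_opt − b (T_i − T_opt)²,

   giving the photosynthetic optimum (T_opt, A_opt) and the thermal breadth
   T_80 = 2√(0.2 A_opt / b) — the width of the interval where A > 0.8 A_opt.
   Dark respiration is fitted with R_i = R_25 · Q_10^((T_i − 25)/10).

2. **Acclimation functions** (`acclimation`).  Fitted traits are regressed
   (OLS) on the mean air temperature of the two weeks preceding each
   campaign; the species-specific linear R_25 and Q_10 functions feed the
   simulator.  A two-way ANOVA + Tukey HSD stage summarises species × site
   differences.

3. **Coupled leaf model** (`spac`).  A soil–plant–atmosphere-continuum leaf
   model: Farquhar-type limiting rate with peaked-Arrhenius temperature
   responses of V_C,max and J_max (entropy terms acclimating to growth
   temperature), a closed-form stomatal optimum down-regulated by a
   sigmoidal hydraulic cost, the CO2 diffusion constraint
   A_net = g_s (C_a − C_i)/1.6, and a full leaf energy balance — solved
   jointly by nested, vectorized bisection at every 30-min met step.

4. **Calibration** (`calibration`).  Unmeasured parameters are calibrated
   against diurnal A_net observations with a DEzs-type differential-
   evolution MCMC sampler (snooker updates from a thinned past-state
   archive), 70/30 calibration/validation split, Gelman–Rubin ≤ 1.1
   convergence rule, and RMSE / percent-bias / Nash–Sutcliffe validation.

5. **Carbon budgets** (`budget`).  Per-step leaf states integrate to annual
   leaf-level uptake C_leaf (gC m⁻²) and whole-plant C_tot; acclimated and
   non-acclimated (traits frozen at the reference site) scenarios run on
   identical drivers and are differenced per site.

A synthetic-data module (`synthetic`) generates met drivers and gas-exchange
observations with known truth, so the whole chain is testable end to end
without any external dataset.

## Worked example

```python
import leafacclim as la

# generate dark-respiration campaigns whose R_25 follows the packaged
# T. fortunei acclimation line, fit each curve, and regress on the
# antecedent temperature
truth = la.default_species_truth("trachycarpus_fortunei")
obs = la.generate_campaign_curves(truth, n_campaigns=30, mode="dark",
                                  n_timepoints=5, tair_range=(15, 35),
                                  noise_sd=0.03, seed=1)
fits = la.fit_curves_table(obs, group_cols=("site", "species", "campaign"))
m = la.regress_trait(fits["r25"], fits["antecedent_tair_C"], "r25")
print(f"R25(T) = {m.intercept:.3f} {m.slope:+.4f} T  (R2={m.r_squared:.2f})")
```

prints

```
R25(T) = 0.493 -0.0038 T  (R2=0.72)
```

i.e. the fitted respiration base rate declines by ≈0.004 µmol m⁻² s⁻¹ per
degree of antecedent warming, recovering the generating line
(0.50 − 0.0037 T) within its OLS uncertainty.  One coupled leaf state:

```python
import pandas as pd
met = pd.DataFrame({"timestamp": [pd.Timestamp("2023-07-01 12:00")],
                    "tair_C": [25.0], "rh_pct": [60.0],
                    "ppfd_umol_m2_s": [1200.0], "wind_m_s": [1.0],
                    "co2_ppm": [400.0], "pressure_kPa": [101.325]})
state = la.solve_leaf_state(met.iloc[0], la.SpeciesParams())
print(f"T_L={state.t_leaf:.1f} C  gs={state.gs:.3f}  Ci={state.ci:.0f} ppm"
      f"  A_net={state.a_net:.1f}")
```

```
T_L=29.8 C  gs=0.115  Ci=273 ppm  A_net=9.1
```

— a sunlit leaf ~5 °C above air temperature, stomata partly open, drawing
C_i down to ~0.7 C_a.

## Command line

```bash
leafacclim generate --site semi_arid --n-days 365 --out met.csv
leafacclim fit-curves --observations obs.csv --out fits.csv
leafacclim regress --fits fits.csv --out models.csv
leafacclim run-all --outdir demo_run --seed 1   # full pipeline
```

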