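# Methods

## Scope and model chain

`leafacclim` reconstructs a complete thermal-acclimation analysis for leaf
gas exchange: temperature-response curve fitting, trait-acclimation
regression against antecedent air temperature, a coupled leaf
gas-exchange/energy-balance simulator with acclimating physiology, Bayesian
calibration of unmeasured simulator parameters, and growing-season carbon
budgets under acclimated versus non-acclimated physiology.  All stages run
end to end on synthetic data whose generating truth is known, so every
statistical claim the package makes is testable by construction.

## Temperature-response curves

Net assimilation across the diurnal air-temperature range is modelled as a
parabola `A(T) = A_opt − b (T − T_opt)²`.  Because the parabola is linear in
its monomial coefficients, the least-squares problem is solved exactly by
the normal equations (no iteration, no starting values); the apex
parameters and their standard errors follow by the delta method.  The
thermal breadth `T_80 = 2 √(0.2 A_opt / b)` is the closed-form distance
between the two roots of `A(T) = 0.8 A_opt`.  Dark respiration follows the
Q10 form `R(T) = R_25 Q_10^{(T−25)/10}`, fitted by nonlinear least squares
on the original scale, initialized from the log-linear regression.  Fits
with fewer than 4 points (3 for respiration), degenerate temperature
spread, non-positive curvature, or `Q_10 ≤ 1` are returned as flagged
records, never silently dropped; downstream regressions exclude flagged
rows and report the exclusion count.

## Acclimation functions

The exposure metric is the arithmetic mean air temperature over the
closed-open interval `[t − 14 d, t)` before a measurement — closed at the
start and open at the measurement instant so no step is double-counted.
Traits are regressed on this antecedent temperature by ordinary least
squares (statsmodels), campaign-averaged per species, pooling sites.  The
fitted species R_25 lines (defaults: 0.50 − 0.0037 T for the palm,
1.42 − 0.0293 T for holly, 1.36 − 0.0317 T for linden, µmol m⁻² s⁻¹) are
clamped at 0.01 µmol m⁻² s⁻¹ because the native species' lines extrapolate
negative above ~43–48 °C.  Q_10 acclimation is enabled only for the palm;
its slope (−0.02 per °C) is a placeholder for a relationship whose
existence is established but whose coefficients are not published, and it
is configurable.  The species × climate ANOVA with Tukey HSD uses
statsmodels; zero-residual-variance designs are reported as degenerate
rather than producing spurious F statistics.

## Coupled leaf model

At each meteorological step the model couples four pieces, all evaluated at
leaf temperature T_L:

* **Biochemistry.**  The limiting carboxylation rate is
  `B = min(W_c, W_j)` with `W_c = V_cmax (C_i − Γ*)/(C_i + K_m)` and
  `W_j = J (C_i − Γ*)/(4 C_i + 8 Γ*)`; J comes from a non-rectangular
  hyperbola of incident PPFD (θ = 0.9, α = 0.3).  Γ*, K_c, K_o follow
  Arrhenius responses with Bernacchi et al. (2001) constants.  V_cmax and
  J_max follow the peaked Arrhenius function normalized to 1 at 25 °C, with
  entropy terms acclimating linearly to growth temperature using the
  Kattge & Knorr (2007) general coefficients (ΔS_v = 668.39 − 1.07 T_g,
  ΔS_j = 659.70 − 0.75 T_g J mol⁻¹ K⁻¹; Ha_v = 71.513, Ha_j = 49.884,
  Hd = 200 kJ mol⁻¹), so the thermal optimum of photosynthesis shifts
  upward roughly 0.4 °C per °C of growth temperature.

* **Stomatal optimum.**  The closed form
  `g_s,max = [B(C_i − Γ) − R_d(D C_i + E)] / [(E + F)(C_i − C_a)]`
  is used with D = 0, E = 50, F = −200.  D, E, F are *effective* constants:
  their source definitions are not publicly documented, so they were chosen
  once to place the optimum in the observed 0.05–0.3 mol m⁻² s⁻¹ range
  (E + F < 0 makes the expression positive for C_i < C_a) and they are the
  first candidates for DE-MC calibration.  g_s,max is defined as the
  self-consistent point `g_s = g_s,max(C_i(g_s))` where C_i(g_s) solves the
  diffusion/biochemistry balance; the lowest crossing above the cuticular
  minimum is taken.  The closed form diverges as C_i → C_a, which creates a
  spurious near-zero-drawdown root; roots with C_i within 20 ppm of C_a are
  rejected, closing stomata to g_min instead (this regime occurs only for
  strongly overheated leaves where the physical optimum has vanished).

* **Hydraulics.**  Transpirational demand `E = 1.6 g_s VPD_leaf / P`
  draws leaf water potential down from soil water potential through a
  constant soil-to-leaf conductance (k_max = 0.012 mol m⁻² s⁻¹ MPa⁻¹,
  well-watered pots), and a two-parameter sigmoidal vulnerability cost
  `[1 + (ψ/ψ50)^s]⁻¹` (ψ50 = −2.5 MPa, s = 4) multiplies g_s,max.  The
  fixed point over (E, ψ, g_s) is solved by damped iteration; g_s never
  falls below g_min.

* **Energy balance.**  Absorbed shortwave (PAR → W m⁻² at 0.2175 W per
  µmol, doubled for the non-PAR fraction, × absorptance) plus incoming
  longwave (surroundings at air temperature) balance emitted longwave
  (two-sided, ε = 0.97), sensible heat (forced-convection boundary-layer
  conductance from leaf width and wind) and latent heat.  The root in T_L
  is found by bisection on [T_air − 20, T_air + 25] to a residual far below
  0.01 W m⁻².

**Solution scheme.**  An outer loop on T_L wraps the inner (C_i, g_s)
solution: an Aitken-accelerated fixed point (the plain damped map stalls
when the hydraulic feedback slope approaches 1) declared converged when
successive T_L differ by < 0.01 °C, with a bracketed-bisection fallback on
`G(T_L) = EB(g_s(T_L)) − T_L` for any steps the fixed point cannot settle —
bisection cannot limit-cycle, so every step terminates deterministically.
All root-finding is fixed-iteration bracketed bisection, vectorized across
meteorological steps: a full year at 30-min resolution solves in roughly
10–15 s on one core, and the calibration path batches the proposals of all
MCMC chains into one vectorized forward call.  At convergence the model
guarantees: carbon closure `A_gross − R_d − A_net = 0` to 1e-9; diffusion/
biochemistry agreement below 1e-6 µmol m⁻² s⁻¹; energy residual below
0.01 W m⁻².

**Sign convention.**  The diffusion constraint is
`A_net = g_s (C_a − C_i)/1.6` with R_d subtracted inside the biochemical
rate.  An alternative reading that adds R_d on the diffusion side is
implemented behind `eq3_printed_sign=True` for auditing but is off by
default because it is not mass-consistent.

**A note on monotonicity.**  At fixed leaf temperature, raising VPD never
raises g_s and raising PPFD never lowers the limiting rate, and the tests
assert exactly that.  In the fully coupled solution both can reverse
through the energy balance: drier air cools the leaf, and a leaf above its
thermal optimum then assimilates more and opens further.  This is model
behavior, not a defect.

## Synthetic data

The generator emulates the structure of a five-site transplant experiment
(site means 8.4–21.8 °C, coldest to warmest, 70 % shading), three species
with distinct trait means, six campaigns of up to 10 individuals, and 5–6
point diurnal curves spanning ~12–35 °C.  Air temperature is a seasonal
plus diurnal sinusoid (peaks mid-July and 14:00) with additive Gaussian
noise (sd 1.5 °C); PPFD is a clear-sky half-sine scaled by one minus the
shading fraction; RH derives from a fixed site dew point (vapor pressure
pinned at the site-mean RH of saturation at the site-mean temperature), so
it is anti-correlated with temperature without extra configuration.  All
per-campaign generating traits are linear in the 2-week antecedent mean,
and the parabola curvature is derived per campaign as
`b = 0.8 A_opt / T_80²`, so the generated curves carry *exactly* the
configured linear T_opt, A_opt and T_80 acclimation.  Observation noise
defaults (sd 0.2 µmol m⁻² s⁻¹ light, 0.03 dark) are assumptions — the
magnitudes are not documented for the instrument protocols emulated here —
and are configurable.  All randomness flows from a single seed through
numpy Generator spawning.

What the generator does **not** emulate: frost damage and mortality, leaf
phenology detection (flush/senescence are configuration dates), radiation
geometry, weather autocorrelation beyond the sinusoids, instrument drift,
or within-canopy gradients.  Passing recovery tests therefore demonstrate
that the estimators are unbiased and correctly propagate uncertainty under
the assumed noise model — not that field data of this shape would yield
equally clean recoveries.

## Calibration

70 % of diurnal A_net observations (seeded random split, exhaustive and
disjoint) calibrate the free parameters; 30 % are held out for RMSE,
percent bias and Nash–Sutcliffe efficiency.  The sampler is a
differential-evolution MCMC of the DEzs family: parallel-direction
proposals `x* = x + γ(z1 − z2)(1 + e) + ε` with γ = 2.38/√(2d) (10 % of
proposals use γ = 1 for mode jumps) and 10 % snooker updates along the
direction to a random archive state with the (d−1)/2-power Jacobian
correction; z1, z2 are drawn from an archive seeded with prior draws and
appended with the population every 5 iterations.  Priors are bounded
uniform; the Gaussian residual sd is a free nuisance parameter; burn-in is
the first half.  Convergence is judged by the per-parameter potential scale
reduction factor against 1.1.  On the packaged fixture (~200 observations,
noise sd 0.5 µmol m⁻² s⁻¹), 3 chains × 2000 iterations converge with all
PSRF ≤ 1.02 and recover V_C,max,25 within a few percent.  The calibration
fixture is generated unshaded: under deep shade nearly all observations are
electron-transport-limited and V_C,max is weakly identified, a property of
the design rather than the sampler.  Forward runs inside the likelihood use
coarser bisection settings (documented in `FAST_SOLVER_KWARGS`) whose
effect on A_net is far below observation noise.

## Carbon budgets and scenarios

`C_leaf = Σ A_net Δt · 10⁻⁶ · 12.011` gC m⁻² over the phenology window
(default the full generated year; deciduous species integrate only
[flush, senescence]); negative night/heat contributions are retained since
C_leaf is a net quantity.  `C_tot = C_leaf ×` total leaf area.  The
non-acclimated scenario freezes exactly {V_C,max, J_max, R_25, Q_10} — via
the growth temperature pinned to the reference site's mean — while the
energy balance and g_s still respond to weather.  The acclimated scenario
uses each site's growth temperature; by default this is the site's
season-mean of the rolling 2-week antecedent mean (one value per site),
which makes the two scenarios *exactly* identical at the reference site; a
per-step rolling mode is available for seasonal acclimation dynamics.

## Problem sizes

Default test and acceptance problem sizes were chosen as the smallest
designs at which the statistical checks are well powered: 30 campaigns for
slope recovery (the pooled two-year, five-site campaign count), ~200
observations and 3 × 2000 DE-MC iterations for calibration, one synthetic
year at 30-min steps for budget closure.  Larger runs change none of the
qualitative results.

## Known limitations

* D, E, F of the stomatal closed form are effective constants; absolute
  conductances and budgets inherit their scale.  Calibrate them against
  observed diurnal A_net before quantitative use.
* The hydraulic submodel has no soil water dynamics (ψ_soil is an input),
  matching well-watered pot experiments only.
* Boundary-layer and radiation treatments are single-leaf, forced-
  convection approximations; no canopy radiative transfer.
* The DEzs archive is unthinned within the returned chains; effective
  sample sizes are modest at 2000 iterations and quantile summaries beyond
  the median should use longer runs.
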