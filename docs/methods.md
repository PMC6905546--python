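# Methods

## Scope and model structure

The package treats hydrogenotrophic methanogenesis at three levels:

1. **Stoichiometry and thermodynamics** (`methanergy.thermo`).  Growth is
   a linear combination of one catabolic reaction (R1, 4 H₂ + CO₂ → CH₄ +
   2 H₂O) and one anabolic reaction (R2, 10 H₂ + 5 CO₂ + NH₃ → C₅H₇O₂N +
   8 H₂O), with ammonia as sole nitrogen source and biomass idealised as
   C₅H₇O₂N (113 g/mol).  The biomass yield factor Y (mol biomass/mol H₂)
   fixes the catabolic H₂ fraction f = 1 − 10Y and thereby the gas yields
   Y_CH₄ = f/4 and Y_CO₂ = f/4 + (1 − f)/2.  Per mol of biomass formed,
   ν_cat = (1 − 10Y)/(4Y) catabolic turns accompany one anabolic turn;
   dividing by 5 gives all quantities per C-mol.
2. **Batch kinetics** (`methanergy.kinetics`).  Five ODEs — biomass,
   dissolved CO₂, and headspace H₂/CO₂/CH₄ — with the exergy-based growth
   law μ = μ_max·exp(−K_s·V_g/n_H₂) on headspace hydrogen, first-order
   decay k_d, and non-equilibrium liquid–gas CO₂ transfer
   k_La·(s_CO₂ − K_H·R·T·n_CO₂/V_g).  H₂ and CH₄ are treated as insoluble
   (their liquid pools are not modelled), and the gas phase is ideal.
3. **Chemostat competition** (`methanergy.competition`).  Per species,
   dx_i/dt = (μ_i − D_i)x_i; the shared hydrogen pool receives a constant
   supply q_H₂ and loses hydrogen to consumption and a first-order outflow
   b·n.  The closed-form steady state n*_i = K_{s,i}V_g/ln(μ_max,i/D_i)
   (natural logarithm) ranks competitors: the lowest n* wins.

## Parameters

| symbol | meaning | unit | default | origin |
|---|---|---|---|---|
| μ_max | maximum growth rate constant | 1/h | 0.12 / 0.07 / 0.046 | calorimetric exponential-phase fits (Ms/Mr/Mf) |
| K_s | affinity constant | mol/L | 0.028 / 0.042 / 0.011 | gas time-series calibration |
| Y | biomass yield | mol/mol H₂ | 0.006 / 0.006 / 0.007 | methane-based growth yields 2.8 and 3.5 g/mol CH₄ |
| k_d | decay constant | 1/h | 8.33e-4 | anaerobic-digestion practice |
| k_La | CO₂ transfer constant | 1/h | 8.33 | idem |
| K_H,CO₂ | Henry coefficient | M/bar | 0.0246 | value at 39 °C |
| V_g, V_L | gas/liquid volumes | L | 0.020 / 0.006 | Balch tube |
| T | temperature | K | 312.15 | incubation at 39 °C |
| D | dilution rate | 1/h | 0.021 or 0.04 | retention times of 48 h / 25 h |
| b | substrate outflow constant | 1/h | 0.5 | chemostat scenario |
| q_H₂ | hydrogen supply | mol/h | 0.02 | chemostat scenario (see below) |

The chemostat volumes default to the in vitro values because the toy
model does not define its own, and q_H₂ is interpreted as mol **per
hour**: all other rate constants of the model are per hour, and a supply
of 0.02 mol/min would demand a steady biomass near 57 mol/L (6.4 kg dry
weight per litre), which is physically absurd.  Both choices are plain
configuration fields.

## Thermodynamic data

The default formation table holds standard-state values at 298.15 K
(kJ/mol): H₂ 0/0, CO₂(g) −394.36/−393.51, CH₄(g) −50.72/−74.81,
H₂O(l) −237.13/−285.83, NH₃(aq) −26.50/−80.29, and generic biomass at
−67/−91 per C-mol (×5 for C₅H₇O₂N).  With Y = 0.006 this gives
ΔG_m = −1069.9, ΔH_m = −2120.3 and TΔS_m = −1050.3 kJ/C-mol, an
enthalpy-driven but entropy-retarded process in which the anabolic
reaction carries ~7% of the metabolic heat and ~50% of the heat merely
compensates the entropy lost when five moles of gas condense into one.
No temperature correction is applied by default — the 298 K values
describe the 39 °C cultures well within the uncertainty of the biomass
formation properties — and the table is user-replaceable (YAML).  Ionic
strength/activity corrections and temperature-dependent heat capacities
are out of scope.

The destock reaction behind the stored exergy E_M defaults to the reverse
of R2 per C-mol biomass; with the default table it is endergonic, so
E_M = 0 and K_s is carried entirely by the dissipated exergy.

## Driving-force classification

For a spontaneous process (ΔG < 0), ΔH < 0 and TΔS > 0 each count as
"driving" (they lower ΔG).  When both drive, the larger |contribution|
names the label (enthalpy- vs entropy-driven); when one term opposes, the
label gains a "retarded" suffix.  This rule yields a total order and
reproduces the classification of hydrogenotrophic (enthalpy-driven but
entropy-retarded), formatotrophic and methylotrophic (enthalpy-driven)
and aceticlastic (entropy-driven but enthalpy-retarded) growth.

## Calorimetry

Instrument power is positive for exothermic cultures; integrated process
heat Q is reported negative for exothermic processes (trapezoidal rule,
1 μW·h = 3.6 mJ).  The exponential-phase rate μ_c is the slope of
ln(power) vs time; the automatic window search scans contiguous windows
ending at or before the main peak, at least 20% of the time-to-peak long,
and keeps the longest with log-linear r² ≥ 0.99 (earliest start on ties).
Both thresholds are arguments.  An optional constant baseline is
estimated from the first/last 5% of samples.

**Caveat — μ_c vs μ_max.**  The identification strategy sets
μ_max = μ_c.  Inside the model this is exact only when the culture starts
substrate-replete: the early-time growth rate is
μ_max·exp(−K_s·V_g/n_H₂(0)), which for a 1.7 bar 80/20 headspace and
K_s = 0.028 mol/L is only ~60% of μ_max.  The calorimetric recovery tests
therefore use a regime with K_s·V_g/n_H₂(0) ≈ 0.06, where the exponential
approximation actually holds; for strongly substrate-limited starts μ_c
should be read as an effective early-phase rate, not μ_max.

## Calibration

μ_max, Y, k_d, k_La, K_H and the initial biomass are fixed; K_s
(bounds 1e-4–1 mol/L) and the initial dissolved CO₂ (0–0.2 mol/L) are
estimated by bounded trust-region least squares on the concatenated
residuals of the three gas series, each scaled by its observed maximum so
that gases on different mole scales weigh equally (no weighting scheme is
canonical here; max-normalisation is the package's choice).  A seeded
Latin-hypercube multistart (default 8) guards against local optima of the
exp(−K_s·V_g/n) rate; integrator failures at trial points (e.g. dissolved
CO₂ driven negative at extreme parameter guesses, a structural artifact
of a model with no CO₂ limitation term) discard that start with a log
entry.  Parameter uncertainty is the Gauss–Newton covariance
σ²(JᵀJ)⁻¹ at the optimum — a practical-identifiability report, not a
posterior.  Structural identifiability of (μ_max, K_s, s_CO₂(0)) given
the three gas observables is known from symbolic analysis and is not
re-derived here.  Goodness of fit is reported per gas as Lin's
concordance correlation coefficient (population moments), squared Pearson
correlation, and CV(RMSE) in percent of the observed mean.

## Batch integration

Units are fixed globally (mol, L, h, bar, K).  LSODA with rtol 1e-8 /
atol 1e-12 integrates the stiff late phase of hydrogen depletion; μ(0) is
defined as 0 by continuity and the exponent is guarded against underflow.
Negative excursions are clipped at zero within 1e-9 (mol or mol/L);
larger excursions raise instead of being silently repaired.  Halving the
tolerances changes the final CH₄ by < 1e-6 relative.

A structural consequence of the exponential growth law worth knowing:
batch hydrogen depletion stalls.  As n_H₂ falls, μ collapses like
exp(−K_s·V_g/n_H₂), so with the M. smithii parameters and a 1.7 bar
80/20 headspace roughly a fifth of the initial hydrogen is still present
after 72 h regardless of inoculum size — complete (>99%) depletion is
unreachable on that horizon.

## Competition and the meaning of "survivor"

Exclusion in the chemostat is asymptotic.  A losing species declines at
most at D − μ_i(n*), which for M. smithii at D = 0.021 1/h against
M. formicium is ≈ 0.0047 1/h: from any appreciable inoculum it remains
*detectable* for hundreds of days while being deterministically doomed.
`simulate_competition` therefore reports two things separately: the time
at which each biomass first crosses the extinction threshold (default
1e-9 mol/L, ~4×10⁵ cells/L), and a survivor set defined by the classical
persistence criterion — a species survives if it is above the threshold
*and* can at least replace itself at the final hydrogen level
(μ_i(n_end) ≥ D_i).  Under that definition the 50-day outcome of the
reference scenario (equal 0.1 mol/L inocula, D = 0.021 1/h, b = 0.5 1/h)
is exactly one survivor, M. formicium, independently of inoculum sizes
over several orders of magnitude; a threshold-only definition would make
the day-50 outcome an artifact of the chosen threshold and inoculum.

## Synthetic data

The generators emulate the Balch-tube design: 20 mL headspace over 6 mL
medium at 39 °C, 1.7 bar H₂/CO₂ 80/20 fill (≈1.05 mmol H₂), an inoculum
of 2×10⁻⁵ mol/L (≈2.3 mg dw/L, a ~10% v/v transfer of a late-exponential
culture), initial dissolved CO₂ 0.01 mol/L, and 13 sampling times over
0–72 h, denser early.  Observation noise is multiplicative lognormal
(default σ = 0.05) applied independently per observation, with an
optional additive floor; calorimetric curves add a lag phase and an
instrument baseline.  What the generators do **not** emulate: correlated
errors between gases measured on the same injection, drift, the small
secondary heat-flux peaks seen in real thermograms, or qPCR biomass
observables.  Passing recovery tests therefore demonstrate correctness
of the estimation machinery under the stated error model, not robustness
to every artifact of real chromatography or calorimetry.

## Problem sizes used in the tests

Recovery studies use 13-point datasets with 3–4 multistarts and 20 noise
replicates; batch conservation checks run on 400–2001-point grids;
chemostat runs span 50 days (scenario checks) to 250 days (steady-state
convergence, which is slow near equilibrium).  These sizes make the whole
suite comfortably reproducible on a laptop while leaving every tolerance
meaningfully tight.

## Known limitations

* No pH, carbonate speciation, or CO₂/ammonia limitation of growth; the
  batch model can drive dissolved CO₂ negative at extreme parameter
  values (handled by rejection, not by a limitation term).
* Liquid-phase H₂/CH₄ dynamics are absent by construction; at high cell
  densities gas-transfer limitation of H₂ could matter.
* The chemostat toy model is spatially homogeneous and cannot, by
  design, reproduce coexistence of methanogens; it quantifies exactly
  which coexistence-promoting mechanisms (adhesion, spatial structure,
  pH differentiation) must be added to overturn exclusion.
* Literature thermodynamic rows used for classification fixtures are
  inputs, not outputs; the M. formicium metabolic row reported elsewhere
  is not reproduced by the default table at Y = 0.007 and is deliberately
  not asserted.
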