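# methanergy

Energetics and growth kinetics of gut hydrogenotrophic methanogens.

Methanogenic archaea such as *Methanobrevibacter smithii* (human gut),
*Methanobrevibacter ruminantium* and *Methanobacterium formicium* (rumen)
grow by reducing CO₂ with H₂.  This package is for microbial ecologists and
modellers who want to treat that process quantitatively: it couples a
thermodynamic account of methanogenesis with an exergy-based growth model,
fits the model to headspace gas measurements and isothermal
microcalorimetry, and explores competition between species in a
continuous-flow (gut-like) environment.

## The model

Metabolism is split into a catabolic and an anabolic macro-reaction,

* R1: 4 H₂ + CO₂ → CH₄ + 2 H₂O
* R2: 10 H₂ + 5 CO₂ + NH₃ → C₅H₇O₂N + 8 H₂O

tied together by the biomass yield factor *Y* (mol biomass/mol H₂): a
fraction *f* = 1 − 10 *Y* of the hydrogen is catabolised, giving the gas
yields Y_CH₄ = *f*/4 and Y_CO₂ = *f*/4 + (1 − *f*)/2.  Gibbs energies,
enthalpies and the entropic term TΔS of every process follow from standard
formation properties; the exergy decomposition (E_cat, E_M, E_dis) gives
the substrate-affinity constant of the energetic growth law an explicit
physical meaning, K_s = (E_M + E_dis)/(v_harv · E_cat).

A sealed-tube batch culture is described by five ODEs (biomass, dissolved
CO₂, headspace H₂/CO₂/CH₄) with the growth law

    μ = μ_max · exp(−K_s·V_g / n_H₂)

and first-order liquid–gas CO₂ transfer.  Calorimetric heat-flux curves
give μ_max through the exponential-phase relation dQ/dt = μ_c·Q; the gas
time series then constrain K_s and the initial dissolved CO₂ by bounded
nonlinear least squares.  A chemostat extension for *n* species has the
closed-form steady state n*_i = K_{s,i}·V_g / ln(μ_max,i / D_i) and
predicts competitive exclusion of every species except the one with the
lowest n*.

## Worked example

```python
import numpy as np
from methanergy import (M_SMITHII, VesselConfig, NoiseModel, FitSpec,
                        fit_batch, metabolic_state, steady_state_substrate)
from methanergy.synthetic import default_initial_state, generate_batch_dataset

vessel = VesselConfig()                      # 20 mL headspace, 6 mL medium, 39 C
init = default_initial_state(vessel)         # 1.7 bar H2/CO2 80/20, small inoculum
data = generate_batch_dataset(M_SMITHII, vessel, init,
                              noise=NoiseModel(sigma=0.05, seed=1))
res = fit_batch(data.observations, FitSpec(multistart=4, seed=1),
                M_SMITHII, vessel, x0=init.x)
print(res.summary())
```

```
Batch methanogenesis calibration
================================================
species:          M. smithii
observed series:  ngH2_mol, ngCO2_mol, ngCH4_mol
n observations:   39
fixed mu_max:     0.12 1/h
fixed Y:          0.006 mol/mol
fixed kd:         0.000833 1/h
multistart:       4 (seed 1, 1 failed)
converged:        True
final objective:  0.0121469
------------------------------------------------
parameter         estimate     std err
Ks_molL           0.028896    0.000363
sCO2_0_molL       0.010011    0.000425
------------------------------------------------
series           CCC      r2  CV_RMSE%
ngH2_mol       0.994   0.989       3.5
ngCO2_mol      0.991   0.985       3.5
ngCH4_mol      0.999   0.998       7.7
```

The fit recovers the generating affinity constant (true K_s = 0.028 mol/L)
to about 3% from data carrying 5% multiplicative observation noise, with
concordance correlation coefficients above 0.99 for all three gases; the
standard errors come from the Gauss–Newton covariance at the optimum.

The energetics of the same organism:

```python
state = metabolic_state(0.006)     # Y = 0.006 mol biomass / mol H2
print(state.dg, state.dh, state.tds)
# -1069.9 -2120.3 -1050.3   (kJ per C-mol biomass)
```

Growth on H₂/CO₂ is strongly exothermic and *entropy-retarded*: the gas
phase loses entropy as 5 moles of gas collapse into one, so roughly half
of the released heat only compensates that entropy loss.

Steady-state hydrogen requirements in a chemostat at a 48 h retention
time (`D = 0.021 1/h`):

```python
for sp in (M_SMITHII,):
    print(sp.name, 1e3 * steady_state_substrate(sp, vessel.vg, 0.021), "mmol")
# M. smithii 0.321 mmol
```

A command-line interface mirrors the library:
`methanergy thermo --yield 0.006`, `methanergy simulate`, `methanergy fit`,
`methanergy calorimetry`, `methanergy compete`, `methanergy synth`,
`methanergy run --config analysis.yaml`.

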