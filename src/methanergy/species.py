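"""Default parameter sets for the three reference gut methanogens.

Kinetic constants correspond to pure-culture Balch-tube experiments at
39 C: maximum growth rate constants from calorimetric exponential-phase
fits, affinity constants from gas time-series calibration, yields from
literature methane-based molar growth yields (2.8 g/mol CH4 for the
Methanobrevibacter pair, 3.5 g/mol CH4 for M. formicium).
"""

from .kinetics import MethanogenParams

__all__ = ["M_SMITHII", "M_RUMINANTIUM", "M_FORMICIUM", "REFERENCE_SPECIES"]

DEFAULT_KD = 8.33e-4  # 1/h

M_SMITHII = MethanogenParams(
    name="M. smithii", mu_max=0.12, ks=0.028, y=0.006, kd=DEFAULT_KD
)
M_RUMINANTIUM = MethanogenParams(
    name="M. ruminantium", mu_max=0.07, ks=0.042, y=0.006, kd=DEFAULT_KD
)
M_FORMICIUM = MethanogenParams(
    name="M. formicium", mu_max=0.046, ks=0.011, y=0.007, kd=DEFAULT_KD
)

REFERENCE_SPECIES = (M_SMITHII, M_RUMINANTIUM, M_FORMICIUM)
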