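"""Stoichiometry and thermodynamics of hydrogenotrophic methanogenesis.

Growth of a hydrogenotrophic methanogen is represented macroscopically by
two reactions sharing H2 as electron donor:

* catabolism  (R1):  4 H2 + CO2        -> CH4 + 2 H2O
* anabolism   (R2): 10 H2 + 5 CO2 + NH3 -> C5H7O2N + 8 H2O

The split between them is controlled by the biomass yield factor
``Y`` (mol biomass / mol H2): a fraction ``f = 1 - 10 Y`` of the hydrogen
flows through R1 and the remainder through R2.  From ``f`` follow the gas
yield factors ``YCH4 = f/4`` and ``YCO2 = f/4 + (1-f)/2``.

All Gibbs energies, enthalpies and entropic terms are obtained as
coefficient-weighted sums of standard formation properties, carried on a
:class:`ThermoState` together with an explicit basis label (per mol
reaction, per mol H2, or per C-mol biomass) so that unit drift is loud
rather than silent.  The exergy quantities (``E_cat``, ``E_M``, ``E_dis``)
parameterise the substrate-affinity constant of the energetic growth law,
``Ks = (E_M + E_dis) / (v_harv * E_cat)``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Mapping

import yaml

__all__ = [
    "SpeciesThermo",
    "FormationTable",
    "ReactionSpec",
    "MetabolicStoichiometry",
    "ThermoState",
    "ExergyTerms",
    "DEFAULT_FORMATION_TABLE",
    "R1_CATABOLISM",
    "R2_ANABOLISM",
    "BIOMASS_MOLAR_MASS",
    "fraction_from_yield",
    "yield_factors",
    "yield_from_methane_growth_yield",
    "reaction_delta",
    "metabolic_state",
    "process_heat",
    "exergy_terms",
    "ks_from_exergy",
    "harvest_volume_from_ks",
    "classify_driving_force",
    "thermo_report",
]

BIOMASS_MOLAR_MASS = 113.0  # g/mol for C5H7O2N
_ELEMENTS = ("C", "H", "O", "N")
_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


class ThermoError(ValueError):
    """Raised for invalid stoichiometric or thermodynamic input."""


def parse_formula(formula: str) -> dict[str, int]:
    """Parse a molecular formula such as ``C5H7O2N`` into element counts."""
    counts: dict[str, int] = {}
    pos = 0
    for m in _FORMULA_RE.finditer(formula):
        if not m.group(0):
            continue
        if m.start() != pos:
            raise ThermoError(f"cannot parse formula {formula!r}")
        pos = m.end()
        counts[m.group(1)] = counts.get(m.group(1), 0) + int(m.group(2) or 1)
    if pos != len(formula):
        raise ThermoError(f"cannot parse formula {formula!r}")
    return counts


@dataclass(frozen=True)
class SpeciesThermo:
    """Standard formation properties of one chemical species.

    ``dgf``/``dhf`` are the standard Gibbs energy and enthalpy of formation
    in kJ/mol at the table's reference temperature.
    """

    dgf: float
    dhf: float
    phase: str
    formula: str
    molar_mass: float

    @property
    def elements(self) -> dict[str, int]:
        return parse_formula(self.formula)


@dataclass(frozen=True)
class FormationTable:
    """Formation-property lookup for the species of the metabolic network."""

    species: Mapping[str, SpeciesThermo]
    temperature: float = 298.15  # K, reference for the tabulated values

    def __getitem__(self, name: str) -> SpeciesThermo:
        try:
            return self.species[name]
        except KeyError:
            raise ThermoError(
                f"species {name!r} missing from formation table "
                f"(have: {sorted(self.species)})"
            ) from None

    def __contains__(self, name: str) -> bool:
        return name in self.species

    def with_species(self, name: str, entry: SpeciesThermo) -> "FormationTable":
        merged = dict(self.species)
        merged[name] = entry
        return replace(self, species=merged)

    # -- plain-text serialisation ------------------------------------------
    def to_yaml(self, path) -> None:
        payload = {
            "temperature_K": self.temperature,
            "species": {
                name: {
                    "dgf_kJ_mol": sp.dgf,
                    "dhf_kJ_mol": sp.dhf,
                    "phase": sp.phase,
                    "formula": sp.formula,
                    "molar_mass_g_mol": sp.molar_mass,
                }
                for name, sp in self.species.items()
            },
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "FormationTable":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        species = {
            name: SpeciesThermo(
                dgf=float(d["dgf_kJ_mol"]),
                dhf=float(d["dhf_kJ_mol"]),
                phase=str(d["phase"]),
                formula=str(d["formula"]),
                molar_mass=float(d["molar_mass_g_mol"]),
            )
            for name, d in payload["species"].items()
        }
        return cls(species=species, temperature=float(payload.get("temperature_K", 298.15)))


#: Standard-state formation properties at 298.15 K.  Biomass (C5H7O2N) uses
#: generic per-C-mol values of -67 kJ (Gibbs) and -91 kJ (enthalpy) per
#: C-mol, times 5 C per formula unit.  The table is user-replaceable.
DEFAULT_FORMATION_TABLE = FormationTable(
    species={
        "H2": SpeciesThermo(0.0, 0.0, "g", "H2", 2.016),
        "CO2": SpeciesThermo(-394.36, -393.51, "g", "CO2", 44.01),
        "CH4": SpeciesThermo(-50.72, -74.81, "g", "CH4", 16.04),
        "H2O": SpeciesThermo(-237.13, -285.83, "l", "H2O", 18.015),
        "NH3": SpeciesThermo(-26.50, -80.29, "aq", "NH3", 17.031),
        "biomass": SpeciesThermo(-335.0, -455.0, "s", "C5H7O2N", BIOMASS_MOLAR_MASS),
    }
)


@dataclass(frozen=True)
class ReactionSpec:
    """A reaction as a map species -> signed stoichiometric coefficient.

    Products carry positive coefficients, substrates negative ones.
    """

    name: str
    coefficients: Mapping[str, float]

    def element_imbalance(self, table: FormationTable) -> dict[str, float]:
        """Net atoms of C, H, O, N created by the reaction (all 0 if balanced)."""
        totals = dict.fromkeys(_ELEMENTS, 0.0)
        for species, coef in self.coefficients.items():
            for el, count in table[species].elements.items():
                if el in totals:
                    totals[el] += coef * count
        return totals

    def assert_balanced(self, table: FormationTable, tol: float = 1e-9) -> None:
        imbalance = self.element_imbalance(table)
        bad = {el: v for el, v in imbalance.items() if abs(v) > tol}
        if bad:
            raise ThermoError(f"reaction {self.name!r} is not element-balanced: {bad}")

    def reversed(self) -> "ReactionSpec":
        return ReactionSpec(
            name=f"{self.name} (reversed)",
            coefficients={sp: -c for sp, c in self.coefficients.items()},
        )

    def scaled(self, factor: float, name: str | None = None) -> "ReactionSpec":
        return ReactionSpec(
            name=name or f"{self.name} (x{factor:g})",
            coefficients={sp: factor * c for sp, c in self.coefficients.items()},
        )


R1_CATABOLISM = ReactionSpec(
    "R1 catabolism (4 H2 + CO2 -> CH4 + 2 H2O)",
    {"H2": -4.0, "CO2": -1.0, "CH4": 1.0, "H2O": 2.0},
)
R2_ANABOLISM = ReactionSpec(
    "R2 anabolism (10 H2 + 5 CO2 + NH3 -> C5H7O2N + 8 H2O)",
    {"H2": -10.0, "CO2": -5.0, "NH3": -1.0, "biomass": 1.0, "H2O": 8.0},
)


@dataclass(frozen=True)
class ThermoState:
    """Gibbs energy / enthalpy / entropic term of a process on a stated basis.

    Invariant ``dg = dh - tds`` is enforced at construction.
    """

    dg: float  # kJ per basis unit
    dh: float  # kJ per basis unit
    tds: float  # kJ per basis unit (T * delta S)
    temperature: float  # K
    basis: str

    def __post_init__(self) -> None:
        scale = max(abs(self.dg), abs(self.dh), abs(self.tds), 1.0)
        if abs(self.dg - (self.dh - self.tds)) > 1e-9 * scale:
            raise ThermoError(
                f"inconsistent state: dG={self.dg} != dH-TdS={self.dh - self.tds}"
            )

    def scaled(self, factor: float, basis: str) -> "ThermoState":
        return ThermoState(
            dg=self.dg * factor,
            dh=self.dh * factor,
            tds=self.tds * factor,
            temperature=self.temperature,
            basis=basis,
        )


@dataclass(frozen=True)
class MetabolicStoichiometry:
    """Yield bookkeeping derived from the biomass yield factor Y."""

    y: float  # mol biomass / mol H2
    f: float  # catabolic H2 fraction
    y_co2: float  # mol CO2 consumed / mol H2
    y_ch4: float  # mol CH4 produced / mol H2
    nu_cat: float  # mol CH4 (catabolic turns) per mol biomass

    @classmethod
    def from_yield(cls, y: float) -> "MetabolicStoichiometry":
        f = fraction_from_yield(y)
        y_co2, y_ch4 = yield_factors(f)
        if y <= 0:
            raise ThermoError("nu_cat diverges at Y=0: no biomass basis exists")
        nu_cat = (1.0 - 10.0 * y) / (4.0 * y)
        return cls(y=y, f=f, y_co2=y_co2, y_ch4=y_ch4, nu_cat=nu_cat)


@dataclass(frozen=True)
class ExergyTerms:
    """Exergy decomposition entering the energetic growth law.

    ``e_cat``: work harvestable from one catabolic turn (kJ/mol reaction);
    ``e_m``: exergy stored in biomass, from the destock reaction (kJ/mol);
    ``e_dis``: exergy dissipated by the overall metabolic reaction, per mol
    of the stated substrate basis; ``v_harv``: harvest volume (L).
    """

    e_cat: float
    e_m: float
    e_dis: float
    v_harv: float = field(default=1.0)
    basis: str = "per mol H2"

    def __post_init__(self) -> None:
        if self.e_cat < 0 or self.e_m < 0:
            raise ThermoError("exergies must be non-negative")
        if self.v_harv <= 0:
            raise ThermoError("harvest volume must be positive")


# ---------------------------------------------------------------------------
# yield algebra


def fraction_from_yield(y: float) -> float:
    """Catabolic H2 fraction ``f = 1 - 10 Y`` for biomass yield ``Y``."""
    if not 0.0 <= y <= 0.1:
        raise ThermoError(f"yield Y={y} outside [0, 0.1]: f would leave [0, 1]")
    return 1.0 - 10.0 * y


def yield_factors(f: float) -> tuple[float, float]:
    """(YCO2, YCH4) in mol per mol H2 for catabolic fraction ``f``."""
    if not 0.0 <= f <= 1.0:
        raise ThermoError(f"catabolic fraction f={f} outside [0, 1]")
    y_ch4 = f / 4.0
    y_co2 = f / 4.0 + 0.5 * (1.0 - f)
    return y_co2, y_ch4


def yield_from_methane_growth_yield(
    g_biomass_per_mol_ch4: float,
    biomass_molar_mass: float = BIOMASS_MOLAR_MASS,
) -> float:
    """Biomass yield Y (mol/mol H2) from a methane-based growth yield.

    A measured growth yield of ``g`` grams biomass per mol CH4 fixes the
    molar ratio ``Y / YCH4 = g / M``.  Substituting ``YCH4 = f/4`` and
    ``f = 1 - 10 Y`` and solving for Y gives ``Y = r / (4 + 10 r)`` with
    ``r = g / M``.
    """
    if g_biomass_per_mol_ch4 < 0:
        raise ThermoError("growth yield must be non-negative")
    if biomass_molar_mass <= 0:
        raise ThermoError("biomass molar mass must be positive")
    r = g_biomass_per_mol_ch4 / biomass_molar_mass
    return r / (4.0 + 10.0 * r)


# ---------------------------------------------------------------------------
# reaction and process thermodynamics


def reaction_delta(
    rxn: ReactionSpec,
    table: FormationTable = DEFAULT_FORMATION_TABLE,
    temperature: float | None = None,
) -> ThermoState:
    """Standard reaction Gibbs energy and enthalpy from formation properties.

    ``dG`` and ``dH`` are coefficient-weighted sums over the reaction's
    species; ``TdS`` follows from the identity ``dG = dH - TdS``.  Basis is
    per mol of reaction as written.
    """
    dg = sum(coef * table[sp].dgf for sp, coef in rxn.coefficients.items())
    dh = sum(coef * table[sp].dhf for sp, coef in rxn.coefficients.items())
    return ThermoState(
        dg=dg,
        dh=dh,
        tds=dh - dg,
        temperature=temperature if temperature is not None else table.temperature,
        basis=f"per mol reaction [{rxn.name}]",
    )


def metabolic_state(
    y: float,
    table: FormationTable = DEFAULT_FORMATION_TABLE,
    temperature: float | None = None,
) -> ThermoState:
    """Thermodynamic state of the overall metabolic process per C-mol biomass.

    Per mol of biomass formed, growth couples ``nu_cat = (1-10Y)/(4Y)``
    catabolic turns of R1 with one anabolic turn of R2; dividing by the
    5 carbons of C5H7O2N expresses the result per C-mol.
    """
    if not 0.0 < y < 0.1:
        raise ThermoError(
            f"Y={y} outside (0, 0.1): the per-biomass basis requires 0 < Y < 0.1 "
            "(nu_cat diverges as Y -> 0)"
        )
    stoich = MetabolicStoichiometry.from_yield(y)
    cat = reaction_delta(R1_CATABOLISM, table, temperature)
    ana = reaction_delta(R2_ANABOLISM, table, temperature)
    dg = stoich.nu_cat * cat.dg + ana.dg
    dh = stoich.nu_cat * cat.dh + ana.dh
    return ThermoState(
        dg=dg / 5.0,
        dh=dh / 5.0,
        tds=(dh - dg) / 5.0,
        temperature=cat.temperature,
        basis="per C-mol biomass",
    )


def process_heat(
    n_h2_consumed: float,
    y: float,
    table: FormationTable = DEFAULT_FORMATION_TABLE,
    temperature: float | None = None,
) -> tuple[float, float, float]:
    """Heat of metabolising ``n_h2_consumed`` mol H2 at yield ``Y``.

    Returns ``(Q_total, Q_cat, Q_ana)`` in joules, negative for exothermic
    processes.  Per mol H2 the catabolic share is ``f * dH_R1 / 4`` and the
    anabolic share ``(1-f) * dH_R2 / 10``; their sum is exact by
    construction.
    """
    if n_h2_consumed < 0:
        raise ThermoError("H2 consumption must be non-negative")
    f = fraction_from_yield(y)
    cat = reaction_delta(R1_CATABOLISM, table, temperature)
    ana = reaction_delta(R2_ANABOLISM, table, temperature)
    q_cat = n_h2_consumed * f * cat.dh / 4.0 * 1e3
    q_ana = n_h2_consumed * (1.0 - f) * ana.dh / 10.0 * 1e3
    return q_cat + q_ana, q_cat, q_ana


def metabolic_enthalpy_per_mol_h2(
    y: float,
    table: FormationTable = DEFAULT_FORMATION_TABLE,
) -> float:
    """Reaction enthalpy of the metabolic process in kJ per mol H2 consumed."""
    total, _, _ = process_heat(1.0, y, table)
    return total / 1e3


def exergy_terms(
    y: float,
    table: FormationTable = DEFAULT_FORMATION_TABLE,
    temperature: float | None = None,
    destock: ReactionSpec | None = None,
    v_harv: float = 1.0,
) -> ExergyTerms:
    """Exergy decomposition of growth at yield ``Y``.

    ``E_cat`` is |dG| of R1 when exergonic (else 0).  ``E_M`` is |dG| of
    the destock reaction (by default the reverse of R2 normalised per C-mol
    biomass) when exergonic, else 0.  ``E_dis`` is the negative of the
    Gibbs energy of the overall metabolic reaction, expressed per mol H2.
    """
    cat = reaction_delta(R1_CATABOLISM, table, temperature)
    e_cat = max(0.0, -cat.dg)
    if destock is None:
        destock = R2_ANABOLISM.reversed().scaled(
            1.0 / 5.0, name="destock (reverse anabolism, per C-mol biomass)"
        )
    destock.assert_balanced(table)
    dst = reaction_delta(destock, table, temperature)
    e_m = max(0.0, -dst.dg)
    f = fraction_from_yield(y)
    ana = reaction_delta(R2_ANABOLISM, table, temperature)
    dg_per_h2 = f * cat.dg / 4.0 + (1.0 - f) * ana.dg / 10.0
    return ExergyTerms(e_cat=e_cat, e_m=e_m, e_dis=-dg_per_h2, v_harv=v_harv)


def ks_from_exergy(terms: ExergyTerms) -> float:
    """Affinity constant ``Ks = (E_M + E_dis) / (v_harv * E_cat)``."""
    if terms.e_cat <= 0:
        raise ThermoError(
            "E_cat = 0: substrate yields no catabolic exergy, Ks is infinite"
        )
    return (terms.e_m + terms.e_dis) / (terms.v_harv * terms.e_cat)


def harvest_volume_from_ks(
    ks: float, e_cat: float, e_m: float, e_dis: float
) -> float:
    """Invert the affinity relation for the harvest volume ``v_harv``."""
    if ks <= 0:
        raise ThermoError("Ks must be positive")
    if e_cat <= 0:
        raise ThermoError("E_cat must be positive")
    return (e_m + e_dis) / (ks * e_cat)


# ---------------------------------------------------------------------------
# driving-force classification

ENTHALPY_DRIVEN = "enthalpy-driven"
ENTROPY_DRIVEN = "entropy-driven"
ENTHALPY_DRIVEN_ENTROPY_RETARDED = "enthalpy-driven but entropy-retarded"
ENTROPY_DRIVEN_ENTHALPY_RETARDED = "entropy-driven but enthalpy-retarded"


def classify_driving_force(state: ThermoState) -> str:
    """Classify what makes a spontaneous process go.

    A negative dH drives (it lowers dG), a positive TdS drives (via
    ``dG = dH - TdS``).  When both drive, the larger |contribution| names
    the label; when one opposes spontaneity the label carries a
    "retarded" suffix.
    """
    if state.dg >= 0:
        raise ThermoError(
            f"process is not spontaneous (dG={state.dg:+.1f} {state.basis}); "
            "driving-force classification requires dG < 0"
        )
    h_drives = state.dh < 0
    s_drives = state.tds > 0
    if h_drives and s_drives:
        return ENTHALPY_DRIVEN if abs(state.dh) >= abs(state.tds) else ENTROPY_DRIVEN
    if h_drives:
        return ENTHALPY_DRIVEN_ENTROPY_RETARDED
    return ENTROPY_DRIVEN_ENTHALPY_RETARDED


# ---------------------------------------------------------------------------
# reporting


def thermo_report(
    y: float,
    table: FormationTable = DEFAULT_FORMATION_TABLE,
    temperature: float | None = None,
) -> dict:
    """Full energetic account of growth at yield ``Y`` (plain dict)."""
    stoich = MetabolicStoichiometry.from_yield(y)
    met = metabolic_state(y, table, temperature)
    q_total, q_cat, q_ana = process_heat(1e-3, y, table, temperature)
    terms = exergy_terms(y, table, temperature)
    return {
        "Y_mol_per_molH2": y,
        "f_catabolic_fraction": stoich.f,
        "YCO2_mol_per_molH2": stoich.y_co2,
        "YCH4_mol_per_molH2": stoich.y_ch4,
        "nu_cat": stoich.nu_cat,
        "dGm_kJ_per_Cmol": met.dg,
        "dHm_kJ_per_Cmol": met.dh,
        "TdSm_kJ_per_Cmol": met.tds,
        "driving_force": classify_driving_force(met),
        "heat_per_mmolH2_J": q_total,
        "anabolic_heat_share": q_ana / q_total if q_total else 0.0,
        "entropy_compensation_share": abs(met.tds) / abs(met.dh),
        "E_cat_kJ_per_mol_reaction": terms.e_cat,
        "E_M_kJ_per_mol": terms.e_m,
        "E_dis_kJ_per_molH2": terms.e_dis,
    }
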