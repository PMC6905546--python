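"""Stoichiometry, yield algebra and thermodynamic accounting."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from methanergy import thermo
from methanergy.thermo import (
    DEFAULT_FORMATION_TABLE,
    ExergyTerms,
    FormationTable,
    R1_CATABOLISM,
    R2_ANABOLISM,
    ReactionSpec,
    SpeciesThermo,
    ThermoState,
    classify_driving_force,
    exergy_terms,
    fraction_from_yield,
    harvest_volume_from_ks,
    ks_from_exergy,
    metabolic_state,
    process_heat,
    reaction_delta,
    yield_factors,
    yield_from_methane_growth_yield,
)


class TestYieldAlgebra:
    @pytest.mark.parametrize(
        "y, f", [(0.0, 1.0), (0.1, 0.0), (0.006, 0.94), (0.007, 0.93)]
    )
    def test_catabolic_fraction(self, y, f):
        assert fraction_from_yield(y) == pytest.approx(f)

    @pytest.mark.parametrize("y", [-0.01, 0.11, 1.0])
    def test_fraction_rejects_out_of_range_yield(self, y):
        with pytest.raises(ValueError):
            fraction_from_yield(y)

    @pytest.mark.parametrize(
        "f, expected",
        [
            (1.0, (0.25, 0.25)),  # pure catabolism: R1 stoichiometry
            (0.0, (0.5, 0.0)),  # pure anabolism: R2 stoichiometry
            (0.94, (0.265, 0.235)),
        ],
    )
    def test_yield_factors(self, f, expected):
        assert yield_factors(f) == pytest.approx(expected)

    @pytest.mark.parametrize("f", [-0.1, 1.1])
    def test_yield_factors_reject_bad_fraction(self, f):
        with pytest.raises(ValueError):
            yield_factors(f)

    @given(st.floats(min_value=0.0, max_value=1.0))
    @settings(max_examples=100, derandomize=True)
    def test_carbon_conservation_identity(self, f):
        """YCO2 - YCH4 - 5Y vanishes for every catabolic split."""
        y = (1.0 - f) / 10.0
        y_co2, y_ch4 = yield_factors(f)
        assert y_co2 - y_ch4 - 5.0 * y == pytest.approx(0.0, abs=1e-15)

    @pytest.mark.parametrize(
        "g_per_mol_ch4, expected",
        [(2.8, 0.006), (3.5, 0.007), (0.0, 0.0)],
    )
    def test_yield_from_methane_growth_yield(self, g_per_mol_ch4, expected):
        y = yield_from_methane_growth_yield(g_per_mol_ch4)
        assert round(y, 3) == pytest.approx(expected)

    def test_growth_yield_rejects_negative(self):
        with pytest.raises(ValueError):
            yield_from_methane_growth_yield(-1.0)
        with pytest.raises(ValueError):
            yield_from_methane_growth_yield(2.8, biomass_molar_mass=0.0)

    def test_growth_yield_is_self_consistent(self):
        """Converting back through Y/YCH4 reproduces the measured yield."""
        g = 2.8
        y = yield_from_methane_growth_yield(g)
        _, y_ch4 = yield_factors(fraction_from_yield(y))
        assert y / y_ch4 * 113.0 == pytest.approx(g, rel=1e-12)


class TestReactions:
    def test_both_metabolic_reactions_are_element_balanced(self):
        R1_CATABOLISM.assert_balanced(DEFAULT_FORMATION_TABLE)
        R2_ANABOLISM.assert_balanced(DEFAULT_FORMATION_TABLE)

    def test_unbalanced_reaction_is_caught(self):
        broken = ReactionSpec("broken", {"H2": -3.0, "CH4": 1.0})
        with pytest.raises(ValueError, match="not element-balanced"):
            broken.assert_balanced(DEFAULT_FORMATION_TABLE)

    def test_empty_reaction_has_zero_deltas(self):
        state = reaction_delta(ReactionSpec("null", {}))
        assert (state.dg, state.dh, state.tds) == (0.0, 0.0, 0.0)

    def test_catabolic_reaction_energetics(self):
        # hand sum of standard formation values for 4H2 + CO2 -> CH4 + 2H2O(l)
        state = reaction_delta(R1_CATABOLISM)
        assert state.dg == pytest.approx(-130.62, abs=0.01)
        assert state.dh == pytest.approx(-252.96, abs=0.01)

    def test_reversal_flips_all_signs(self):
        fwd = reaction_delta(R1_CATABOLISM)
        rev = reaction_delta(R1_CATABOLISM.reversed())
        assert rev.dg == pytest.approx(-fwd.dg)
        assert rev.dh == pytest.approx(-fwd.dh)
        assert rev.tds == pytest.approx(-fwd.tds)

    def test_missing_species_is_named(self):
        rxn = ReactionSpec("exotic", {"H2S": -1.0})
        with pytest.raises(ValueError, match="H2S"):
            reaction_delta(rxn)

    def test_formation_table_yaml_round_trip(self, tmp_path):
        path = tmp_path / "table.yaml"
        DEFAULT_FORMATION_TABLE.to_yaml(path)
        loaded = FormationTable.from_yaml(path)
        assert loaded == DEFAULT_FORMATION_TABLE

    def test_biomass_molar_mass(self):
        assert DEFAULT_FORMATION_TABLE["biomass"].molar_mass == 113.0
        assert DEFAULT_FORMATION_TABLE["biomass"].elements == {
            "C": 5,
            "H": 7,
            "O": 2,
            "N": 1,
        }


class TestMetabolicState:
    def test_reference_energetics_of_methanobrevibacter_growth(self):
        """Growth on H2/CO2 at Y=0.006: dGm/dHm/TdSm per C-mol biomass."""
        state = metabolic_state(0.006)
        assert state.dg == pytest.approx(-1073.0, rel=0.01)
        assert state.dh == pytest.approx(-2132.0, rel=0.01)
        assert state.tds == pytest.approx(-1059.0, rel=0.01)
        assert state.basis == "per C-mol biomass"

    @pytest.mark.parametrize("y", [0.0, 0.1, -0.01, 0.2])
    def test_rejects_yields_without_biomass_basis(self, y):
        with pytest.raises(ValueError):
            metabolic_state(y)

    @given(st.floats(min_value=1e-4, max_value=0.0999))
    @settings(max_examples=50, derandomize=True)
    def test_gibbs_helmholtz_identity(self, y):
        state = metabolic_state(y)
        assert state.dg - (state.dh - state.tds) == pytest.approx(0.0, abs=1e-9)

    def test_thermostate_rejects_inconsistent_components(self):
        with pytest.raises(ValueError, match="inconsistent"):
            ThermoState(dg=-1.0, dh=-2.0, tds=-3.0, temperature=298.15, basis="x")


class TestProcessHeat:
    def test_no_substrate_no_heat(self):
        assert process_heat(0.0, 0.006) == (0.0, 0.0, 0.0)

    def test_heat_of_one_millimole_hydrogen(self):
        # hand evaluation: 0.94*(-252.96)/4 + 0.06*(-693.80)/10 kJ/mol H2
        q_total, q_cat, q_ana = process_heat(1e-3, 0.006)
        assert q_total == pytest.approx(-63.61, abs=0.05)
        assert q_cat + q_ana == q_total  # exact by construction

    def test_anabolic_share_of_metabolic_heat(self):
        q_total, _, q_ana = process_heat(1e-3, 0.006)
        assert round(100.0 * q_ana / q_total) == 7

    @given(st.floats(min_value=0.0, max_value=1.0))
    @settings(max_examples=30, derandomize=True)
    def test_heat_is_linear_in_consumption(self, n):
        q1 = process_heat(1.0, 0.006)[0]
        qn = process_heat(n, 0.006)[0]
        assert qn == pytest.approx(n * q1, rel=1e-12, abs=1e-12)


class TestExergy:
    def test_catabolic_exergy_is_magnitude_of_r1_gibbs(self):
        terms = exergy_terms(0.006)
        assert terms.e_cat == pytest.approx(130.62, abs=0.01)

    def test_endergonic_catabolism_gives_zero_exergy(self):
        # a table in which R1 is uphill: swap the sign of CH4 formation
        table = DEFAULT_FORMATION_TABLE.with_species(
            "CH4", SpeciesThermo(800.0, 700.0, "g", "CH4", 16.04)
        )
        terms = exergy_terms(0.006, table=table)
        assert terms.e_cat == 0.0

    def test_dissipated_exergy_matches_metabolic_gibbs_energy(self):
        y = 0.006
        f = fraction_from_yield(y)
        cat = reaction_delta(R1_CATABOLISM)
        ana = reaction_delta(R2_ANABOLISM)
        expected = -(f * cat.dg / 4.0 + (1.0 - f) * ana.dg / 10.0)
        assert exergy_terms(y).e_dis == pytest.approx(expected, rel=1e-12)

    def test_destock_of_default_table_is_endergonic(self):
        # consuming own biomass back to H2/CO2/NH3 is uphill here, so E_M = 0
        assert exergy_terms(0.006).e_m == 0.0

    @given(
        e_cat=st.floats(min_value=1e-3, max_value=1e3),
        e_m=st.floats(min_value=0.0, max_value=1e3),
        e_dis=st.floats(min_value=1e-6, max_value=1e3),
        v_harv=st.floats(min_value=1e-3, max_value=1e3),
    )
    @settings(max_examples=100, derandomize=True)
    def test_affinity_round_trip(self, e_cat, e_m, e_dis, v_harv):
        ks = ks_from_exergy(ExergyTerms(e_cat, e_m, e_dis, v_harv))
        assert harvest_volume_from_ks(ks, e_cat, e_m, e_dis) == pytest.approx(
            v_harv, rel=1e-12
        )

    def test_doubling_harvest_volume_halves_ks(self):
        terms = exergy_terms(0.006, v_harv=1.0)
        doubled = ExergyTerms(terms.e_cat, terms.e_m, terms.e_dis, 2.0)
        assert ks_from_exergy(doubled) == pytest.approx(ks_from_exergy(terms) / 2.0)

    def test_zero_catabolic_exergy_means_infinite_ks(self):
        with pytest.raises(ValueError, match="infinite"):
            ks_from_exergy(ExergyTerms(0.0, 0.0, 10.0, 1.0))

    def test_harvest_volume_of_m_smithii(self):
        # frozen oracle: v = (E_M + E_dis) / (Ks * E_cat) with default exergies
        terms = exergy_terms(0.006)
        v = harvest_volume_from_ks(0.028, terms.e_cat, terms.e_m, terms.e_dis)
        assert v == pytest.approx(8.776, abs=0.01)


class TestDrivingForce:
    @pytest.mark.parametrize(
        "dh, tds, label",
        [
            # growth on H2/CO2 (this model), and a thermophilic analogue
            (-2132.0, -1059.0, "enthalpy-driven but entropy-retarded"),
            (-1605.0, -804.0, "enthalpy-driven but entropy-retarded"),
            (-3730.0, -2928.0, "enthalpy-driven but entropy-retarded"),
            # growth on formate and on methanol
            (-613.0, 267.0, "enthalpy-driven"),
            (-420.0, 150.0, "enthalpy-driven"),
            # aceticlastic methanogenesis
            (145.0, 511.0, "entropy-driven but enthalpy-retarded"),
        ],
    )
    def test_reference_classifications(self, dh, tds, label):
        state = ThermoState(
            dg=dh - tds, dh=dh, tds=tds, temperature=312.15, basis="per C-mol biomass"
        )
        assert classify_driving_force(state) == label

    def test_entropy_driven_when_entropy_dominates(self):
        state = ThermoState(dg=-900.0, dh=-100.0, tds=800.0, temperature=298.15, basis="x")
        assert classify_driving_force(state) == "entropy-driven"

    def test_non_spontaneous_process_is_rejected(self):
        state = ThermoState(dg=10.0, dh=5.0, tds=-5.0, temperature=298.15, basis="x")
        with pytest.raises(ValueError, match="not spontaneous"):
            classify_driving_force(state)


def test_thermo_report_is_complete_and_consistent():
    report = thermo.thermo_report(0.006)
    assert report["driving_force"] == "enthalpy-driven but entropy-retarded"
    assert math.isclose(
        report["TdSm_kJ_per_Cmol"],
        report["dHm_kJ_per_Cmol"] - report["dGm_kJ_per_Cmol"],
        rel_tol=1e-12,
    )
    assert 0.0 < report["anabolic_heat_share"] < 0.1
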