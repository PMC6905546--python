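"""Batch methanogenesis model: growth law, transfer, integration."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from methanergy import (
    BatchState,
    M_SMITHII,
    MethanogenParams,
    VesselConfig,
    co2_transfer_rate,
    derivatives,
    growth_rate,
    headspace_pressure,
    initial_state_from_headspace,
    simulate,
)
from methanergy.kinetics import SimulationError, biomass_concentration_from_cells


class TestGrowthRate:
    def test_zero_substrate_limit(self, vessel):
        assert growth_rate(0.0, M_SMITHII, vessel.vg) == 0.0

    def test_characteristic_point(self, vessel):
        # at ng_H2 = Ks*Vg the exponent is exactly -1
        ng = M_SMITHII.ks * vessel.vg
        assert growth_rate(ng, M_SMITHII, vessel.vg) == pytest.approx(
            M_SMITHII.mu_max / np.e
        )

    def test_saturation_limit(self, vessel):
        assert growth_rate(1e6, M_SMITHII, vessel.vg) == pytest.approx(
            M_SMITHII.mu_max, rel=1e-6
        )

    @given(st.floats(min_value=1e-5, max_value=1.0))
    @settings(max_examples=100, derandomize=True)
    def test_bounded_and_increasing(self, ng):
        vg = VesselConfig().vg
        mu = growth_rate(ng, M_SMITHII, vg)
        assert 0.0 < mu < M_SMITHII.mu_max
        assert growth_rate(ng * 1.01, M_SMITHII, vg) > mu

    def test_invalid_headspace_volume(self):
        with pytest.raises(ValueError):
            growth_rate(1e-3, M_SMITHII, 0.0)


class TestCo2Transfer:
    def test_zero_at_henry_equilibrium(self, vessel):
        ng = 2e-4
        s_eq = vessel.co2_equilibrium_concentration(ng)
        assert co2_transfer_rate(s_eq, ng, vessel) == pytest.approx(0.0, abs=1e-15)

    def test_supersaturated_liquid_degasses(self, vessel):
        ng = 2e-4
        s_eq = vessel.co2_equilibrium_concentration(ng)
        assert co2_transfer_rate(2 * s_eq, ng, vessel) > 0
        assert co2_transfer_rate(0.5 * s_eq, ng, vessel) < 0

    def test_linear_in_transfer_constant(self, vessel):
        fast = VesselConfig(kla=2 * vessel.kla)
        assert co2_transfer_rate(0.02, 1e-4, fast) == pytest.approx(
            2 * co2_transfer_rate(0.02, 1e-4, vessel)
        )


class TestDerivatives:
    def test_sterile_tube_has_no_biology(self, vessel):
        state = BatchState(x=0.0, s_co2=0.05, ng_h2=1e-3, ng_co2=2e-4, ng_ch4=0.0)
        d = derivatives(state, M_SMITHII, vessel)
        assert d[0] == 0.0  # no biomass change
        assert d[2] == 0.0  # no H2 uptake
        assert d[4] == 0.0  # no CH4 production
        # only CO2 keeps equilibrating between phases
        assert d[1] == pytest.approx(-co2_transfer_rate(0.05, 2e-4, vessel))

    def test_no_substrate_no_decay_is_stationary_biomass(self, vessel):
        params = MethanogenParams(name="x", mu_max=0.1, ks=0.03, y=0.006, kd=0.0)
        state = BatchState(x=1e-4, s_co2=0.0, ng_h2=0.0, ng_co2=0.0, ng_ch4=0.0)
        assert derivatives(state, params, vessel)[0] == 0.0

    def test_stoichiometric_coupling_of_rates(self, vessel):
        """CH4 production and H2 uptake are locked in the ratio YCH4."""
        state = BatchState(x=1e-4, s_co2=0.02, ng_h2=8e-4, ng_co2=2e-4, ng_ch4=1e-5)
        d = derivatives(state, M_SMITHII, vessel)
        st_ = M_SMITHII.stoichiometry
        assert d[4] / (-d[2]) == pytest.approx(st_.y_ch4, rel=1e-12)
        # carbon closure: CO2 drawn from both phases feeds CH4 and biomass
        # (the liquid-gas transfer term cancels in the combined pool)
        carbon_consumed = -(d[3] + vessel.vl * d[1])
        growth = growth_rate(state.ng_h2, M_SMITHII, vessel.vg) * state.x
        carbon_fixed = d[4] + 5.0 * M_SMITHII.y * (growth / M_SMITHII.y) * vessel.vl
        assert carbon_consumed == pytest.approx(carbon_fixed, rel=1e-10)


class TestInitialState:
    def test_ideal_gas_moles_at_standard_fill(self, vessel):
        state = initial_state_from_headspace(1.7, 0.8, 0.2, 1e-5, 0.01, vessel)
        assert state.ng_h2 == pytest.approx(1.048e-3, rel=1e-3)
        assert state.ng_co2 == pytest.approx(state.ng_h2 / 4.0)
        assert state.ng_ch4 == 0.0

    def test_zero_pressure_zero_moles(self, vessel):
        state = initial_state_from_headspace(0.0, 0.8, 0.2, 0.0, 0.0, vessel)
        assert state.ng_h2 == state.ng_co2 == 0.0

    def test_pure_hydrogen_fill(self, vessel):
        state = initial_state_from_headspace(1.0, 1.0, 0.0, 0.0, 0.0, vessel)
        assert state.ng_co2 == 0.0
        assert state.ng_h2 > 0.0

    def test_negative_pressure_rejected(self, vessel):
        with pytest.raises(ValueError):
            initial_state_from_headspace(-1.0, 0.8, 0.2, 0.0, 0.0, vessel)

    def test_overfull_fractions_rejected(self, vessel):
        with pytest.raises(ValueError):
            initial_state_from_headspace(1.0, 0.8, 0.5, 0.0, 0.0, vessel)

    def test_pressure_round_trip(self, vessel):
        state = initial_state_from_headspace(1.7, 0.8, 0.2, 0.0, 0.0, vessel)
        assert headspace_pressure(state, vessel) == pytest.approx(1.7)

    def test_pressure_of_one_millimole(self, vessel):
        state = BatchState(x=0.0, s_co2=0.0, ng_h2=1e-3, ng_co2=0.0, ng_ch4=0.0)
        assert headspace_pressure(state, vessel) == pytest.approx(1.2976, abs=1e-3)

    def test_negative_state_component_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            BatchState(x=-1e-3, s_co2=0.0, ng_h2=0.0, ng_co2=0.0, ng_ch4=0.0)


class TestSimulate:
    def test_trajectory_conserves_stoichiometry(self, smithii_run, vessel):
        """Gas changes stay locked to the yield factors along the whole run."""
        st_ = M_SMITHII.stoichiometry
        consumed = smithii_run.h2_consumed
        dch4 = smithii_run.ng_ch4 - smithii_run.ng_ch4[0]
        scale = max(consumed.max(), 1e-12)
        assert np.allclose(dch4, st_.y_ch4 * consumed, atol=1e-7 * scale)
        co2_pool = smithii_run.ng_co2 + vessel.vl * smithii_run.s_co2
        assert np.allclose(
            co2_pool[0] - co2_pool, st_.y_co2 * consumed, atol=1e-7 * scale
        )

    def test_biomass_balance_without_decay(self, vessel, balch_init):
        params = MethanogenParams(
            name="no-decay", mu_max=0.12, ks=0.028, y=0.006, kd=0.0
        )
        sim = simulate(params, vessel, balch_init, np.linspace(0, 72, 500))
        formed = (sim.x - sim.x[0]) * vessel.vl
        assert np.allclose(formed, params.y * sim.h2_consumed, rtol=1e-6, atol=1e-12)

    def test_hydrogen_depletion_extent(self, smithii_run):
        # frozen oracle: late-time growth stalls as mu collapses with H2,
        # leaving ~21% of the initial hydrogen after 72 h at x0 = 2e-5 mol/L
        frac_left = smithii_run.ng_h2[-1] / smithii_run.ng_h2[0]
        assert frac_left == pytest.approx(0.2109, abs=0.002)

    def test_sterile_tube_only_equilibrates_co2(self, vessel):
        init = BatchState(x=0.0, s_co2=0.05, ng_h2=0.0, ng_co2=1e-4, ng_ch4=0.0)
        params = MethanogenParams(name="x", mu_max=0.12, ks=0.028, y=0.006, kd=0.0)
        sim = simulate(params, vessel, init, np.linspace(0, 24, 100))
        assert np.all(sim.x == 0.0)
        assert np.all(sim.ng_ch4 == 0.0)
        assert sim.s_co2[-1] == pytest.approx(
            vessel.co2_equilibrium_concentration(sim.ng_co2[-1]), rel=1e-6
        )

    def test_grid_and_tolerance_refinement(self, vessel, balch_init):
        t = np.linspace(0, 72, 100)
        coarse = simulate(M_SMITHII, vessel, balch_init, t)
        tight = simulate(
            M_SMITHII, vessel, balch_init, t, rtol=5e-9, atol=5e-13
        )
        rel = abs(tight.ng_ch4[-1] - coarse.ng_ch4[-1]) / tight.ng_ch4[-1]
        assert rel < 1e-6

    def test_deterministic(self, vessel, balch_init):
        t = np.linspace(0, 72, 50)
        a = simulate(M_SMITHII, vessel, balch_init, t)
        b = simulate(M_SMITHII, vessel, balch_init, t)
        assert np.array_equal(a.states, b.states)

    def test_rejects_bad_grid(self, vessel, balch_init):
        with pytest.raises(ValueError):
            simulate(M_SMITHII, vessel, balch_init, [0.0, 2.0, 1.0])
        with pytest.raises(ValueError):
            simulate(M_SMITHII, vessel, balch_init, [0.0])

    def test_csv_round_trip(self, smithii_run, tmp_path, vessel):
        path = tmp_path / "run.csv"
        smithii_run.to_csv(path)
        from methanergy import SimulationResult

        loaded = SimulationResult.from_csv(path, M_SMITHII, vessel)
        assert np.allclose(loaded.states, smithii_run.states)
        assert "pressure_bar" in smithii_run.to_frame().columns


def test_cell_count_conversion_scales_linearly():
    one = biomass_concentration_from_cells(1e8)
    assert biomass_concentration_from_cells(2e8) == pytest.approx(2 * one)
    # 1e8 cells/mL at 0.3 pg/cell is ~0.03 g/L of C5H7O2N
    assert one == pytest.approx(0.03 / 113.0, rel=1e-9)
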