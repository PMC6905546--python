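"""Batch methanogenesis in a sealed anaerobic culture tube.

State variables (units fixed globally to mol, L, h, bar, K):

* ``x``        biomass concentration in the liquid (mol/L)
* ``s_co2``    dissolved CO2 concentration (mol/L)
* ``ng_h2``    headspace H2 (mol)
* ``ng_co2``   headspace CO2 (mol)
* ``ng_ch4``   headspace CH4 (mol)

Growth follows the exergy-based law ``mu = mu_max * exp(-Ks*Vg/ng_h2)``
on headspace hydrogen; CO2 exchanges between liquid and gas through a
first-order transfer driven by the departure from Henry equilibrium.
H2 and CH4 are treated as insoluble (their liquid-phase pools are not
modelled), so hydrogen is consumed directly from the headspace and
methane is released directly to it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .thermo import BIOMASS_MOLAR_MASS, MetabolicStoichiometry

__all__ = [
    "MethanogenParams",
    "VesselConfig",
    "BatchState",
    "SimulationResult",
    "growth_rate",
    "co2_transfer_rate",
    "derivatives",
    "simulate",
    "initial_state_from_headspace",
    "headspace_pressure",
    "biomass_concentration_from_cells",
]

_EXP_UNDERFLOW = -700.0  # exp() underflows to exactly 0 well before this
_NEGATIVE_TOL = 1e-9  # mol or mol/L; larger excursions are integrator failures


class SimulationError(RuntimeError):
    pass


@dataclass(frozen=True)
class MethanogenParams:
    """Kinetic and stoichiometric constants of one methanogen."""

    name: str
    mu_max: float  # 1/h
    ks: float  # mol/L
    y: float  # mol biomass / mol H2
    kd: float = 8.33e-4  # 1/h, first-order decay

    def __post_init__(self) -> None:
        if min(self.mu_max, self.ks, self.y, self.kd) < 0:
            raise ValueError("kinetic parameters must be non-negative")
        if self.mu_max <= self.kd:
            import warnings

            warnings.warn(
                f"{self.name}: mu_max <= kd, culture cannot sustain growth",
                stacklevel=2,
            )

    @property
    def stoichiometry(self) -> MetabolicStoichiometry:
        return MetabolicStoichiometry.from_yield(self.y)


@dataclass(frozen=True)
class VesselConfig:
    """Physical configuration of the culture vessel.

    Defaults describe a Balch tube: 20 mL headspace over 6 mL medium at
    39 C, with the CO2 transfer constant and Henry coefficient of
    standard anaerobic-digestion practice.
    """

    vg: float = 0.020  # L gas headspace
    vl: float = 0.006  # L liquid
    temperature: float = 312.15  # K
    kla: float = 8.33  # 1/h
    kh_co2: float = 0.0246  # M/bar
    r_gas: float = 0.08314  # bar/(M K)

    def __post_init__(self) -> None:
        if self.vg <= 0 or self.vl <= 0:
            raise ValueError("vessel volumes must be positive")
        if self.kh_co2 <= 0:
            raise ValueError("Henry coefficient must be positive")

    def co2_equilibrium_concentration(self, ng_co2: float) -> float:
        """Dissolved CO2 (mol/L) in Henry equilibrium with the headspace."""
        return self.kh_co2 * self.r_gas * self.temperature * ng_co2 / self.vg


@dataclass(frozen=True)
class BatchState:
    """One point of the batch state vector (all quantities non-negative)."""

    x: float  # mol biomass / L
    s_co2: float  # mol/L
    ng_h2: float  # mol
    ng_co2: float  # mol
    ng_ch4: float  # mol

    def __post_init__(self) -> None:
        for name, value in self.as_dict().items():
            if value < -_NEGATIVE_TOL:
                raise ValueError(f"negative state component {name}={value}")

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.s_co2, self.ng_h2, self.ng_co2, self.ng_ch4])

    def as_dict(self) -> dict[str, float]:
        return {
            "x": self.x,
            "s_co2": self.s_co2,
            "ng_h2": self.ng_h2,
            "ng_co2": self.ng_co2,
            "ng_ch4": self.ng_ch4,
        }

    @classmethod
    def from_array(cls, arr: Sequence[float]) -> "BatchState":
        arr = [0.0 if -_NEGATIVE_TOL < v < 0.0 else float(v) for v in arr]
        return cls(*arr)


def growth_rate(ng_h2: float, params: MethanogenParams, vg: float) -> float:
    """Specific growth rate ``mu = mu_max * exp(-Ks*Vg/ng_H2)`` (1/h).

    Defined as 0 at ``ng_h2 = 0`` (the continuous limit).
    """
    if vg <= 0:
        raise ValueError("headspace volume must be positive")
    if ng_h2 <= 0:
        return 0.0
    exponent = -params.ks * vg / ng_h2
    if exponent < _EXP_UNDERFLOW:
        return 0.0
    return params.mu_max * math.exp(exponent)


def co2_transfer_rate(s_co2: float, ng_co2: float, vessel: VesselConfig) -> float:
    """Liquid-to-gas CO2 transfer rate (mol/(L h), positive = degassing)."""
    return vessel.kla * (s_co2 - vessel.co2_equilibrium_concentration(ng_co2))


def derivatives(
    state: BatchState | Sequence[float],
    params: MethanogenParams,
    vessel: VesselConfig,
) -> np.ndarray:
    """Time derivative of the batch state vector.

    Hydrogen uptake is ``(mu/Y) * VL * x`` mol/h; CO2 and CH4 follow with
    the yield factors YCO2 and YCH4, and CO2 additionally exchanges with
    the headspace.
    """
    if isinstance(state, BatchState):
        x, s_co2, ng_h2, ng_co2, _ = state.as_array()
    else:
        x, s_co2, ng_h2, ng_co2, _ = state
    st = params.stoichiometry
    mu = growth_rate(ng_h2, params, vessel.vg)
    transfer = co2_transfer_rate(s_co2, ng_co2, vessel)  # mol/(L h)
    uptake = mu / params.y * x if params.y > 0 else 0.0  # mol H2 / (L h)
    return np.array(
        [
            mu * x - params.kd * x,
            -st.y_co2 * uptake - transfer,
            -uptake * vessel.vl,
            vessel.vl * transfer,
            st.y_ch4 * uptake * vessel.vl,
        ]
    )


def initial_state_from_headspace(
    p0: float,
    h2_fraction: float,
    co2_fraction: float,
    x0: float,
    s_co2_0: float,
    vessel: VesselConfig,
) -> BatchState:
    """Initial state from total headspace pressure and gas-mix fractions."""
    if p0 < 0:
        raise ValueError("initial pressure must be non-negative")
    if h2_fraction < 0 or co2_fraction < 0 or h2_fraction + co2_fraction > 1 + 1e-12:
        raise ValueError("gas fractions must be non-negative and sum to at most 1")
    n_total = p0 * vessel.vg / (vessel.r_gas * vessel.temperature)
    return BatchState(
        x=x0,
        s_co2=s_co2_0,
        ng_h2=h2_fraction * n_total,
        ng_co2=co2_fraction * n_total,
        ng_ch4=0.0,
    )


def headspace_pressure(state: BatchState, vessel: VesselConfig) -> float:
    """Total headspace pressure (bar) by the ideal gas law."""
    n_total = state.ng_h2 + state.ng_co2 + state.ng_ch4
    return n_total * vessel.r_gas * vessel.temperature / vessel.vg


def biomass_concentration_from_cells(
    cells_per_ml: float, g_per_cell: float = 3e-13
) -> float:
    """Convert a cell count to biomass concentration (mol C5H7O2N / L).

    The dry mass per cell is not well constrained for gut methanogens;
    the default 0.3 pg is a typical order of magnitude and should be
    overridden when a measured value is available.
    """
    return cells_per_ml * 1e3 * g_per_cell / BIOMASS_MOLAR_MASS


@dataclass
class SimulationResult:
    """Trajectory of a batch simulation plus derived series."""

    time: np.ndarray  # h
    states: np.ndarray  # shape (n_times, 5), columns as BatchState
    params: MethanogenParams
    vessel: VesselConfig

    _COLUMNS = ("xH2_molL", "sCO2_molL", "ngH2_mol", "ngCO2_mol", "ngCH4_mol")

    @property
    def x(self) -> np.ndarray:
        return self.states[:, 0]

    @property
    def s_co2(self) -> np.ndarray:
        return self.states[:, 1]

    @property
    def ng_h2(self) -> np.ndarray:
        return self.states[:, 2]

    @property
    def ng_co2(self) -> np.ndarray:
        return self.states[:, 3]

    @property
    def ng_ch4(self) -> np.ndarray:
        return self.states[:, 4]

    @property
    def pressure(self) -> np.ndarray:
        n_total = self.ng_h2 + self.ng_co2 + self.ng_ch4
        return n_total * self.vessel.r_gas * self.vessel.temperature / self.vessel.vg

    @property
    def mu(self) -> np.ndarray:
        return np.array(
            [growth_rate(n, self.params, self.vessel.vg) for n in self.ng_h2]
        )

    @property
    def h2_uptake_rate(self) -> np.ndarray:
        """Instantaneous H2 consumption by growth (mol/h)."""
        return self.mu / self.params.y * self.x * self.vessel.vl

    @property
    def h2_consumed(self) -> np.ndarray:
        """Cumulative H2 consumed since t0 (mol)."""
        return self.ng_h2[0] - self.ng_h2

    def final_state(self) -> BatchState:
        return BatchState.from_array(self.states[-1])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.states, columns=list(self._COLUMNS))
        df.insert(0, "time_h", self.time)
        df["pressure_bar"] = self.pressure
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, params: MethanogenParams, vessel: VesselConfig):
        df = pd.read_csv(path)
        states = df[list(cls._COLUMNS)].to_numpy()
        return cls(
            time=df["time_h"].to_numpy(), states=states, params=params, vessel=vessel
        )

    def plot(self, ax=None):
        """Quick diagnostic plot of gas moles and biomass."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.time, 1e3 * self.ng_h2, label="H2 (mmol)")
        ax.plot(self.time, 1e3 * self.ng_co2, label="CO2 (mmol)")
        ax.plot(self.time, 1e3 * self.ng_ch4, label="CH4 (mmol)")
        ax2 = ax.twinx()
        ax2.plot(self.time, 1e3 * self.x, color="k", ls=":", label="biomass (mmol/L)")
        ax.set_xlabel("time (h)")
        ax.set_ylabel("headspace gas (mmol)")
        ax2.set_ylabel("biomass (mmol/L)")
        ax.legend(loc="center right")
        return ax


def simulate(
    params: MethanogenParams,
    vessel: VesselConfig,
    init: BatchState,
    t_grid: Sequence[float],
    rtol: float = 1e-8,
    atol: float = 1e-12,
    method: str = "LSODA",
) -> SimulationResult:
    """Integrate the batch model over ``t_grid`` (h).

    Uses a stiff-capable implicit integrator: hydrogen depletion drives
    the growth term through many orders of magnitude late in the run.
    Small negative excursions (below 1e-9 in absolute value) are clipped
    to zero; anything larger raises.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or len(t_grid) < 2 or np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be a strictly increasing 1-D grid")

    def rhs(_t, s):
        return derivatives(s, params, vessel)

    sol = solve_ivp(
        rhs,
        (t_grid[0], t_grid[-1]),
        init.as_array(),
        t_eval=t_grid,
        method=method,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise SimulationError(f"integration failed: {sol.message}")
    states = sol.y.T
    worst = states.min()
    if worst < -_NEGATIVE_TOL:
        raise SimulationError(
            f"negative state excursion {worst:.3e} exceeds tolerance {_NEGATIVE_TOL}"
        )
    states = np.clip(states, 0.0, None)
    return SimulationResult(time=t_grid, states=states, params=params, vessel=vessel)
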