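"""Synthetic data with the structure of the Balch-tube experiments.

Generators produce (i) noisy headspace gas time series sampled like the
72-h growth experiments, (ii) calorimetric heat-flux curves with a lag,
an exponential phase and substrate depletion, and (iii) chemostat
competition trajectories.  All generators are pure functions of their
inputs and a seed, and every dataset records its provenance, so the full
analysis chain is testable without measured data.

Observation noise is multiplicative lognormal: gas amounts and thermal
powers are positive and span orders of magnitude, and a relative error
model keeps fixtures positive.  The default relative sigma of 5% is an
engineering choice for manometer + gas chromatography error.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__ as _version
from .calorimetry import HeatFluxCurve, heat_flux_from_simulation
from .competition import ChemostatConfig, CompetitionResult, simulate_competition
from .kinetics import (
    BatchState,
    MethanogenParams,
    VesselConfig,
    initial_state_from_headspace,
    simulate,
)

__all__ = [
    "NoiseModel",
    "SyntheticDataset",
    "DEFAULT_SAMPLING_TIMES",
    "default_initial_state",
    "generate_batch_dataset",
    "generate_heatflux_curve",
    "generate_competition_scenario",
]

#: ~13 sampling times over 0-72 h, denser early where dynamics are fast.
DEFAULT_SAMPLING_TIMES = np.array(
    [0.0, 2.0, 4.0, 6.0, 9.0, 12.0, 18.0, 24.0, 30.0, 36.0, 48.0, 60.0, 72.0]
)

#: defaults of the emulated experiment: 1.7 bar H2/CO2 80/20 headspace,
#: inoculum ~2 mg dry weight per litre, modest initial dissolved CO2.
DEFAULT_P0_BAR = 1.7
DEFAULT_H2_FRACTION = 0.8
DEFAULT_CO2_FRACTION = 0.2
DEFAULT_X0 = 2e-5  # mol/L
DEFAULT_S_CO2_0 = 0.01  # mol/L


@dataclass(frozen=True)
class NoiseModel:
    """Multiplicative lognormal observation noise with an additive floor."""

    sigma: float = 0.05  # relative (lognormal) scale
    floor: float = 0.0  # additive Gaussian SD in the observable's unit
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0 or self.floor < 0:
            raise ValueError("noise scales must be non-negative")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def apply(self, clean: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        clean = np.asarray(clean, dtype=float)
        noisy = clean * np.exp(self.sigma * rng.standard_normal(clean.shape))
        if self.floor > 0:
            noisy = noisy + self.floor * rng.standard_normal(clean.shape)
        return noisy


@dataclass
class SyntheticDataset:
    """A generated fixture: truth, clean trajectory, noisy observations."""

    truth: dict
    clean: pd.DataFrame
    observations: pd.DataFrame
    noise: NoiseModel
    provenance: dict = field(default_factory=dict)

    def write(self, directory) -> None:
        from pathlib import Path

        out = Path(directory)
        out.mkdir(parents=True, exist_ok=True)
        self.clean.to_csv(out / "clean.csv", index=False)
        self.observations.to_csv(out / "observations.csv", index=False)
        with open(out / "provenance.json", "w") as fh:
            json.dump(
                {"truth": self.truth, "noise": asdict(self.noise), **self.provenance},
                fh,
                indent=2,
                default=float,
            )


def default_initial_state(
    vessel: VesselConfig,
    p0: float = DEFAULT_P0_BAR,
    x0: float = DEFAULT_X0,
    s_co2_0: float = DEFAULT_S_CO2_0,
) -> BatchState:
    """Initial state of the emulated Balch-tube run."""
    return initial_state_from_headspace(
        p0, DEFAULT_H2_FRACTION, DEFAULT_CO2_FRACTION, x0, s_co2_0, vessel
    )


def generate_batch_dataset(
    params: MethanogenParams,
    vessel: VesselConfig,
    init: BatchState,
    sampling_times: Sequence[float] = DEFAULT_SAMPLING_TIMES,
    noise: NoiseModel = NoiseModel(),
) -> SyntheticDataset:
    """Simulate a batch culture and sample noisy gas observations.

    Noise is applied per observation to the three gas series only (the
    biomass and dissolved CO2 columns stay clean in the output frame, as
    in the experiment they are not observed through the same channel).
    """
    sampling_times = np.asarray(sampling_times, dtype=float)
    sim = simulate(params, vessel, init, sampling_times)
    clean = sim.to_frame()
    rng = noise.rng()
    obs = pd.DataFrame({"time_h": sampling_times})
    for col in ("ngH2_mol", "ngCO2_mol", "ngCH4_mol"):
        obs[col] = noise.apply(clean[col].to_numpy(), rng)
    truth = {
        "species": params.name,
        "mu_max": params.mu_max,
        "ks": params.ks,
        "y": params.y,
        "kd": params.kd,
        "x0": init.x,
        "s_co2_0": init.s_co2,
        "ng_h2_0": init.ng_h2,
        "ng_co2_0": init.ng_co2,
    }
    return SyntheticDataset(
        truth=truth,
        clean=clean,
        observations=obs,
        noise=noise,
        provenance={"generator": "batch", "version": _version, "seed": noise.seed},
    )


def generate_heatflux_curve(
    params: MethanogenParams,
    vessel: VesselConfig,
    init: BatchState,
    lag_h: float = 0.0,
    noise: NoiseModel = NoiseModel(sigma=0.0),
    baseline_uw: float = 0.0,
    t_max: float = 72.0,
    dt: float = 0.25,
) -> HeatFluxCurve:
    """Synthetic calorimetric curve: lag, exponential rise, depletion peak.

    The metabolic part is the model-predicted heat flux of a simulated
    batch culture, shifted right by the lag; before the lag only the
    baseline is recorded.  Noise is multiplicative on the metabolic
    signal, then the baseline is added.
    """
    if lag_h < 0:
        raise ValueError("lag must be non-negative")
    t_grid = np.arange(0.0, t_max + dt / 2, dt)
    sim = simulate(params, vessel, init, t_grid)
    flux = heat_flux_from_simulation(sim)
    if lag_h > 0:
        pre = np.arange(0.0, lag_h, dt)
        time = np.concatenate([pre, flux.time + lag_h])
        power = np.concatenate([np.zeros(len(pre)), flux.power])
    else:
        time, power = flux.time, flux.power
    rng = noise.rng()
    power = noise.apply(power, rng) if noise.sigma > 0 or noise.floor > 0 else power
    return HeatFluxCurve(time, power + baseline_uw, baseline=baseline_uw)


def generate_competition_scenario(
    species: Sequence[MethanogenParams],
    config: ChemostatConfig,
    init_biomass: Sequence[float],
    t_grid: Sequence[float],
    init_ng_h2: float = 1e-4,
    noise: NoiseModel = NoiseModel(sigma=0.0),
) -> tuple[CompetitionResult, pd.DataFrame]:
    """Chemostat trajectories plus (optionally) noisy biomass observations.

    Observation noise is applied post hoc, so the dynamics -- and the
    survivor classification -- are unaffected by it.
    """
    result = simulate_competition(species, config, init_biomass, t_grid, init_ng_h2)
    obs = result.to_frame().copy()
    if noise.sigma > 0 or noise.floor > 0:
        rng = noise.rng()
        for sp in species:
            col = f"x_{sp.name}_molL"
            obs[col] = noise.apply(obs[col].to_numpy(), rng)
    return result, obs
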