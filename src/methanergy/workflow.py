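"""Configuration handling and end-to-end analysis orchestration.

A single YAML configuration drives the full chain: per species, obtain
gas observations (from a file or the synthetic generator), estimate the
calorimetric growth rate constant when a heat-flux curve is available,
calibrate the batch model (Ks, sCO2_0), compute goodness statistics, a
thermodynamic report, and finally the competition prediction across the
requested dilution rates.  Every numeric output is traceable to the
(config, seed, version) triple echoed in the report header.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _version
from .calibration import BatchCalibration, FitSpec
from .calorimetry import HeatFluxCurve, detect_exponential_window, fit_growth_rate, total_heat
from .competition import predict_winner
from .kinetics import MethanogenParams, VesselConfig
from .synthetic import (
    DEFAULT_S_CO2_0,
    DEFAULT_SAMPLING_TIMES,
    DEFAULT_X0,
    NoiseModel,
    default_initial_state,
    generate_batch_dataset,
)
from .thermo import DEFAULT_FORMATION_TABLE, FormationTable, thermo_report

__all__ = ["AnalysisConfig", "SpeciesBlock", "load_config", "run_full_analysis"]

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    pass


_SPECIES_KEYS = {
    "name",
    "mu_max",
    "ks",
    "y",
    "kd",
    "data",
    "heat_data",
    "synthetic",
    "x0",
    "p0_bar",
    "s_co2_0",
}
_VESSEL_KEYS = {"vg", "vl", "temperature", "kla", "kh_co2", "r_gas"}
_FIT_KEYS = {"ks_bounds", "s_co2_0_bounds", "multistart", "seed"}
_TOP_KEYS = {
    "output_dir",
    "seed",
    "verbosity",
    "vessel",
    "thermo_table",
    "fit",
    "dilution_rates",
    "species",
}


def _reject_unknown(mapping: dict, allowed: set[str], context: str) -> None:
    unknown = set(mapping) - allowed
    if unknown:
        raise ConfigError(
            f"unknown key(s) in {context}: {sorted(unknown)} "
            f"(allowed: {sorted(allowed)})"
        )


@dataclass(frozen=True)
class SpeciesBlock:
    """Per-species configuration: kinetics plus data sources."""

    name: str
    mu_max: float
    ks: float = 0.02  # starting guess when re-estimated
    y: float = 0.006
    kd: float = 8.33e-4
    data: str | None = None
    heat_data: str | None = None
    synthetic: dict | None = None
    x0: float = DEFAULT_X0
    p0_bar: float = 1.7
    s_co2_0: float = DEFAULT_S_CO2_0

    def params(self) -> MethanogenParams:
        return MethanogenParams(
            name=self.name, mu_max=self.mu_max, ks=self.ks, y=self.y, kd=self.kd
        )


@dataclass(frozen=True)
class AnalysisConfig:
    """Validated top-level configuration for the full analysis."""

    species: tuple[SpeciesBlock, ...]
    vessel: VesselConfig = VesselConfig()
    fit: FitSpec = FitSpec()
    dilution_rates: tuple[float, ...] = (0.021, 0.04)
    thermo_table: str | None = None
    output_dir: str = "methanergy_out"
    seed: int = 0
    verbosity: str = "info"

    def __post_init__(self) -> None:
        if not self.species:
            raise ConfigError("config lists no species")

    def formation_table(self) -> FormationTable:
        if self.thermo_table is None:
            return DEFAULT_FORMATION_TABLE
        return FormationTable.from_yaml(self.thermo_table)

    def to_dict(self) -> dict:
        d = {
            "output_dir": self.output_dir,
            "seed": self.seed,
            "verbosity": self.verbosity,
            "vessel": dataclasses.asdict(self.vessel),
            "fit": {
                "ks_bounds": list(self.fit.ks_bounds),
                "s_co2_0_bounds": list(self.fit.s_co2_0_bounds),
                "multistart": self.fit.multistart,
                "seed": self.fit.seed,
            },
            "dilution_rates": list(self.dilution_rates),
            "species": [
                {k: v for k, v in dataclasses.asdict(sp).items() if v is not None}
                for sp in self.species
            ],
        }
        if self.thermo_table is not None:
            d["thermo_table"] = self.thermo_table
        return d

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def _build_config(payload: dict, base: Path) -> AnalysisConfig:
    if not isinstance(payload, dict):
        raise ConfigError("top level of the config must be a mapping")
    _reject_unknown(payload, _TOP_KEYS, "config")

    vessel_map = payload.get("vessel", {})
    _reject_unknown(vessel_map, _VESSEL_KEYS, "vessel block")
    vessel = VesselConfig(**vessel_map)
    for key in sorted(_VESSEL_KEYS - set(vessel_map)):
        logger.info("vessel.%s defaulted to %s", key, getattr(vessel, key))

    fit_map = dict(payload.get("fit", {}))
    _reject_unknown(fit_map, _FIT_KEYS, "fit block")
    for key in ("ks_bounds", "s_co2_0_bounds"):
        if key in fit_map:
            fit_map[key] = tuple(float(v) for v in fit_map[key])
    fit = FitSpec(**fit_map)

    species_list = payload.get("species") or []
    blocks = []
    for i, sp_map in enumerate(species_list):
        _reject_unknown(sp_map, _SPECIES_KEYS, f"species[{i}]")
        if "name" not in sp_map or "mu_max" not in sp_map:
            raise ConfigError(f"species[{i}] needs at least 'name' and 'mu_max'")
        sp_map = dict(sp_map)
        for key in ("data", "heat_data"):
            if sp_map.get(key):
                path = (base / sp_map[key]).resolve()
                if not path.exists():
                    raise ConfigError(f"species[{i}].{key}: file not found: {path}")
                sp_map[key] = str(path)
        blocks.append(SpeciesBlock(**sp_map))

    thermo_table = payload.get("thermo_table")
    if thermo_table is not None:
        path = (base / thermo_table).resolve()
        if not path.exists():
            raise ConfigError(f"thermo_table file not found: {path}")
        thermo_table = str(path)

    return AnalysisConfig(
        species=tuple(blocks),
        vessel=vessel,
        fit=fit,
        dilution_rates=tuple(payload.get("dilution_rates", (0.021, 0.04))),
        thermo_table=thermo_table,
        output_dir=str(payload.get("output_dir", "methanergy_out")),
        seed=int(payload.get("seed", 0)),
        verbosity=str(payload.get("verbosity", "info")),
    )


def load_config(path) -> AnalysisConfig:
    """Load and validate a YAML analysis configuration."""
    path = Path(path)
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    return _build_config(payload, path.parent)


def _analyse_species(
    block: SpeciesBlock, config: AnalysisConfig, table: FormationTable, out: Path
) -> dict:
    params = block.params()
    result: dict = {"species": block.name}

    # calorimetric growth rate, if a heat-flux curve is supplied
    mu_max = block.mu_max
    if block.heat_data:
        curve = HeatFluxCurve.from_csv(block.heat_data)
        window = detect_exponential_window(curve)
        fit = fit_growth_rate(curve, window)
        mu_max = fit.mu_c
        result["calorimetry"] = {
            "mu_c": fit.mu_c,
            "window_h": list(fit.window),
            "r_squared": fit.r_squared,
            "total_heat_J": total_heat(curve),
        }
        params = dataclasses.replace(params, mu_max=mu_max)

    # observations: measured file or seeded synthetic generation
    if block.data:
        observations = pd.read_csv(block.data)
        data_source = {"kind": "file", "path": block.data}
    else:
        synth = dict(block.synthetic or {})
        noise = NoiseModel(
            sigma=float(synth.get("sigma", 0.05)),
            seed=int(synth.get("seed", config.seed)),
        )
        init = default_initial_state(
            config.vessel, p0=block.p0_bar, x0=block.x0, s_co2_0=block.s_co2_0
        )
        dataset = generate_batch_dataset(
            params, config.vessel, init, DEFAULT_SAMPLING_TIMES, noise
        )
        dataset.write(out / f"synthetic_{block.name.replace(' ', '_').replace('.', '')}")
        observations = dataset.observations
        data_source = {"kind": "synthetic", "seed": noise.seed, "sigma": noise.sigma}
    result["data_source"] = data_source

    model = BatchCalibration(
        observations, params, config.vessel, x0=block.x0, fit_spec=config.fit
    )
    fit_res = model.fit()
    result["fit"] = {
        "estimates": fit_res.params.to_dict(),
        "std_errors": fit_res.bse.to_dict(),
        "objective": fit_res.cost,
        "converged": fit_res.converged,
    }
    result["goodness"] = {
        gas: dataclasses.asdict(g) for gas, g in fit_res.goodness.items()
    }
    result["summary_text"] = fit_res.summary()
    result["thermodynamics"] = thermo_report(block.y, table)
    return result


def run_full_analysis(config: AnalysisConfig) -> dict:
    """Run the whole pipeline and write artifacts to the output directory.

    Per-species failures are isolated: the run only fails if every
    species fails.
    """
    logging.basicConfig(level=getattr(logging, config.verbosity.upper(), logging.INFO))
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    table = config.formation_table()

    report: dict = {
        "version": _version,
        "seed": config.seed,
        "config": config.to_dict(),
        "species": [],
        "errors": {},
    }
    fitted_params = []
    for block in config.species:
        logger.info("analysing %s", block.name)
        try:
            species_report = _analyse_species(block, config, table, out)
        except Exception as err:
            logger.error("species %s failed: %s", block.name, err)
            report["errors"][block.name] = str(err)
            continue
        report["species"].append(species_report)
        fitted_params.append(
            dataclasses.replace(
                block.params(), ks=species_report["fit"]["estimates"]["Ks_molL"]
            )
        )

    if not report["species"]:
        raise RuntimeError(f"all species failed: {report['errors']}")

    report["competition"] = {}
    for d_rate in config.dilution_rates:
        try:
            ranking = predict_winner(fitted_params, config.vessel.vg, d_rate)
        except Exception as err:
            report["competition"][str(d_rate)] = {"error": str(err)}
            continue
        report["competition"][str(d_rate)] = {
            "ranking": [
                {"species": sp.name, "n_star_mmol": n * 1e3 if np.isfinite(n) else None}
                for sp, n in ranking
            ],
            "winner": ranking[0][0].name,
        }

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=float)
    return report
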