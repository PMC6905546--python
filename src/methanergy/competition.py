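"""Chemostat competition between hydrogenotrophic methanogens.

A toy continuous-flow model: each species ``i`` grows on the shared
headspace hydrogen pool ``n`` and washes out at its dilution rate
``D_i``; hydrogen is produced at a constant rate ``qH2`` and leaves with
first-order constant ``b``:

    dx_i/dt = mu_i(n) x_i - D_i x_i
    dn/dt   = qH2 - (VL/Y) sum_i mu_i(n) x_i - b n

with ``mu_i(n) = mu_max_i exp(-Ks_i Vg / n)``.  At a steady state a
persisting species satisfies ``mu_i(n*) = D_i``, which inverts to the
closed-form substrate requirement

    n*_i = Ks_i Vg / ln(mu_max_i / D_i)        (natural log).

Under constant conditions the species with the lowest ``n*`` excludes
all others (competitive exclusion).  Exclusion is asymptotic: a losing
species decays no faster than ``D_i - mu_i(n*)``, so it can remain
detectable long after its fate is sealed.  The survivor set reported
here therefore uses the classical persistence criterion -- a species
survives if it is above the extinction threshold *and* can at least
replace itself at the final hydrogen level (``mu_i(n_end) >= D_i``);
threshold crossings are reported separately as extinction times.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .kinetics import MethanogenParams, growth_rate

__all__ = [
    "ChemostatConfig",
    "CompetitionResult",
    "steady_state_substrate",
    "predict_winner",
    "simulate_competition",
    "single_species_equilibrium_biomass",
]


class CompetitionError(RuntimeError):
    pass


class WashoutError(CompetitionError):
    """No positive steady state: the dilution rate exceeds mu_max."""


@dataclass(frozen=True)
class ChemostatConfig:
    """Operating conditions of the multi-species chemostat.

    ``dilution`` may be a single rate applied to every species or one
    rate per species.  ``q_h2`` is the hydrogen supply in mol/h (note:
    per hour, like every other rate constant in the model).
    """

    dilution: float | tuple[float, ...]  # 1/h
    b: float = 0.5  # 1/h, substrate outflow constant
    q_h2: float = 0.02  # mol/h
    y: float = 0.006  # shared biomass yield, mol/mol H2
    vg: float = 0.020  # L
    vl: float = 0.006  # L
    extinction_threshold: float = 1e-9  # mol/L

    def __post_init__(self) -> None:
        rates = np.atleast_1d(np.asarray(self.dilution, dtype=float))
        if np.any(rates < 0) or self.b < 0 or self.q_h2 < 0:
            raise ValueError("rates must be non-negative")
        if self.extinction_threshold <= 0:
            raise ValueError("extinction threshold must be positive")

    def dilution_rates(self, n_species: int) -> np.ndarray:
        rates = np.atleast_1d(np.asarray(self.dilution, dtype=float))
        if len(rates) == 1:
            return np.full(n_species, rates[0])
        if len(rates) != n_species:
            raise ValueError(
                f"{len(rates)} dilution rates for {n_species} species"
            )
        return rates


def steady_state_substrate(
    params: MethanogenParams, vg: float, dilution: float
) -> float:
    """Closed-form steady-state headspace hydrogen ``n*`` (mol).

    ``n* = Ks Vg / ln(mu_max / D)``; diverges as ``D -> mu_max`` and has
    no positive solution at or beyond washout.
    """
    if dilution <= 0:
        raise ValueError("dilution rate must be positive")
    if dilution >= params.mu_max:
        raise WashoutError(
            f"{params.name}: D={dilution} >= mu_max={params.mu_max}, washout"
        )
    return params.ks * vg / math.log(params.mu_max / dilution)


def predict_winner(
    species: Sequence[MethanogenParams], vg: float, dilution: float
) -> list[tuple[MethanogenParams, float]]:
    """Rank species by their steady-state substrate requirement.

    Returns ``(species, n*)`` pairs sorted ascending by ``n*`` (the head
    of the list wins the competition); washed-out species are ranked
    last with ``n* = inf``.
    """
    if not species:
        raise ValueError("need at least one species")
    ranked = []
    for sp in species:
        try:
            nstar = steady_state_substrate(sp, vg, dilution)
        except WashoutError:
            nstar = math.inf
        ranked.append((sp, nstar))
    if all(math.isinf(n) for _, n in ranked):
        raise WashoutError("all species wash out at this dilution rate")
    ranked.sort(key=lambda item: item[1])
    return ranked


def single_species_equilibrium_biomass(
    params: MethanogenParams, config: ChemostatConfig, dilution: float
) -> float:
    """Equilibrium biomass ``x* = Y (qH2 - b n*) / (VL D)`` when positive."""
    nstar = steady_state_substrate(params, config.vg, dilution)
    xstar = config.y * (config.q_h2 - config.b * nstar) / (config.vl * dilution)
    if xstar <= 0:
        raise CompetitionError(
            "hydrogen supply cannot sustain this species at steady state"
        )
    return xstar


@dataclass
class CompetitionResult:
    """Trajectories and outcome of a competition simulation."""

    time: np.ndarray  # h
    biomass: np.ndarray  # (n_times, n_species) mol/L
    ng_h2: np.ndarray  # mol
    species: tuple[MethanogenParams, ...]
    config: ChemostatConfig
    extinction_times: dict[str, float | None] = field(default_factory=dict)
    survivors: tuple[str, ...] = ()

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"time_h": self.time, "ngH2_mol": self.ng_h2})
        for j, sp in enumerate(self.species):
            df[f"x_{sp.name}_molL"] = self.biomass[:, j]
        return df

    def summary(self) -> str:
        lines = [
            "Chemostat competition",
            "=" * 48,
            f"species:   {', '.join(sp.name for sp in self.species)}",
            f"horizon:   {self.time[-1]:.0f} h ({self.time[-1] / 24:.1f} d)",
            f"survivors: {', '.join(self.survivors) or '(none)'}",
            f"final headspace H2: {self.ng_h2[-1] * 1e3:.4f} mmol",
            "-" * 48,
        ]
        rates = self.config.dilution_rates(len(self.species))
        for j, sp in enumerate(self.species):
            t_ext = self.extinction_times.get(sp.name)
            status = (
                f"extinct at {t_ext:.0f} h"
                if t_ext is not None
                else ("survives" if sp.name in self.survivors else "doomed (mu < D)")
            )
            lines.append(
                f"{sp.name:<18} D={rates[j]:.3f}/h  x_end={self.biomass[-1, j]:.3e} mol/L  {status}"
            )
        return "\n".join(lines)


def simulate_competition(
    species: Sequence[MethanogenParams],
    config: ChemostatConfig,
    init_biomass: Sequence[float],
    t_grid: Sequence[float],
    init_ng_h2: float = 1e-4,
    rtol: float = 1e-8,
    atol: float = 1e-14,
) -> CompetitionResult:
    """Integrate the n-species chemostat and classify the outcome."""
    species = tuple(species)
    x0 = np.asarray(init_biomass, dtype=float)
    if len(x0) != len(species):
        raise ValueError("one initial biomass per species required")
    if np.any(x0 <= 0):
        raise ValueError("initial biomasses must be positive")
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or len(t_grid) < 2 or np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be strictly increasing")
    rates = config.dilution_rates(len(species))

    def rhs(_t, s):
        xs, n = s[:-1], s[-1]
        mus = np.array([growth_rate(n, sp, config.vg) for sp in species])
        dxs = (mus - rates) * xs
        dn = config.q_h2 - config.vl / config.y * float(mus @ xs) - config.b * n
        return np.append(dxs, dn)

    sol = solve_ivp(
        rhs,
        (t_grid[0], t_grid[-1]),
        np.append(x0, init_ng_h2),
        t_eval=t_grid,
        method="LSODA",
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise CompetitionError(f"integration failed: {sol.message}")
    biomass = np.clip(sol.y[:-1].T, 0.0, None)
    ng_h2 = np.clip(sol.y[-1], 0.0, None)

    threshold = config.extinction_threshold
    extinction: dict[str, float | None] = {}
    for j, sp in enumerate(species):
        below = np.nonzero(biomass[:, j] < threshold)[0]
        extinction[sp.name] = float(t_grid[below[0]]) if len(below) else None

    n_end = float(ng_h2[-1])
    survivors = []
    for j, sp in enumerate(species):
        detectable = biomass[-1, j] >= threshold
        sustainable = growth_rate(n_end, sp, config.vg) >= rates[j] * (1.0 - 1e-3)
        if detectable and sustainable:
            survivors.append(sp.name)
    return CompetitionResult(
        time=t_grid,
        biomass=biomass,
        ng_h2=ng_h2,
        species=species,
        config=config,
        extinction_times=extinction,
        survivors=tuple(survivors),
    )
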