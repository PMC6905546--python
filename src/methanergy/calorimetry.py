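"""Isothermal microcalorimetry: heat-flux curves and growth-rate fits.

During exponential growth the thermal power of a culture obeys
``dQ/dt = mu_c * Q``, so the slope of ``ln(power)`` against time over the
exponential window estimates the growth rate constant ``mu_c``.

Sign convention: instrument power is positive for an exothermic culture
(as plotted by calorimeters), while accumulated process heat Q is
reported negative for exothermic processes, matching the thermochemical
convention for reaction enthalpies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .kinetics import SimulationResult
from .thermo import DEFAULT_FORMATION_TABLE, FormationTable, metabolic_enthalpy_per_mol_h2

__all__ = [
    "HeatFluxCurve",
    "ExponentialFit",
    "fit_growth_rate",
    "detect_exponential_window",
    "total_heat",
    "heat_flux_from_simulation",
]

JOULE_PER_UWH = 3.6e-3  # 1 uW * 1 h = 3.6 mJ


class CalorimetryError(ValueError):
    pass


@dataclass
class HeatFluxCurve:
    """Time-stamped thermal power trace.

    ``time`` in hours (strictly increasing), ``power`` in microwatts.
    """

    time: np.ndarray
    power: np.ndarray
    baseline: float | None = None
    sampling_interval_h: float | None = field(default=None)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if self.time.shape != self.power.shape or self.time.ndim != 1:
            raise CalorimetryError("time and power must be 1-D arrays of equal length")
        if len(self.time) >= 2 and np.any(np.diff(self.time) <= 0):
            raise CalorimetryError("time must be strictly increasing")
        if not np.all(np.isfinite(self.power)):
            raise CalorimetryError("power must be finite")
        if self.sampling_interval_h is None and len(self.time) >= 2:
            self.sampling_interval_h = float(np.median(np.diff(self.time)))

    def __len__(self) -> int:
        return len(self.time)

    def estimate_baseline(self, edge_fraction: float = 0.05) -> float:
        """Constant baseline from the first and last ``edge_fraction`` samples."""
        k = max(1, int(edge_fraction * len(self.time)))
        edges = np.concatenate([self.power[:k], self.power[-k:]])
        return float(np.median(edges))

    def baseline_subtracted(self, baseline: float | None = None) -> "HeatFluxCurve":
        b = self.estimate_baseline() if baseline is None else baseline
        return HeatFluxCurve(self.time, self.power - b, baseline=b)

    def window(self, t_start: float, t_end: float) -> "HeatFluxCurve":
        mask = (self.time >= t_start) & (self.time <= t_end)
        return HeatFluxCurve(self.time[mask], self.power[mask], baseline=self.baseline)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_h": self.time, "power_uW": self.power})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "HeatFluxCurve":
        df = pd.read_csv(path)
        return cls(df["time_h"].to_numpy(), df["power_uW"].to_numpy())


@dataclass(frozen=True)
class ExponentialFit:
    """Log-linear fit of the exponential phase of a heat-flux curve."""

    mu_c: float  # 1/h
    window: tuple[float, float]  # (t_start, t_end) in h
    r_squared: float
    initial_power: float  # uW at window start, from the fit
    n_points: int

    def __post_init__(self) -> None:
        if self.window[0] >= self.window[1]:
            raise CalorimetryError("fit window must have t_start < t_end")
        if not np.isfinite(self.mu_c):
            raise CalorimetryError("mu_c must be finite")


def fit_growth_rate(
    curve: HeatFluxCurve, window: tuple[float, float] | None = None
) -> ExponentialFit:
    """Estimate ``mu_c`` as the slope of ln(power) vs time on a window.

    Requires at least 5 strictly positive power samples in the window.
    """
    sub = curve if window is None else curve.window(*window)
    if len(sub) < 5:
        raise CalorimetryError(
            f"need >= 5 points in the fit window, have {len(sub)}"
        )
    if np.any(sub.power <= 0):
        raise CalorimetryError(
            "non-positive power in fit window: logarithm undefined "
            "(subtract the baseline or narrow the window)"
        )
    log_p = np.log(sub.power)
    slope, intercept = np.polyfit(sub.time, log_p, 1)
    fitted = slope * sub.time + intercept
    ss_res = float(np.sum((log_p - fitted) ** 2))
    ss_tot = float(np.sum((log_p - log_p.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else max(0.0, 1.0 - ss_res / ss_tot)
    return ExponentialFit(
        mu_c=float(slope),
        window=(float(sub.time[0]), float(sub.time[-1])),
        r_squared=r2,
        initial_power=float(np.exp(intercept + slope * sub.time[0])),
        n_points=len(sub),
    )


def detect_exponential_window(
    curve: HeatFluxCurve,
    r2_min: float = 0.99,
    min_length_fraction: float = 0.20,
) -> tuple[float, float]:
    """Locate the exponential phase preceding the main heat-flux peak.

    Scans contiguous windows ending at or before the global power maximum
    whose duration is at least ``min_length_fraction`` of the time to
    peak, and returns the longest one whose log-linear fit reaches
    ``r2_min`` (earliest start on ties).
    """
    if len(curve) < 5:
        raise CalorimetryError("curve too short for window detection")
    peak_idx = int(np.argmax(curve.power))
    if peak_idx == 0:
        raise CalorimetryError(
            "no growth phase: the curve is maximal at its start "
            "(supply a manual window to fit_growth_rate)"
        )
    t0 = curve.time[0]
    min_length = min_length_fraction * (curve.time[peak_idx] - t0)
    positive = curve.power > 0

    best: tuple[float, float, float] | None = None  # (length, -t_start, ...)
    best_window: tuple[float, float] | None = None
    t = curve.time
    log_p = np.where(positive, np.log(np.where(positive, curve.power, 1.0)), np.nan)
    for start in range(peak_idx - 3):
        # vectorised log-linear r^2 for all windows [start, end], end <= peak
        if not positive[start]:
            continue
        ends = np.arange(start + 4, peak_idx + 1)
        if len(ends) == 0:
            continue
        valid = np.array([positive[start : e + 1].all() for e in ends])
        for e, ok in zip(ends, valid):
            if not ok:
                continue
            length = t[e] - t[start]
            if length < min_length:
                continue
            ts, ys = t[start : e + 1], log_p[start : e + 1]
            slope, intercept = np.polyfit(ts, ys, 1)
            resid = ys - (slope * ts + intercept)
            ss_tot = np.sum((ys - ys.mean()) ** 2)
            r2 = 1.0 if ss_tot == 0 else 1.0 - np.sum(resid**2) / ss_tot
            if r2 < r2_min:
                continue
            key = (length, -t[start])
            if best is None or key > best:
                best = key
                best_window = (float(t[start]), float(t[e]))
    if best_window is None:
        raise CalorimetryError(
            "no window reaches the log-linearity threshold; "
            "select the exponential phase manually"
        )
    return best_window


def total_heat(curve: HeatFluxCurve) -> float:
    """Accumulated process heat Q (J) by trapezoidal integration.

    Positive instrument power (exothermic) integrates to a negative Q.
    """
    if len(curve) < 2:
        raise CalorimetryError("need at least 2 samples to integrate")
    integral_uwh = float(np.trapezoid(curve.power, curve.time))
    return -integral_uwh * JOULE_PER_UWH


def heat_flux_from_simulation(
    sim: SimulationResult,
    table: FormationTable = DEFAULT_FORMATION_TABLE,
) -> HeatFluxCurve:
    """Model-predicted thermal power of a simulated batch culture.

    Power is the instantaneous H2 uptake rate times the metabolic
    reaction enthalpy per mol H2 (catabolic + anabolic shares weighted by
    the yield split), converted to microwatts; exothermic growth gives
    positive power.
    """
    dh_per_h2 = metabolic_enthalpy_per_mol_h2(sim.params.y, table)  # kJ/mol, < 0
    rate = sim.h2_uptake_rate  # mol/h
    power_uw = -rate * dh_per_h2 * 1e3 / 3600.0 * 1e6  # kJ/h -> uW
    return HeatFluxCurve(sim.time.copy(), power_uw)
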