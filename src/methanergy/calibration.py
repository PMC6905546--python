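"""Calibration of the batch model against gas time series.

The experimental design measures headspace H2, CO2 and CH4 over ~72 h.
With the maximum growth rate fixed from calorimetry (``mu_max = mu_c``)
and the physico-chemical constants known, only the affinity constant
``Ks`` and the initial dissolved CO2 ``sCO2_0`` remain free.  They are
estimated by bounded nonlinear least squares on the concatenated
residuals of the three gas series, each scaled by its observed maximum,
with a seeded Latin-hypercube multistart to guard against local optima
of the exponential-in-1/n growth law.

The module follows the model/results idiom: build a
:class:`BatchCalibration` from a tidy observation frame, call
:meth:`~BatchCalibration.fit`, inspect the returned
:class:`BatchCalibrationResults` (estimates, standard errors, per-gas
goodness statistics, ``summary()``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import qmc

from .kinetics import (
    BatchState,
    MethanogenParams,
    SimulationResult,
    VesselConfig,
    simulate,
)

__all__ = [
    "GoodnessStats",
    "FitSpec",
    "BatchCalibration",
    "BatchCalibrationResults",
    "ccc",
    "cv_rmse",
    "r_squared",
    "goodness_stats",
    "fit_batch",
]

logger = logging.getLogger(__name__)

GAS_COLUMNS = ("ngH2_mol", "ngCO2_mol", "ngCH4_mol")
_STATE_COLUMN = {"ngH2_mol": 2, "ngCO2_mol": 3, "ngCH4_mol": 4}


class CalibrationError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# goodness-of-fit statistics


def _validate_pair(obs, pred) -> tuple[np.ndarray, np.ndarray]:
    obs = np.asarray(obs, dtype=float)
    pred = np.asarray(pred, dtype=float)
    if obs.shape != pred.shape or obs.ndim != 1:
        raise ValueError("series must be 1-D and of equal length")
    if len(obs) < 2:
        raise ValueError("need at least 2 points")
    if not (np.all(np.isfinite(obs)) and np.all(np.isfinite(pred))):
        raise ValueError("series must be finite")
    return obs, pred


def ccc(obs, pred) -> float:
    """Lin's concordance correlation coefficient (population moments).

    ``CCC = 2 cov(x, y) / (var(x) + var(y) + (mean(x) - mean(y))^2)``,
    penalising location and scale shifts as well as poor correlation.
    """
    x, y = _validate_pair(obs, pred)
    mx, my = x.mean(), y.mean()
    vx, vy = x.var(), y.var()  # population (1/n) moments
    cov = ((x - mx) * (y - my)).mean()
    denom = vx + vy + (mx - my) ** 2
    if denom == 0:
        return 1.0  # both constant with equal means: perfect concordance
    if vx == 0 or vy == 0:
        return 0.0
    return float(2.0 * cov / denom)


def cv_rmse(obs, pred) -> float:
    """Coefficient of variation of the RMSE, in percent of the observed mean."""
    x, y = _validate_pair(obs, pred)
    mean = x.mean()
    if mean == 0:
        raise ValueError("CV_RMSE undefined for zero-mean observations")
    rmse = float(np.sqrt(np.mean((x - y) ** 2)))
    return 100.0 * rmse / abs(mean)


def r_squared(obs, pred) -> float:
    """Squared Pearson correlation between observations and predictions."""
    x, y = _validate_pair(obs, pred)
    if x.std() == 0 or y.std() == 0:
        return 0.0
    return float(np.corrcoef(x, y)[0, 1] ** 2)


@dataclass(frozen=True)
class GoodnessStats:
    ccc: float
    r2: float
    cv_rmse_pct: float

    def __post_init__(self) -> None:
        if not -1.0 - 1e-12 <= self.ccc <= 1.0 + 1e-12:
            raise ValueError("CCC outside [-1, 1]")
        if self.cv_rmse_pct < 0:
            raise ValueError("CV_RMSE must be non-negative")


def goodness_stats(obs, pred) -> GoodnessStats:
    return GoodnessStats(
        ccc=ccc(obs, pred), r2=r_squared(obs, pred), cv_rmse_pct=cv_rmse(obs, pred)
    )


# ---------------------------------------------------------------------------
# fit specification


@dataclass(frozen=True)
class FitSpec:
    """Free parameters, bounds and optimiser settings for a batch fit."""

    ks_bounds: tuple[float, float] = (1e-4, 1.0)  # mol/L
    s_co2_0_bounds: tuple[float, float] = (0.0, 0.2)  # mol/L
    multistart: int = 8
    seed: int = 0
    rtol: float = 1e-8
    atol: float = 1e-12

    def __post_init__(self) -> None:
        for lo, hi in (self.ks_bounds, self.s_co2_0_bounds):
            if not np.isfinite([lo, hi]).all() or lo >= hi:
                raise ValueError("bounds must be finite with lower < upper")
        if self.multistart < 1:
            raise ValueError("need at least one start")

    @property
    def lower(self) -> np.ndarray:
        return np.array([self.ks_bounds[0], self.s_co2_0_bounds[0]])

    @property
    def upper(self) -> np.ndarray:
        return np.array([self.ks_bounds[1], self.s_co2_0_bounds[1]])


# ---------------------------------------------------------------------------
# model


class BatchCalibration:
    """Batch methanogenesis model bound to observed gas time series.

    Parameters
    ----------
    data : DataFrame with columns ``time_h`` and at least one of
        ``ngH2_mol``, ``ngCO2_mol``, ``ngCH4_mol`` (missing cells allowed;
        they are dropped from the residuals).
    params : fixed kinetic constants; ``mu_max`` (from calorimetry),
        ``y`` and ``kd`` are held fixed while ``ks`` is re-estimated.
    vessel : physical configuration (volumes, temperature, transfer).
    x0 : initial biomass concentration (mol/L), held fixed.
    fit_spec : bounds and optimiser settings.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        params: MethanogenParams,
        vessel: VesselConfig,
        x0: float,
        fit_spec: FitSpec | None = None,
    ) -> None:
        if "time_h" not in data.columns:
            raise CalibrationError("data must have a time_h column")
        present = [c for c in GAS_COLUMNS if c in data.columns and data[c].notna().any()]
        if not present:
            raise CalibrationError(
                f"no observed gas series: need one of {GAS_COLUMNS}"
            )
        data = data.sort_values("time_h").reset_index(drop=True)
        if data["time_h"].nunique() < 5:
            raise CalibrationError("need at least 5 distinct time points")
        self.data = data
        self.observed = present
        self.params = params
        self.vessel = vessel
        self.x0 = float(x0)
        self.fit_spec = fit_spec or FitSpec()
        # per-series max-normalisation weights
        self._scales = {
            c: float(np.nanmax(np.abs(data[c]))) or 1.0 for c in present
        }
        t = data["time_h"].to_numpy(dtype=float)
        self._t_grid = t if t[0] == 0.0 else np.concatenate([[0.0], t])
        self._t_is_padded = t[0] != 0.0

    @classmethod
    def from_csv(
        cls, path, params: MethanogenParams, vessel: VesselConfig, x0: float, **kw
    ) -> "BatchCalibration":
        return cls(pd.read_csv(path), params, vessel, x0, **kw)

    # -- forward model -----------------------------------------------------
    def _initial_state(self, s_co2_0: float) -> BatchState:
        row = self.data.iloc[0]
        return BatchState(
            x=self.x0,
            s_co2=s_co2_0,
            ng_h2=float(row.get("ngH2_mol", 0.0) or 0.0),
            ng_co2=float(row.get("ngCO2_mol", 0.0) or 0.0),
            ng_ch4=float(row.get("ngCH4_mol", 0.0) or 0.0),
        )

    def predict(self, ks: float, s_co2_0: float) -> SimulationResult:
        """Forward-simulate the model at the observation times."""
        params = replace(self.params, ks=float(ks))
        sim = simulate(
            params,
            self.vessel,
            self._initial_state(s_co2_0),
            self._t_grid,
            rtol=self.fit_spec.rtol,
            atol=self.fit_spec.atol,
        )
        return sim

    def _residuals(self, theta: np.ndarray) -> np.ndarray:
        sim = self.predict(theta[0], theta[1])
        states = sim.states[1:] if self._t_is_padded else sim.states
        out = []
        for col in self.observed:
            obs = self.data[col].to_numpy(dtype=float)
            pred = states[:, _STATE_COLUMN[col]]
            mask = np.isfinite(obs)
            out.append((pred[mask] - obs[mask]) / self._scales[col])
        return np.concatenate(out)

    # -- fitting -----------------------------------------------------------
    def fit(self) -> "BatchCalibrationResults":
        spec = self.fit_spec
        sampler = qmc.LatinHypercube(d=2, seed=spec.seed)
        starts = qmc.scale(sampler.random(spec.multistart), spec.lower, spec.upper)
        best = None
        n_failed = 0
        for k, theta0 in enumerate(starts):
            try:
                res = optimize.least_squares(
                    self._residuals,
                    theta0,
                    bounds=(spec.lower, spec.upper),
                    method="trf",
                    x_scale=np.maximum(np.abs(theta0), 1e-3),
                )
            except Exception as err:  # integrator failure at a trial point
                n_failed += 1
                logger.warning("multistart %d from %s discarded: %s", k, theta0, err)
                continue
            if best is None or res.cost < best.cost:
                best = res
        if best is None:
            raise CalibrationError(
                f"all {spec.multistart} starts failed (integrator errors)"
            )
        return BatchCalibrationResults(model=self, optimum=best, n_failed_starts=n_failed)


class BatchCalibrationResults:
    """Estimates, uncertainties and diagnostics of a batch calibration."""

    param_names = ("Ks_molL", "sCO2_0_molL")

    def __init__(self, model: BatchCalibration, optimum, n_failed_starts: int = 0):
        self.model = model
        self._opt = optimum
        self.n_failed_starts = n_failed_starts
        self.params = pd.Series(optimum.x, index=list(self.param_names))
        self.cost = float(optimum.cost)
        self.converged = bool(optimum.success)
        self.residuals = np.asarray(optimum.fun)
        self._cov = self._covariance()
        self.bse = pd.Series(
            np.sqrt(np.diag(self._cov)) if self._cov is not None else np.nan,
            index=list(self.param_names),
        )

    # practical identifiability: Gauss-Newton covariance at the optimum
    def _covariance(self):
        jac = self._opt.jac
        m, p = jac.shape
        if m <= p:
            return None
        sigma2 = 2.0 * self.cost / (m - p)
        try:
            return sigma2 * np.linalg.inv(jac.T @ jac)
        except np.linalg.LinAlgError:
            return None

    @property
    def cov_params(self) -> pd.DataFrame | None:
        if self._cov is None:
            return None
        return pd.DataFrame(
            self._cov, index=list(self.param_names), columns=list(self.param_names)
        )

    def predict(self) -> SimulationResult:
        return self.model.predict(*self.params.to_numpy())

    @property
    def goodness(self) -> dict[str, GoodnessStats]:
        sim = self.predict()
        states = sim.states[1:] if self.model._t_is_padded else sim.states
        out = {}
        for col in self.model.observed:
            obs = self.model.data[col].to_numpy(dtype=float)
            mask = np.isfinite(obs)
            out[col] = goodness_stats(obs[mask], states[mask, _STATE_COLUMN[col]])
        return out

    def summary(self) -> str:
        lines = [
            "Batch methanogenesis calibration",
            "=" * 48,
            f"species:          {self.model.params.name}",
            f"observed series:  {', '.join(self.model.observed)}",
            f"n observations:   {len(self.residuals)}",
            f"fixed mu_max:     {self.model.params.mu_max:.4g} 1/h",
            f"fixed Y:          {self.model.params.y:.4g} mol/mol",
            f"fixed kd:         {self.model.params.kd:.4g} 1/h",
            f"multistart:       {self.model.fit_spec.multistart} "
            f"(seed {self.model.fit_spec.seed}, {self.n_failed_starts} failed)",
            f"converged:        {self.converged}",
            f"final objective:  {self.cost:.6g}",
            "-" * 48,
            f"{'parameter':<14}{'estimate':>12}{'std err':>12}",
        ]
        for name in self.param_names:
            lines.append(
                f"{name:<14}{self.params[name]:>12.5g}{self.bse[name]:>12.3g}"
            )
        lines.append("-" * 48)
        lines.append(f"{'series':<12}{'CCC':>8}{'r2':>8}{'CV_RMSE%':>10}")
        for col, g in self.goodness.items():
            lines.append(
                f"{col:<12}{g.ccc:>8.3f}{g.r2:>8.3f}{g.cv_rmse_pct:>10.1f}"
            )
        return "\n".join(lines)

    def plot_fit(self, ax=None):
        import matplotlib.pyplot as plt

        sim = self.predict()
        states = sim.states[1:] if self.model._t_is_padded else sim.states
        t = self.model.data["time_h"]
        if ax is None:
            _, ax = plt.subplots()
        for col in self.model.observed:
            line = ax.plot(sim.time, 1e3 * sim.states[:, _STATE_COLUMN[col]], label=col)
            ax.plot(
                t,
                1e3 * self.model.data[col],
                "o",
                color=line[0].get_color(),
                mfc="none",
            )
        ax.set_xlabel("time (h)")
        ax.set_ylabel("headspace gas (mmol)")
        ax.legend()
        return ax


def fit_batch(
    data: pd.DataFrame,
    spec: FitSpec,
    params: MethanogenParams,
    vessel: VesselConfig,
    x0: float,
) -> BatchCalibrationResults:
    """One-call interface: build a :class:`BatchCalibration` and fit it."""
    return BatchCalibration(data, params, vessel, x0, fit_spec=spec).fit()
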