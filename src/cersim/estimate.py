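"""Multistart weighted least-squares estimation of the 29 rate constants.

The objective is the sum over non-driver sphingolipids i and fitting time
points t of the squared relative error ((X_i(t) - Exp_i(t)) / Exp_i(t))^2,
where X is the deterministic model trajectory and Exp the measured
concentration.  Relative weighting keeps abundant species (SM is ~4 orders
of magnitude above S1P) from dominating the fit.

Fitting draws ``n_starts`` points log-uniformly within the rate bounds and
runs a bound-constrained trust-region-reflective least-squares solve
(scipy.optimize.least_squares) from each, in log10-rate space; the
residual vector is exactly the per-(species, time) relative error, so the
solver minimizes the stated objective.  The best of all local optima is
returned along with the full per-start table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .model import ModelSpec
from .simulate import TimeCourse, make_ode_solver

__all__ = ["FitConfig", "FitResult", "DataError", "objective", "fit_multistart"]

RAW_FIT_TIMES = (0.5, 1.0, 2.0, 4.0, 8.0, 12.0, 24.0)

_FAIL_RESIDUAL = 1e3  # residual magnitude reported when integration fails


class DataError(ValueError):
    """Raised when experimental data cannot support the relative objective."""


@dataclass
class FitConfig:
    """Configuration of the multistart fit.

    bounds: global (low, high) for every rate constant, in 1/h-equivalent
    mass-action units; sampling is uniform in log10 within them.
    time_points: fitting times in hours (t = 0 is excluded; measurements
    there set the initial conditions).
    """

    bounds: tuple[float, float] = (1e-6, 1e3)
    n_starts: int = 200
    seed: int = 0
    time_points: tuple[float, ...] = RAW_FIT_TIMES
    xtol: float = 1e-10
    ftol: float = 1e-10
    gtol: float = 1e-10
    max_nfev: int = 400
    rtol: float = 1e-6
    atol: float = 1e-9
    # per-evaluation integration-step budget: rate vectors whose fastest
    # timescale stalls the explicit solver count as failed evaluations, so
    # local solves cannot stall in infeasibly stiff corners of the box
    max_steps: int = 6_000

    def __post_init__(self) -> None:
        lo, hi = self.bounds
        if lo < 0 or hi <= lo:
            raise ValueError("bounds must satisfy 0 <= low < high")
        if self.n_starts < 1:
            raise ValueError("n_starts must be >= 1")


@dataclass
class FitResult:
    """Best rates found, with per-start provenance."""

    rates: np.ndarray
    objective_value: float
    start_index: int
    converged: bool
    starts: pd.DataFrame = field(repr=False)  # start rates, final objective, status


def _exp_matrix(model: ModelSpec, data: TimeCourse, time_points) -> np.ndarray:
    """Experimental values aligned to (time_points x dynamic species)."""
    names = model.dynamic_names
    missing = [n for n in names if n not in data.species]
    if missing:
        raise DataError(f"data is missing model species {missing}")
    cols = [data.species.index(n) for n in names]
    E = np.empty((len(time_points), len(names)))
    for i, t in enumerate(time_points):
        hits = np.nonzero(np.isclose(data.times, t))[0]
        if len(hits) != 1:
            raise DataError(f"data has no unique measurement at t = {t} h")
        E[i] = data.values[hits[0], cols]
    if np.any(E <= 0):
        raise DataError(
            "experimental values at fitting time points must be positive "
            "(the relative error is undefined otherwise)"
        )
    return E


def relative_residuals(X: np.ndarray, E: np.ndarray) -> np.ndarray:
    """Flattened per-(species, time) relative errors (X - E) / E."""
    return ((np.asarray(X, float) - E) / E).ravel()


def objective(
    model: ModelSpec,
    rates: np.ndarray,
    data: TimeCourse,
    config: FitConfig | None = None,
) -> float:
    """Weighted squared-relative-error objective at a given rate vector."""
    config = config or FitConfig()
    E = _exp_matrix(model, data, config.time_points)
    solve = make_ode_solver(model)
    t_eval = np.concatenate([[0.0], np.asarray(config.time_points, float)])
    values, status, t_fail = solve(
        np.asarray(rates, float), t_eval, rtol=config.rtol, atol=config.atol,
        max_steps=config.max_steps,
    )
    if status != 0:
        raise RuntimeError(f"simulation failed at t = {t_fail:.4g} h under these rates")
    r = relative_residuals(values[1:], E)
    return float(np.dot(r, r))


def fit_multistart(
    model: ModelSpec,
    data: TimeCourse,
    config: FitConfig,
    extra_starts: np.ndarray | None = None,
) -> FitResult:
    """Multistart bound-constrained nonlinear least squares.

    Returns the best local optimum over ``config.n_starts`` log-uniform
    starting points (plus any user-supplied ``extra_starts`` rate vectors,
    e.g. a previous fit to warm-start a validation refit); every start's
    outcome is recorded in the result.
    """
    E = _exp_matrix(model, data, config.time_points)
    solve = make_ode_solver(model)
    t_eval = np.concatenate([[0.0], np.asarray(config.time_points, float)])
    n_rates = len(model.reactions)
    lo, hi = config.bounds
    log_lo, log_hi = np.log10(lo), np.log10(hi)
    n_res = E.size

    def residual(theta: np.ndarray) -> np.ndarray:
        rates = 10.0**theta
        values, status, _ = solve(
            rates, t_eval, rtol=config.rtol, atol=config.atol,
            max_steps=config.max_steps,
        )
        if status != 0:
            return np.full(n_res, _FAIL_RESIDUAL)
        return relative_residuals(values[1:], E)

    rng = np.random.default_rng(config.seed)
    starts_theta = rng.uniform(log_lo, log_hi, size=(config.n_starts, n_rates))
    if extra_starts is not None:
        extra = np.log10(np.clip(np.atleast_2d(extra_starts), lo, hi))
        starts_theta = np.vstack([starts_theta, extra])

    records = []
    best = None
    for i in range(len(starts_theta)):
        try:
            sol = least_squares(
                residual,
                starts_theta[i],
                bounds=(log_lo, log_hi),
                method="trf",
                xtol=config.xtol,
                ftol=config.ftol,
                gtol=config.gtol,
                max_nfev=config.max_nfev,
            )
            obj = float(np.dot(sol.fun, sol.fun))
            records.append(
                {
                    "start_index": i,
                    "objective": obj,
                    "status": int(sol.status),
                    "nfev": int(sol.nfev),
                    "start_rates": 10.0 ** starts_theta[i],
                    "rates": 10.0**sol.x,
                }
            )
            if best is None or obj < best["objective"]:
                best = records[-1]
        except Exception as exc:  # noqa: BLE001 - keep the multistart going
            records.append(
                {
                    "start_index": i,
                    "objective": np.inf,
                    "status": -99,
                    "nfev": 0,
                    "start_rates": 10.0 ** starts_theta[i],
                    "rates": None,
                    "error": str(exc),
                }
            )
    if best is None or not np.isfinite(best["objective"]):
        raise RuntimeError(
            "all local solves failed; per-start diagnostics: "
            + "; ".join(str(r.get("error", r["status"])) for r in records)
        )
    rates = np.clip(best["rates"], lo, hi)
    return FitResult(
        rates=rates,
        objective_value=objective(model, rates, data, config),
        start_index=best["start_index"],
        converged=best["status"] > 0,
        starts=pd.DataFrame(records),
    )
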