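"""Enzyme and initial-condition perturbation experiments scored by AUC ratios.

Every experiment compares a perturbed simulation against the unperturbed
control through log2(AUC-perturbed / AUC-control) per sphingolipid, where
AUC is the trapezoidal integral of the simulated trajectory over the full
span.  Positive entries mean the perturbation increased the species' net
exposure.

Enzyme perturbations scale the rate constants of every reaction the
enzyme mediates (enzyme concentrations are folded into the rates, so
[E] * FC * kf' is exactly rate * FC).  Expression fold changes use the
2^x (up) / 2^-x (down) convention.  Dynamic perturbations redraw a
normal(0, sd) exponent per enzyme at each scheduled time and *replace*
the previous factor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .model import ModelSpec
from .simulate import TimeCourse, UNITS_CONC, make_ode_solver, simulate_ode

__all__ = [
    "PerturbationSpec",
    "scale_enzyme",
    "scale_reaction",
    "auc",
    "log2_auc_ratio",
    "enzyme_availability_scan",
    "fc_experiment",
    "dynamic_perturbation",
    "initial_condition_scan",
    "default_grid",
]

AVAILABILITY_FACTORS = tuple(np.round(np.arange(0.1, 1.01, 0.1), 10))
TRANSPORTED_SPECIES = ("Cer", "GluCer", "SM")  # ER -> Golgi/membrane traffic
INITIAL_FACTORS = (1.0, 0.8, 0.6, 0.4, 0.2)


def default_grid(t_end: float, step: float = 0.1) -> np.ndarray:
    """Output grid dense enough that trapezoid error is negligible."""
    return np.round(np.arange(0.0, t_end + step / 2, step), 10)


@dataclass
class PerturbationSpec:
    """Targets and schedule of an enzyme perturbation.

    mode "static_factor" scales by ``factor`` for the whole run;
    "expression_fc" uses the 2^x / 2^-x convention with ``fc_exponent``;
    "dynamic_random" redraws normal(0, sd) exponents per enzyme at each
    scheduled time.
    """

    targets: tuple[str, ...]
    mode: str = "static_factor"
    factor: float = 1.0
    fc_exponent: float = 0.0
    times: tuple[float, ...] | None = None
    n_random_times: int | None = None
    sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("static_factor", "expression_fc", "dynamic_random"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.factor <= 0:
            raise ValueError("factor must be positive")
        if self.sd < 0:
            raise ValueError("sd must be non-negative")


# ---------------------------------------------------------------------------
# elementary operations


def scale_enzyme(model: ModelSpec, enzyme: str, factor: float) -> ModelSpec:
    """Copy of the model with every rate the enzyme mediates scaled."""
    if enzyme not in model.enzymes:
        raise KeyError(f"unknown enzyme {enzyme!r}")
    if factor <= 0:
        raise ValueError("factor must be positive")
    targets = set(model.enzymes[enzyme])
    rates = model.rates
    for j, r in enumerate(model.reactions):
        if r.id in targets:
            rates[j] *= factor
    return model.with_rates(rates)


def scale_reaction(model: ModelSpec, reaction_id: str, factor: float) -> ModelSpec:
    """Copy of the model with a single reaction's rate constant scaled."""
    if factor <= 0:
        raise ValueError("factor must be positive")
    rates = model.rates
    ids = [r.id for r in model.reactions]
    rates[ids.index(reaction_id)] *= factor
    return model.with_rates(rates)


def auc(tc: TimeCourse, species: str) -> float:
    """Trapezoidal area under one species' trajectory (pmol*h/ug DNA)."""
    if species not in tc.species:
        raise KeyError(f"unknown species {species!r}")
    if len(tc.times) < 2:
        raise ValueError("AUC requires at least two time points")
    return float(np.trapezoid(tc.series(species), tc.times))


def log2_auc_ratio(perturbed: TimeCourse, control: TimeCourse) -> pd.Series:
    """Per-species log2(AUC-perturbed / AUC-control)."""
    if perturbed.species != control.species or not np.array_equal(
        perturbed.times, control.times
    ):
        raise ValueError("perturbed and control grids/species must match")
    out = {}
    for name in control.species:
        a_ctrl = auc(control, name)
        if a_ctrl <= 0:
            raise ZeroDivisionError(f"control AUC for {name} is not positive")
        out[name] = float(np.log2(auc(perturbed, name) / a_ctrl))
    return pd.Series(out, name="log2_auc_ratio")


# ---------------------------------------------------------------------------
# experiments


def enzyme_availability_scan(
    model: ModelSpec,
    enzyme: str,
    factors: Sequence[float] = AVAILABILITY_FACTORS,
    t_end: float = 24.0,
    grid: np.ndarray | None = None,
) -> pd.DataFrame:
    """log2 AUC ratios for reduced enzyme availability, one row per factor.

    Factors scan (0, 1]; the factor-1 simulation is the control.
    """
    factors = [float(f) for f in factors]
    if any(f <= 0 or f > 1 for f in factors):
        raise ValueError("availability factors must lie in (0, 1]")
    grid = default_grid(t_end) if grid is None else np.asarray(grid, float)
    control = simulate_ode(model, grid)
    rows = {}
    for f in factors:
        perturbed = (
            control if f == 1.0 else simulate_ode(scale_enzyme(model, enzyme, f), grid)
        )
        rows[f] = log2_auc_ratio(perturbed, control)
    table = pd.DataFrame(rows).T
    table.index.name = "factor"
    return table


def fc_experiment(
    model: ModelSpec,
    fc_table: pd.DataFrame | Mapping[str, str],
    fc_grid: Sequence[float] | None = None,
    t_end: float = 24.0,
    grid: np.ndarray | None = None,
) -> pd.DataFrame:
    """Expression fold-change experiment over a grid of FC magnitudes.

    ``fc_table`` maps enzymes to a direction ("up"/"down"), either as a
    mapping or as a DataFrame with columns ``enzyme``/``direction``.  At
    grid value f, up-regulated enzymes are scaled by f and down-regulated
    by 1/f (the 2^x / 2^-x convention with f = 2^x), all simultaneously.
    Default grid: 0.25-4 for a single enzyme, 1-4 for a group.
    """
    if isinstance(fc_table, pd.DataFrame):
        directions = dict(zip(fc_table["enzyme"], fc_table["direction"]))
    else:
        directions = dict(fc_table)
    for enz, d in directions.items():
        if enz not in model.enzymes:
            raise KeyError(f"unknown enzyme {enz!r}")
        if d not in ("up", "down"):
            raise ValueError(f"direction for {enz} must be 'up' or 'down'")
    if fc_grid is None:
        fc_grid = (0.25, 0.5, 1.0, 2.0, 4.0) if len(directions) <= 1 else (1.0, 2.0, 4.0)
    if any(f <= 0 for f in fc_grid):
        raise ValueError("FC values must be positive")
    grid = default_grid(t_end) if grid is None else np.asarray(grid, float)
    control = simulate_ode(model, grid)
    rows = {}
    for f in fc_grid:
        scaled = model
        for enz, d in directions.items():
            scaled = scale_enzyme(scaled, enz, f if d == "up" else 1.0 / f)
        perturbed = control if f == 1.0 and not directions else (
            control if f == 1.0 else simulate_ode(scaled, grid)
        )
        rows[float(f)] = log2_auc_ratio(perturbed, control)
    table = pd.DataFrame(rows).T
    table.index.name = "fc"
    return table


def draw_dynamic_factors(
    rng: np.random.Generator, enzymes: Sequence[str], sd: float
) -> dict[str, float]:
    """One 2^normal(0, sd) factor per enzyme (the per-event draw)."""
    return {e: float(2.0 ** rng.normal(0.0, sd)) for e in enzymes}


def dynamic_perturbation(
    model: ModelSpec,
    schedule: PerturbationSpec,
    n_sims: int,
    t_end: float = 24.0,
    grid: np.ndarray | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> tuple[list[TimeCourse], pd.DataFrame, TimeCourse]:
    """Piecewise simulation under random enzyme fold changes.

    At each scheduled time every target enzyme's reactions are rescaled by
    2^FC with FC ~ normal(0, sd), replacing (not compounding) the previous
    draw.  Returns the replicate trajectories, a summary table (per time,
    species: median and quantiles across replicates) and the control.
    """
    if schedule.mode != "dynamic_random":
        raise ValueError("schedule.mode must be 'dynamic_random'")
    grid = default_grid(t_end) if grid is None else np.asarray(grid, float)
    enzymes = schedule.targets or tuple(model.enzymes)
    rng_master = np.random.default_rng(schedule.seed)
    if schedule.times is not None:
        event_times = np.asarray(schedule.times, float)
    elif schedule.n_random_times:
        event_times = None  # drawn per replicate below
    else:
        raise ValueError("schedule needs fixed times or n_random_times")
    if schedule.times is not None and (
        np.any(event_times < 0) or np.any(event_times > t_end)
    ):
        raise ValueError("scheduled times must lie within the simulation span")

    base_rates = model.rates
    solve = make_ode_solver(model)
    enzyme_rxn_rows = {
        e: [i for i, r in enumerate(model.reactions) if r.id in set(model.enzymes[e])]
        for e in enzymes
    }
    control = simulate_ode(model, grid, rtol=rtol, atol=atol)

    replicates: list[TimeCourse] = []
    for rep in range(n_sims):
        rng = np.random.default_rng(rng_master.integers(2**31))
        if schedule.times is None:
            ts = np.sort(rng.uniform(0.0, t_end, size=schedule.n_random_times))
        else:
            ts = event_times
        ts = ts[(ts > 0) & (ts < t_end)]
        segment_edges = np.concatenate([[0.0], ts, [t_end]])
        values = np.empty((len(grid), len(model.dynamic_names)))
        y = model.initial_values.copy()
        rates = base_rates.copy()
        for a, b in zip(segment_edges[:-1], segment_edges[1:]):
            inside = (grid >= a) & (grid <= b)
            seg_grid = np.unique(np.concatenate([[a], grid[inside], [b]]))
            seg_vals, status, t_fail = solve(
                rates, seg_grid, rtol=rtol, atol=atol, y0=y
            )
            if status != 0:
                raise RuntimeError(f"segment integration failed at t = {t_fail:.4g} h")
            for gi in np.nonzero(inside)[0]:
                values[gi] = seg_vals[np.searchsorted(seg_grid, grid[gi])]
            y = seg_vals[-1]
            if b < t_end:  # redraw factors at the event time b
                factors = draw_dynamic_factors(rng, enzymes, schedule.sd)
                rates = base_rates.copy()
                for e, f in factors.items():
                    for row in enzyme_rxn_rows[e]:
                        rates[row] *= f
        replicates.append(
            TimeCourse(grid, np.clip(values, 0, None), tuple(model.dynamic_names),
                       UNITS_CONC, {"replicate": rep, "seed": schedule.seed})
        )
    stack = np.stack([r.values for r in replicates])
    summary = pd.concat(
        {
            "median": pd.DataFrame(
                np.median(stack, axis=0), index=grid, columns=model.dynamic_names
            ),
            "q05": pd.DataFrame(
                np.quantile(stack, 0.05, axis=0), index=grid, columns=model.dynamic_names
            ),
            "q95": pd.DataFrame(
                np.quantile(stack, 0.95, axis=0), index=grid, columns=model.dynamic_names
            ),
        },
        names=["statistic", "time"],
    )
    return replicates, summary, control


def initial_condition_scan(
    model: ModelSpec,
    species_subset: Sequence[str] = TRANSPORTED_SPECIES,
    factors: Sequence[float] = INITIAL_FACTORS,
    t_end: float = 24.0,
    grid: np.ndarray | None = None,
) -> pd.DataFrame:
    """Transport-impairment scan: scale initial concentrations and score.

    One row per (species, factor): the named species' initial value is
    multiplied by the factor, the model re-simulated and scored against
    the unmodified control.
    """
    if any(f <= 0 or f > 1 for f in factors):
        raise ValueError("factors must lie in (0, 1]")
    dyn = set(model.dynamic_names)
    unknown = [s for s in species_subset if s not in dyn]
    if unknown:
        raise KeyError(f"unknown dynamic species {unknown}")
    grid = default_grid(t_end) if grid is None else np.asarray(grid, float)
    control = simulate_ode(model, grid)
    rows = {}
    for name in species_subset:
        base = float(
            next(s.initial_value for s in model.dynamic_species if s.name == name)
        )
        for f in factors:
            if f == 1.0:
                rows[(name, float(f))] = log2_auc_ratio(control, control)
                continue
            scaled = model.with_initial_values({name: base * f})
            rows[(name, float(f))] = log2_auc_ratio(simulate_ode(scaled, grid), control)
    table = pd.DataFrame(rows).T
    table.index.names = ["species_scaled", "factor"]
    return table
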