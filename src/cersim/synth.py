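"""Synthetic lipidomics: driver curves, ground truth and noisy time courses.

The generator emulates the structure of KLA-stimulated macrophage
measurements: positive concentrations spanning orders of magnitude across
species, pulse-shaped driver curves for palmitoyl-CoA / DAG / PC, the
RAW264.7 sampling layout {0, 0.5, 1, 2, 4, 8, 12, 24} h (alternatively the
BMDM layout {0, 0.25, 0.5, 1, 2, 4, 8, 20} h), and multiplicative
measurement noise.  Noise is mean-preserving lognormal: each cell is
multiplied by exp(sigma*z - sigma^2/2) with sigma = sqrt(log(1 + cv^2)),
so E[noisy] equals the noiseless value and the coefficient of variation is
exactly ``noise_cv``.  Every dataset records the generating truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .model import ModelSpec, SpeciesSpec
from .simulate import TimeCourse, UNITS_CONC, simulate_ode

__all__ = [
    "RAW_TIME_POINTS",
    "BMDM_TIME_POINTS",
    "SynthConfig",
    "SynthDataset",
    "generate_drivers",
    "apply_drivers",
    "generate_dataset",
    "generate_fc_table",
]

RAW_TIME_POINTS = (0.0, 0.5, 1.0, 2.0, 4.0, 8.0, 12.0, 24.0)
BMDM_TIME_POINTS = (0.0, 0.25, 0.5, 1.0, 2.0, 4.0, 8.0, 20.0)

DRIVER_NAMES = ("palmCoA", "DAG", "PC")


@dataclass
class SynthConfig:
    """Ground truth and sampling layout of one synthetic dataset."""

    truth_rates: np.ndarray | None = None  # None: use the model's rates
    time_points: tuple[float, ...] = RAW_TIME_POINTS
    noise_cv: float = 0.1
    n_replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be non-negative")
        if 0.0 not in self.time_points:
            raise ValueError("time_points must include 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


@dataclass
class SynthDataset:
    """Noisy replicate tables, their drivers, and the generating truth."""

    replicates: list[TimeCourse]
    drivers: dict[str, tuple[tuple[float, float], ...]]
    truth_rates: np.ndarray
    config: SynthConfig = field(repr=False)

    def mean_timecourse(self) -> TimeCourse:
        """Per-cell mean across replicates (the table a fit consumes)."""
        stack = np.stack([r.values for r in self.replicates])
        first = self.replicates[0]
        return TimeCourse(
            first.times, stack.mean(axis=0), first.species, first.units,
            {"n_replicates": len(self.replicates)},
        )


def generate_drivers(
    seed: int,
    shape: str = "pulse",
    time_points: Sequence[float] = RAW_TIME_POINTS,
    base: float = 1.0,
) -> dict[str, tuple[tuple[float, float], ...]]:
    """Driver knot sets at the dataset time points.

    "pulse" rises then decays (KLA-stimulation-like, unique interior
    maximum), "ramp" increases monotonically, "constant" is flat.
    Deterministic given the seed.
    """
    if shape not in ("pulse", "ramp", "constant"):
        raise ValueError(f"unknown driver shape {shape!r}")
    rng = np.random.default_rng(seed)
    t = np.asarray(sorted(time_points), dtype=float)
    out: dict[str, tuple[tuple[float, float], ...]] = {}
    for name in DRIVER_NAMES:
        if shape == "constant":
            vals = np.full(len(t), base)
        elif shape == "ramp":
            amp = rng.uniform(0.5, 2.0)
            vals = base * (1.0 + amp * (t - t[0]) / (t[-1] - t[0]))
        else:
            peak = float(rng.choice(t[1:-1]))  # interior knot
            amp = rng.uniform(1.0, 2.0)
            tau = np.where(t > 0, t / peak, 0.0)
            vals = base * (1.0 + amp * tau * np.exp(1.0 - tau))
        out[name] = tuple((float(ti), float(v)) for ti, v in zip(t, vals))
    return out


def apply_drivers(
    model: ModelSpec, knots: Mapping[str, Sequence[tuple[float, float]]]
) -> ModelSpec:
    """Copy of the model with named driver curves replaced."""
    new_species = []
    for s in model.species:
        if s.name in knots:
            if s.role != "driver":
                raise ValueError(f"{s.name} is not a driver species")
            new_species.append(
                replace(s, driver_knots=tuple((float(t), float(v)) for t, v in knots[s.name]))
            )
        else:
            new_species.append(s)
    return ModelSpec(new_species, list(model.reactions), dict(model.enzymes))


def generate_dataset(model: ModelSpec, config: SynthConfig) -> SynthDataset:
    """Simulate the truth and apply per-cell multiplicative noise.

    t = 0 rows are the (noisy) initial conditions; every value is strictly
    positive whenever the noiseless trajectory is.
    """
    truth = (
        np.asarray(config.truth_rates, float)
        if config.truth_rates is not None
        else model.rates
    )
    truth_model = model.with_rates(truth)
    times = np.asarray(sorted(config.time_points), dtype=float)
    try:
        clean = simulate_ode(truth_model, times)
    except RuntimeError as exc:
        raise RuntimeError(
            "simulation failed under the requested truth rates; redraw them"
        ) from exc
    rng = np.random.default_rng(config.seed)
    cv = config.noise_cv
    sigma = float(np.sqrt(np.log1p(cv**2)))
    replicates = []
    for rep in range(config.n_replicates):
        if cv == 0:
            noisy = clean.values.copy()
        else:
            z = rng.standard_normal(clean.values.shape)
            noisy = clean.values * np.exp(sigma * z - sigma**2 / 2.0)
        replicates.append(
            TimeCourse(times, noisy, clean.species, UNITS_CONC,
                       {"replicate": rep, "seed": config.seed, "noise_cv": cv})
        )
    drivers = {s.name: s.driver_knots for s in model.driver_species}
    return SynthDataset(replicates, drivers, truth, config)


def generate_fc_table(
    seed: int,
    enzymes: Sequence[str],
    n_up: int,
    n_down: int,
    exponent_range: tuple[float, float] = (0.5, 2.0),
) -> pd.DataFrame:
    """Random disjoint up/down enzyme sets with FC exponents.

    Emulates a differential-expression contrast at the enzyme level;
    columns (enzyme, direction, fc_exponent) feed
    :func:`cersim.perturb.fc_experiment` directly.
    """
    if n_up < 0 or n_down < 0 or n_up + n_down > len(enzymes):
        raise ValueError("need n_up + n_down <= number of enzymes")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(enzymes), size=n_up + n_down, replace=False)
    rows = []
    for i, ci in enumerate(chosen):
        rows.append(
            {
                "enzyme": enzymes[int(ci)],
                "direction": "up" if i < n_up else "down",
                "fc_exponent": float(rng.uniform(*exponent_range)),
            }
        )
    return pd.DataFrame(rows, columns=["enzyme", "direction", "fc_exponent"])
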