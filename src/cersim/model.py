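"""Data model for the extended C16:0 ceramide reaction network.

The network couples de novo synthesis (SPT -> dhSph -> dhCer -> Cer), the
salvage pathway (Cer -> Sph -> Cer re-acylation by CERS) and the
sphingomyelinase branch (SM <-> Cer), together with the glucosylceramide,
ceramide-1-phosphate and sphingosine-1-phosphate side branches.
Palmitoyl-CoA, DAG and PC enter as time-dependent *driver* species
represented by piecewise-linear interpolants of measured concentrations;
they multiply reaction fluxes but are never produced or consumed.

All kinetics are mass action.  Enzyme concentrations are folded into the
rate constants (kf = [E] * kf'), so an enzyme exists in the model purely as
a label grouping the reactions it mediates; scaling an enzyme means scaling
those rate constants.

Units: concentrations in pmol/ug DNA, time in hours, fluxes in
pmol/ug DNA/h.  The stochastic side works in molecule counts via
:class:`UnitConversion`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import yaml

__all__ = [
    "AVOGADRO",
    "ModelDefinitionError",
    "SpeciesSpec",
    "ReactionSpec",
    "ModelSpec",
    "UnitConversion",
    "assemble_reference_model",
    "evaluate_driver",
    "reaction_flux",
    "ode_rhs",
    "propensity",
]

AVOGADRO = 6.02214076e23


class ModelDefinitionError(ValueError):
    """Raised when a model definition violates its structural invariants."""


@dataclass(frozen=True)
class SpeciesSpec:
    """A chemical species: either a dynamic state variable or a driver.

    Dynamic species carry an initial concentration and obtain an ODE.
    Driver species carry an ordered list of ``(time_h, concentration)``
    knots and are evaluated by linear interpolation, clamped to the
    endpoint values outside the knot range.
    """

    name: str
    role: str  # "dynamic" | "driver"
    initial_value: float | None = None
    driver_knots: tuple[tuple[float, float], ...] | None = None

    def __post_init__(self) -> None:
        if self.role not in ("dynamic", "driver"):
            raise ModelDefinitionError(f"unknown role {self.role!r} for {self.name}")
        if self.role == "dynamic":
            if self.initial_value is None or self.driver_knots is not None:
                raise ModelDefinitionError(
                    f"dynamic species {self.name} must set initial_value only"
                )
            if self.initial_value < 0:
                raise ModelDefinitionError(f"negative initial value for {self.name}")
        else:
            if self.driver_knots is None or self.initial_value is not None:
                raise ModelDefinitionError(
                    f"driver species {self.name} must set driver_knots only"
                )
            knots = tuple((float(t), float(v)) for t, v in self.driver_knots)
            if len(knots) < 2:
                raise ModelDefinitionError(f"driver {self.name} needs >= 2 knots")
            times = [t for t, _ in knots]
            if any(b <= a for a, b in zip(times, times[1:])):
                raise ModelDefinitionError(
                    f"driver {self.name} knot times must be strictly increasing"
                )
            object.__setattr__(self, "driver_knots", knots)


def evaluate_driver(species: SpeciesSpec, t: float | np.ndarray) -> float | np.ndarray:
    """Piecewise-linear driver concentration at time ``t`` (hours).

    Exact at knots, linear between them, clamped to the endpoint values
    outside the knot range.
    """
    if species.role != "driver":
        raise ValueError(f"{species.name} is not a driver species")
    knots = np.asarray(species.driver_knots, dtype=float)
    out = np.interp(t, knots[:, 0], knots[:, 1])
    return float(out) if np.isscalar(t) or np.ndim(t) == 0 else out


@dataclass(frozen=True)
class ReactionSpec:
    """A mass-action reaction, possibly enzyme-labelled and driver-modified.

    ``reactants`` may be empty (production) and ``products`` may be empty
    (degradation).  Each driver in ``driver_modifiers`` multiplies the rate
    by its current concentration.
    """

    id: str
    reactants: Mapping[str, int] = field(default_factory=dict)
    products: Mapping[str, int] = field(default_factory=dict)
    enzyme: str | None = None
    driver_modifiers: tuple[str, ...] = ()
    rate_constant: float = 0.0

    def __post_init__(self) -> None:
        if self.rate_constant < 0:
            raise ModelDefinitionError(f"{self.id}: negative rate constant")
        for side in (self.reactants, self.products):
            for name, s in side.items():
                if not (isinstance(s, (int, np.integer)) and s > 0):
                    raise ModelDefinitionError(
                        f"{self.id}: stoichiometry of {name} must be a positive integer"
                    )
        object.__setattr__(self, "reactants", dict(self.reactants))
        object.__setattr__(self, "products", dict(self.products))
        object.__setattr__(self, "driver_modifiers", tuple(self.driver_modifiers))

    @property
    def order(self) -> int:
        """Total kinetic order: reactant stoichiometries plus driver count."""
        return sum(self.reactants.values()) + len(self.driver_modifiers)


@dataclass
class ModelSpec:
    """Full reaction-network description: species, reactions, enzyme map."""

    species: list[SpeciesSpec]
    reactions: list[ReactionSpec]
    enzymes: dict[str, list[str]] = field(default_factory=dict)

    # -- views -----------------------------------------------------------
    @property
    def dynamic_species(self) -> list[SpeciesSpec]:
        return [s for s in self.species if s.role == "dynamic"]

    @property
    def driver_species(self) -> list[SpeciesSpec]:
        return [s for s in self.species if s.role == "driver"]

    @property
    def dynamic_names(self) -> list[str]:
        return [s.name for s in self.dynamic_species]

    @property
    def driver_map(self) -> dict[str, SpeciesSpec]:
        return {s.name: s for s in self.driver_species}

    @property
    def initial_values(self) -> np.ndarray:
        return np.array([s.initial_value for s in self.dynamic_species], dtype=float)

    @property
    def rates(self) -> np.ndarray:
        return np.array([r.rate_constant for r in self.reactions], dtype=float)

    def reaction(self, rid: str) -> ReactionSpec:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise KeyError(rid)

    # -- derived models --------------------------------------------------
    def with_rates(self, rates: Sequence[float]) -> "ModelSpec":
        """A copy of the model with the rate-constant vector replaced."""
        rates = np.asarray(rates, dtype=float)
        if rates.shape != (len(self.reactions),):
            raise ValueError(
                f"expected {len(self.reactions)} rates, got {rates.shape}"
            )
        new_rxns = [
            replace(r, rate_constant=float(k)) for r, k in zip(self.reactions, rates)
        ]
        return ModelSpec(list(self.species), new_rxns, dict(self.enzymes))

    def with_initial_values(self, values: Mapping[str, float]) -> "ModelSpec":
        """A copy with the initial concentrations of some species replaced."""
        new_species = []
        for s in self.species:
            if s.name in values:
                if s.role != "dynamic":
                    raise ValueError(f"{s.name} is not a dynamic species")
                new_species.append(replace(s, initial_value=float(values[s.name])))
            else:
                new_species.append(s)
        return ModelSpec(new_species, list(self.reactions), dict(self.enzymes))

    # -- validation ------------------------------------------------------
    def validate(self) -> "ModelSpec":
        names = [s.name for s in self.species]
        if len(set(names)) != len(names):
            raise ModelDefinitionError("species names must be unique")
        rids = [r.id for r in self.reactions]
        if len(set(rids)) != len(rids):
            raise ModelDefinitionError("reaction ids must be unique")
        dyn = set(self.dynamic_names)
        drv = {s.name for s in self.driver_species}
        for r in self.reactions:
            for name in list(r.reactants) + list(r.products):
                if name not in dyn:
                    raise ModelDefinitionError(
                        f"{r.id}: {name} is not a declared dynamic species"
                    )
            for name in r.driver_modifiers:
                if name not in drv:
                    raise ModelDefinitionError(
                        f"{r.id}: {name} is not a declared driver species"
                    )
        rid_set = set(rids)
        mapped: set[str] = set()
        for enz, enz_rids in self.enzymes.items():
            if not enz_rids:
                raise ModelDefinitionError(f"enzyme {enz} mediates no reactions")
            for rid in enz_rids:
                if rid not in rid_set:
                    raise ModelDefinitionError(f"enzyme {enz}: unknown reaction {rid}")
                if self.reaction(rid).enzyme != enz:
                    raise ModelDefinitionError(
                        f"reaction {rid} does not carry enzyme label {enz}"
                    )
                mapped.add(rid)
        labelled = {r.id for r in self.reactions if r.enzyme is not None}
        if labelled != mapped:
            raise ModelDefinitionError(
                "enzyme map must cover exactly the enzyme-labelled reactions; "
                f"missing {sorted(labelled - mapped)}"
            )
        return self


@dataclass(frozen=True)
class UnitConversion:
    """Concentration (pmol/ug DNA) <-> molecule-count conversion.

    The conversion factor is ``avogadro * 1e-12 * 1e-6 / scaling_factor``:
    1e-12 converts pmol to mol, 1e-6 reflects the per-microgram-DNA
    normalization, and the scaling factor shrinks the effective system size
    so stochastic fluctuations become visible at a tractable number of
    molecules (1000 emphasises the noise; 1 approaches the deterministic
    limit).
    """

    avogadro: float = AVOGADRO
    scaling_factor: float = 1000.0

    def __post_init__(self) -> None:
        if self.scaling_factor <= 0:
            raise ValueError("scaling_factor must be positive")

    @property
    def factor(self) -> float:
        """Molecules per (pmol/ug DNA)."""
        return self.avogadro * 1e-12 * 1e-6 / self.scaling_factor

    def concentration_to_count(self, c):
        """Round-half-up conversion of concentration to a molecule count."""
        c = np.asarray(c, dtype=float)
        if np.any(c < 0):
            raise ValueError("negative concentration")
        counts = np.floor(c * self.factor + 0.5).astype(np.int64)
        return int(counts) if counts.ndim == 0 else counts

    def count_to_concentration(self, n):
        """Exact (unrounded) inverse of :meth:`concentration_to_count`."""
        n = np.asarray(n, dtype=float)
        if np.any(n < 0):
            raise ValueError("negative count")
        c = n / self.factor
        return float(c) if c.ndim == 0 else c


# ---------------------------------------------------------------------------
# rate laws


def reaction_flux(
    reaction: ReactionSpec,
    state: Mapping[str, float],
    t: float,
    drivers: Mapping[str, SpeciesSpec],
) -> float:
    """Mass-action flux of one reaction, in pmol/ug DNA/h.

    flux = k * prod(reactant_conc ** stoich) * prod(driver_value(t)).
    """
    f = reaction.rate_constant
    for name, s in reaction.reactants.items():
        c = state[name]
        if c < 0:
            raise ValueError(f"negative concentration for {name}")
        f *= c**s
    for name in reaction.driver_modifiers:
        f *= evaluate_driver(drivers[name], t)
    return f


def ode_rhs(model: ModelSpec, state: np.ndarray, t: float) -> np.ndarray:
    """Time derivative of the dynamic species, pmol/ug DNA/h.

    Drivers contribute to fluxes but have no derivative entry.
    """
    names = model.dynamic_names
    if len(state) != len(names):
        raise ValueError("state length must match the number of dynamic species")
    state_map = dict(zip(names, state))
    drivers = model.driver_map
    idx = {n: i for i, n in enumerate(names)}
    dxdt = np.zeros(len(names))
    for r in model.reactions:
        flux = reaction_flux(r, state_map, t, drivers)
        for name, s in r.reactants.items():
            dxdt[idx[name]] -= s * flux
        for name, s in r.products.items():
            dxdt[idx[name]] += s * flux
    return dxdt


def propensity(
    model: ModelSpec,
    counts: np.ndarray,
    t: float,
    conv: UnitConversion,
) -> np.ndarray:
    """Stochastic propensities (events/h) for every reaction.

    Stochastic rate constants follow from the deterministic ones by the
    mass-action order conversion c = kf / F**(order-1), where F is the
    molecules-per-concentration factor and the order counts reactant
    stoichiometry plus driver modifiers (drivers enter in count units, as
    interpolated molecule numbers).  First-order reactions keep kf
    unchanged.  Identical-reactant collisions use falling factorials.
    """
    counts = np.asarray(counts)
    if np.any(counts < 0):
        raise ValueError("negative molecule count")
    names = model.dynamic_names
    idx = {n: i for i, n in enumerate(names)}
    drivers = model.driver_map
    F = conv.factor
    a = np.empty(len(model.reactions))
    for j, r in enumerate(model.reactions):
        val = r.rate_constant / F ** (r.order - 1)
        for name, s in r.reactants.items():
            n = counts[idx[name]]
            for m in range(s):  # falling factorial n(n-1)...(n-s+1)
                val *= max(n - m, 0)
        for name in r.driver_modifiers:
            val *= evaluate_driver(drivers[name], t) * F
        a[j] = val
    return a


# ---------------------------------------------------------------------------
# packaged reference model


def model_from_dict(spec: dict) -> ModelSpec:
    """Build a :class:`ModelSpec` from the YAML/JSON dictionary layout."""
    try:
        species = [
            SpeciesSpec(
                name=s["name"],
                role=s["role"],
                initial_value=s.get("initial_value"),
                driver_knots=(
                    tuple((float(t), float(v)) for t, v in s["driver_knots"])
                    if s.get("driver_knots") is not None
                    else None
                ),
            )
            for s in spec["species"]
        ]
        reactions = [
            ReactionSpec(
                id=r["id"],
                reactants={k: int(v) for k, v in (r.get("reactants") or {}).items()},
                products={k: int(v) for k, v in (r.get("products") or {}).items()},
                enzyme=r.get("enzyme"),
                driver_modifiers=tuple(r.get("driver_modifiers") or ()),
                rate_constant=float(r["rate_constant"]),
            )
            for r in spec["reactions"]
        ]
        enzymes = {k: list(v) for k, v in (spec.get("enzymes") or {}).items()}
    except (KeyError, TypeError) as exc:
        raise ModelDefinitionError(f"malformed model definition: {exc}") from exc
    return ModelSpec(species, reactions, enzymes).validate()


def model_to_dict(model: ModelSpec) -> dict:
    """Inverse of :func:`model_from_dict`; plain-type dictionary layout."""
    species = []
    for s in model.species:
        d: dict = {"name": s.name, "role": s.role}
        if s.role == "dynamic":
            d["initial_value"] = float(s.initial_value)
        else:
            d["driver_knots"] = [[float(t), float(v)] for t, v in s.driver_knots]
        species.append(d)
    reactions = [
        {
            "id": r.id,
            "reactants": {k: int(v) for k, v in r.reactants.items()},
            "products": {k: int(v) for k, v in r.products.items()},
            "enzyme": r.enzyme,
            "driver_modifiers": list(r.driver_modifiers),
            "rate_constant": float(r.rate_constant),
        }
        for r in model.reactions
    ]
    return {
        "species": species,
        "reactions": reactions,
        "enzymes": {k: list(v) for k, v in model.enzymes.items()},
    }


def assemble_reference_model() -> ModelSpec:
    """Load and validate the packaged 29-reaction reference network.

    10 dynamic sphingolipids, 3 drivers (palmCoA, DAG, PC) and 29 reactions
    with free rate constants: 19 enzyme-mediated conversions plus one
    first-order clearance per dynamic species.
    """
    text = resources.files("cersim").joinpath("data/reference_model.yaml").read_text()
    try:
        spec = yaml.safe_load(text)
        return model_from_dict(spec)
    except yaml.YAMLError as exc:  # pragma: no cover - packaged file
        raise ModelDefinitionError(f"malformed packaged definition: {exc}") from exc
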