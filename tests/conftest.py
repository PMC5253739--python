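import numpy as np
import pytest
from hypothesis import settings

from cersim.model import ModelSpec, ReactionSpec, SpeciesSpec, assemble_reference_model

settings.register_profile("suite", deadline=None, max_examples=25, derandomize=True)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def reference_model() -> ModelSpec:
    return assemble_reference_model()


def make_decay_model(k: float = 0.5, a0: float = 10.0) -> ModelSpec:
    """Single species A with first-order clearance at rate k."""
    return ModelSpec(
        species=[SpeciesSpec("A", "dynamic", initial_value=a0)],
        reactions=[ReactionSpec("R1", reactants={"A": 1}, rate_constant=k)],
    ).validate()


def make_chain_model(
    k_in: float = 1.0, k_ab: float = 0.4, k_b_out: float = 0.3, a0: float = 2.0,
    b0: float = 1.0, enzyme_on_producer: str | None = None,
) -> ModelSpec:
    """Production -> A -> B -> clearance linear chain (closed-form linear ODE)."""
    enz = {}
    rxns = [
        ReactionSpec("Rin", products={"A": 1}, rate_constant=k_in),
        ReactionSpec(
            "Rab", reactants={"A": 1}, products={"B": 1},
            enzyme=enzyme_on_producer, rate_constant=k_ab,
        ),
        ReactionSpec("Rout", reactants={"B": 1}, rate_constant=k_b_out),
    ]
    if enzyme_on_producer:
        enz[enzyme_on_producer] = ["Rab"]
    return ModelSpec(
        species=[
            SpeciesSpec("A", "dynamic", initial_value=a0),
            SpeciesSpec("B", "dynamic", initial_value=b0),
        ],
        reactions=rxns,
        enzymes=enz,
    ).validate()


@pytest.fixture
def decay_model() -> ModelSpec:
    return make_decay_model()


@pytest.fixture
def chain_model() -> ModelSpec:
    return make_chain_model()
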