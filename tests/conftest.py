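import pytest

from cofactorflux.fixtures import FixtureConfig, generate_fixture
from cofactorflux.model_core import (
    DEFAULT_INF_BOUND,
    MetabolicModel,
    Reaction,
    Species,
)


def build_chain_model(cap: float = 1.0) -> MetabolicModel:
    """EX_A(<=cap) -> A -> B -> biomass sink; unit stoichiometry."""
    model = MetabolicModel(model_id="chain", compartments=["c"], objective="BIOMASS")
    for sid in ("A", "B"):
        model.add_species(Species(id=sid, compartment="c"))
    model.add_reaction(Reaction("EX_A", {"A": -1.0}, -cap, 0.0, is_exchange=True))
    model.add_reaction(Reaction("R_AB", {"A": -1.0, "B": 1.0}))
    model.add_reaction(Reaction("BIOMASS", {"B": -1.0}))
    return model


def build_parallel_model(demand: float = 1.0) -> MetabolicModel:
    """Two equivalent unit-capacity paths feeding a fixed demand."""
    model = MetabolicModel(model_id="parallel", compartments=["c"], objective="BIOMASS")
    for sid in ("A", "B"):
        model.add_species(Species(id=sid, compartment="c"))
    model.add_reaction(
        Reaction("EX_A", {"A": -1.0}, -DEFAULT_INF_BOUND, 0.0, is_exchange=True)
    )
    model.add_reaction(Reaction("P1", {"A": -1.0, "B": 1.0}, 0.0, 1.0))
    model.add_reaction(Reaction("P2", {"A": -1.0, "B": 1.0}, 0.0, 1.0))
    model.add_reaction(Reaction("BIOMASS", {"B": -1.0}, 0.0, demand))
    return model


def build_branched_model() -> MetabolicModel:
    """Small branched network with a non-trivial optimal mix.

    A (<=1) splits into B (yield 2 via R1, capacity 0.3) or C (yield 1
    via R2); both feed biomass. Rich enough that the optimum is a
    genuine vertex-selection problem for the enumeration oracle.
    """
    model = MetabolicModel(model_id="branched", compartments=["c"], objective="BIOMASS")
    for sid in ("A", "B"):
        model.add_species(Species(id=sid, compartment="c"))
    model.add_reaction(Reaction("EX_A", {"A": -1.0}, -1.0, 0.0, is_exchange=True))
    model.add_reaction(Reaction("R1", {"A": -1.0, "B": 2.0}, 0.0, 0.3))
    model.add_reaction(Reaction("R2", {"A": -1.0, "B": 1.0}, 0.0, DEFAULT_INF_BOUND))
    model.add_reaction(Reaction("BIOMASS", {"B": -1.0}))
    return model


@pytest.fixture(scope="session")
def default_fixture():
    return generate_fixture(FixtureConfig())


@pytest.fixture()
def fixture_model(default_fixture):
    model, _ = default_fixture
    return model.copy()


@pytest.fixture()
def fixture_bundle(default_fixture):
    _, bundle = default_fixture
    return bundle


@pytest.fixture()
def chain_model():
    return build_chain_model()


@pytest.fixture()
def parallel_model():
    return build_parallel_model()


@pytest.fixture()
def branched_model():
    return build_branched_model()
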