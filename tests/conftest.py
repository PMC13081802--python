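import numpy as np
import pytest

from lipoflux.constraints import ExpressionProfile, MediumTable
from lipoflux.gpr import parse_gpr
from lipoflux.network import MetabolicNetwork, MetaboliteRecord, ReactionRecord
from lipoflux.synth import PlantedEffect, ToyNetworkSpec, default_medium, make_toy_network


@pytest.fixture
def chain_network() -> MetabolicNetwork:
    """Uptake-limited linear chain: EX_A (lb=-10) -> A -> B -> biomass."""
    return MetabolicNetwork(
        metabolites=(
            MetaboliteRecord(id="A", compartment="e"),
            MetaboliteRecord(id="B", compartment="c"),
        ),
        reactions=(
            ReactionRecord(
                id="EX_A", stoichiometry={"A": -1.0}, lower_bound=-10.0,
                upper_bound=1000.0, is_exchange=True, subsystem="Exchange",
            ),
            ReactionRecord(
                id="R1", stoichiometry={"A": -1.0, "B": 1.0}, lower_bound=0.0,
                upper_bound=1000.0, gpr=parse_gpr("G1"), subsystem="chain",
            ),
            ReactionRecord(
                id="biomass", stoichiometry={"B": -1.0}, lower_bound=0.0,
                upper_bound=1000.0, subsystem="Biomass",
            ),
        ),
        objective_id="biomass",
        name="chain",
    )


@pytest.fixture
def toy_network() -> MetabolicNetwork:
    return make_toy_network(ToyNetworkSpec(n_subsystems=3, reactions_per_subsystem=2, seed=7))


@pytest.fixture
def toy_medium(toy_network) -> MediumTable:
    return default_medium(toy_network)


@pytest.fixture
def flat_profile(toy_network) -> ExpressionProfile:
    return ExpressionProfile(
        condition="UCM", replicate="R1",
        values={g: 1.0 for g in toy_network.genes()},
    )


def random_toy_network(rng: np.random.Generator):
    """A randomized small toy network (used by oracle-equivalence tests)."""
    spec = ToyNetworkSpec(
        n_subsystems=int(rng.integers(1, 4)),
        reactions_per_subsystem=int(rng.integers(1, 4)),
        kcat_range=(1.0, 5.0),
        dgp_fraction=float(rng.uniform(0, 1)),
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    return make_toy_network(spec)
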