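import numpy as np
import pytest

from rxnpaths import make_fixture
from rxnpaths.model import ReactionSystem
from rxnpaths.paths import Path, PathChain


@pytest.fixture(scope="session")
def bd0():
    """Birth-death, x0=0, cb=1.0, cd=0.1."""
    return make_fixture("bd_x0_0")


@pytest.fixture(scope="session")
def bd2():
    """Birth-death, x0=2, cb=1.0, cd=0.1."""
    return make_fixture("bd_x0_2")


@pytest.fixture(scope="session")
def pure_birth():
    return make_fixture("pure_birth")


@pytest.fixture(scope="session")
def death_only():
    """Single death reaction starting from an empty population: the origin
    is absorbing (zero propensity everywhere)."""
    system = ReactionSystem(
        species_names=("X",),
        reaction_names=("death",),
        reactant_stoich=np.array([[1]]),
        product_stoich=np.array([[0]]),
        rate_constants=np.array([0.5]),
    )
    return system, (0,)


@pytest.fixture(scope="session")
def example_chain(bd2):
    """The worked 5-state birth-death chain (0,0)->(1,0)->(1,1)->(1,2)->(1,3)."""
    system, x0 = bd2
    path = Path(
        states=((0, 0), (1, 0), (1, 1), (1, 2), (1, 3)),
        reaction_sequence=(0, 1, 1, 1),
    )
    return PathChain.from_path(system, x0, path, C=1.0)


def random_chain(rng: np.random.Generator, m: int) -> PathChain:
    """A structurally valid chain with random rates (for property tests):
    exit rates in (0.1, 3), along-chain rates a random fraction of each."""
    alphas = rng.uniform(0.1, 3.0, size=m)
    betas = rng.uniform(0.05, 1.0, size=m - 1) * alphas[:-1]
    states = tuple((i,) for i in range(m))
    return PathChain(
        path=Path(states, (0,) * (m - 1)),
        C=1.0,
        alphas=tuple(alphas),
        betas=tuple(betas),
    )
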