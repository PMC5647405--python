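"""Shared fixtures: toy webs, balanced solutions, and one synthetic study.

Session scope is used for everything expensive (balancing, the synthetic
forward run) so the suite pays for each at most once.
"""

import numpy as np
import pytest

from trophicast.dynamics import SimOptions, calibrate_arena, vulnerability_matrix
from trophicast.foodweb import FoodWebModel, Group, balance_model
from trophicast.synthetic import SyntheticSpec, make_observations


def make_toy2() -> FoodWebModel:
    """The two-group hand-example web: producer plus one fished consumer."""
    groups = [
        Group("producer", is_producer=True, biomass=10, pb=10),
        Group("consumer", biomass=1, pb=1, qb=5, catch=0.5),
    ]
    diet = np.zeros((2, 2))
    diet[0, 1] = 1.0
    return FoodWebModel(groups=groups, diet=diet)


@pytest.fixture(scope="session")
def toy2():
    return make_toy2()


@pytest.fixture(scope="session")
def toy2_sol(toy2):
    return balance_model(toy2)


@pytest.fixture(scope="session")
def web3_sol():
    spec = SyntheticSpec(n_groups=3)
    from trophicast.synthetic import make_web

    return balance_model(make_web(spec))


@pytest.fixture(scope="session")
def web6():
    from trophicast.synthetic import make_web

    return make_web(SyntheticSpec(n_groups=6))


@pytest.fixture(scope="session")
def web6_sol(web6):
    return balance_model(web6)


@pytest.fixture(scope="session")
def web12_sol():
    from trophicast.synthetic import make_web

    return balance_model(make_web(SyntheticSpec(n_groups=12)))


@pytest.fixture(scope="session")
def options():
    return SimOptions()


@pytest.fixture(scope="session")
def web6_arena(web6_sol):
    return calibrate_arena(web6_sol, vulnerability_matrix(web6_sol.model))


@pytest.fixture(scope="session")
def synthetic_study():
    """One seeded synthetic study shared across tests: (observed, truth)."""
    spec = SyntheticSpec(seed=0)
    return make_observations(spec)


@pytest.fixture(scope="session")
def noise_free_study():
    spec = SyntheticSpec(seed=0, noise_cv=0.0)
    return make_observations(spec)
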