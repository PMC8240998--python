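import numpy as np
import pytest

from hivncd import FixtureSpec, make_parameter_set
from hivncd.population import Population
from hivncd.rates import FEMALE, MALE


@pytest.fixture(scope="session")
def small_spec():
    return FixtureSpec(seed=7, n_agents=3000)


@pytest.fixture(scope="session")
def small_params(small_spec):
    return make_parameter_set(small_spec)


def make_adult_cohort(n, age=30.0, sex=None, t0=2000.0, seed=0):
    """A closed cohort of alive, disease-free adults at time t0."""
    rng = np.random.default_rng(seed)
    pop = Population(n)
    sexes = (np.full(n, sex, dtype=np.int8) if sex is not None
             else (rng.random(n) < 0.5).astype(np.int8))
    pop.add_agents(sexes, np.full(n, t0 - age))
    return pop
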