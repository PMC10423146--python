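import numpy as np
import pytest

from esme import environment as envmod
from esme import model_zoo
from esme.crn_model import LinearSubsystem, ModulatedCRN, RateStructure


@pytest.fixture(scope="session")
def homogeneous_bd():
    """Birth-death process with lambda=10, mu=1 in a trivial one-state
    environment (stationary mean 10)."""
    env = envmod.explicit_environment([0], [[0.0]])
    sub = LinearSubsystem(["X"], S=[[0, 1]], P=[[1, 0]])
    rates = RateStructure(Gamma=lambda z: [[0.0], [1.0]],
                          gamma=lambda z: [10.0, 0.0], states=env.states)
    return ModulatedCRN(sub, rates, env)


@pytest.fixture(scope="session")
def e1_mid():
    """Telegraph death modulation at matched time scales (ratio 1)."""
    return model_zoo.make_e1(qss_mean=10.0, p_off=0.5, ratio=1.0)


@pytest.fixture(scope="session")
def e2_small():
    """Birth-death death modulation with a coarse truncation (small |Z|)
    for cheap exhaustive checks."""
    return model_zoo.make_e2(qss_mean=10.0, env_mean=4.0, ratio=1.0,
                             tail_mass=1e-8)


@pytest.fixture(scope="session")
def birth_modulated():
    """Zeroth-order-only modulation: the birth rate varies with the
    environment while the death rate is constant, so the heterogeneous
    mean must coincide with the Q.SS mean."""
    env = envmod.telegraph(rate_on=2.0, rate_off=3.0)
    sub = LinearSubsystem(["X"], S=[[0, 1]], P=[[1, 0]])
    rates = RateStructure(Gamma=lambda z: [[0.0], [0.7]],
                          gamma=lambda z: [4.0 + 6.0 * z, 0.0],
                          states=env.states)
    return ModulatedCRN(sub, rates, env)


def random_scalar_model(rng: np.random.Generator) -> ModulatedCRN:
    """Random stable scalar birth-death subsystem over a random irreducible
    environment (3-6 states, dense positive generator)."""
    n = int(rng.integers(3, 7))
    G = rng.uniform(0.1, 3.0, size=(n, n))
    np.fill_diagonal(G, 0.0)
    Lam = G.copy()
    np.fill_diagonal(Lam, -Lam.sum(axis=0))
    env = envmod.explicit_environment(list(range(n)), Lam)
    births = rng.uniform(0.5, 20.0, size=n)
    deaths = rng.uniform(0.05, 4.0, size=n)
    sub = LinearSubsystem(["X"], S=[[0, 1]], P=[[1, 0]])
    rates = RateStructure(
        Gamma={z: np.array([[0.0], [deaths[k]]])
               for k, z in enumerate(env.states)},
        gamma={z: np.array([births[k], 0.0])
               for k, z in enumerate(env.states)},
        states=env.states,
    )
    return ModulatedCRN(sub, rates, env)
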