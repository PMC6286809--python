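import numpy as np
import pytest
from hypothesis import settings

import lyapnet as ln
from lyapnet.ga import GAConfig

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def toy5():
    """Seeded sparse stable 5-node linear model with known Jacobian."""
    return ln.make_toy_network(5, seed=3)


@pytest.fixture(scope="session")
def exact_system5(toy5):
    """Exact covariance system for the 5-node toy with D = 0.005·I."""
    J = toy5.parameters["J"]
    D = np.full(5, 0.005)
    C = ln.forward_solve_covariance(J, D)
    return ln.vectorize_lyapunov(C, D), J, D


@pytest.fixture(scope="session")
def glycolysis():
    return ln.yeast_glycolysis_synthetic()


@pytest.fixture
def small_cfg():
    """A fast GA configuration for unit tests."""
    return GAConfig(
        population_size=40,
        max_generations=40,
        lambda_grid=(0.05,),
        repeats_per_lambda=1,
        rng_seed=0,
    )


def random_stable_system(n, rng, density=0.3):
    """Random Hurwitz J via diagonal dominance, plus positive D."""
    J = np.zeros((n, n))
    off = [(i, j) for i in range(n) for j in range(n) if i != j]
    k = max(1, int(density * len(off)))
    for idx in rng.choice(len(off), size=k, replace=False):
        i, j = off[idx]
        J[i, j] = rng.uniform(-1.5, 1.5)
    J[np.diag_indices(n)] = -(np.abs(J).sum(axis=1) + rng.uniform(0.5, 1.5, n))
    D = rng.uniform(0.1, 1.0, n)
    return J, D
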