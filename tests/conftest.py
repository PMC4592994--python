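import numpy as np
import pytest

from pgordinal.model_core import OrdinalDataset, PriorSpec
from pgordinal.simulate import BETA_TRUE, GAMMA_TRUE


def make_sim_dataset(seed=0, I=40, n_i=5, beta=BETA_TRUE, gamma=GAMMA_TRUE):
    """Hand-rolled draw from the simulation design (independent of the
    simulate module, so it can serve as its oracle)."""
    rng = np.random.default_rng(seed)
    x = rng.uniform(-0.1, 0.1, size=(I, beta.size))
    X = np.repeat(x, n_i, axis=0)
    l = X @ beta + rng.logistic(0, 1, I * n_i)
    y = 1 + np.searchsorted(gamma, l)
    line_of = np.repeat(np.arange(I), n_i)
    return OrdinalDataset(y, X, line_of, C=gamma.size + 1)


@pytest.fixture(scope="session")
def sim_dataset():
    """One n=200 replicate of the logistic simulation design."""
    return make_sim_dataset(seed=20)


@pytest.fixture(scope="session")
def sim_priors():
    return PriorSpec(beta0=0.0, sigma0=10000.0, fix_sigma_beta=True,
                     gamma_min=-4.0, gamma_max=4.0)


@pytest.fixture(scope="session")
def small_dataset():
    """30 observations, 2 covariates, 3 categories; every line its own obs."""
    rng = np.random.default_rng(7)
    X = rng.normal(0, 1, size=(30, 2))
    l = X @ np.array([0.8, -0.5]) + rng.logistic(0, 1, 30)
    y = 1 + np.searchsorted([-0.5, 0.7], l)
    # ensure all categories appear
    y[:3] = [1, 2, 3]
    return OrdinalDataset(y, X, C=3)
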