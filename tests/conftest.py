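import numpy as np
import pytest

from kmrmix.data import MixtureDataset, standardize_exposures
from kmrmix.mcmc import McmcControl, run_mcmc
from kmrmix.simulate import GenerativeSpec, simulate_continuous


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def fit_dataset(data, n_iter=400, seed=5, **ctrl_kwargs):
    """Standardize and fit; shared helper for small end-to-end fixtures."""
    Zs, centers, scales = standardize_exposures(data.Z)
    d2 = MixtureDataset(
        y=data.y, Z=Zs, X=data.X, cluster_id=data.cluster_id,
        family=data.family, exposure_names=data.exposure_names,
        covariate_names=data.covariate_names,
    )
    control = McmcControl(n_iter=n_iter, seed=seed, **ctrl_kwargs)
    return run_mcmc(d2, control=control, centers=centers, scales=scales)


@pytest.fixture(scope="session")
def linear_fixture():
    """Small dataset whose truth is additive: h = 1.2*z1 - 0.8*z2, z3 inert."""
    spec = GenerativeSpec(
        n=150, M=3, seed=42,
        terms=(("linear", 0, 1.2), ("linear", 1, -0.8)),
        beta_x=0.5, noise_sd=0.5,
    )
    return simulate_continuous(spec)


@pytest.fixture(scope="session")
def linear_fit(linear_fixture):
    """Posterior for the additive fixture (shared across summary tests)."""
    data, _ = linear_fixture
    return fit_dataset(data, n_iter=800, seed=9)
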