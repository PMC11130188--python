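import numpy as np
import pytest

from sanfilippopred import GibbsConfig, default_priors, run_gibbs
from sanfilippopred.synthetic import GeneratorSpec, generate_mixture_dataset

# short chain reused by everything that just needs "a fitted posterior";
# dedicated convergence checks configure their own chains
SHORT_CHAIN = dict(n_iter=1200, burn_in=400, thin=2)


@pytest.fixture(scope="session")
def default_spec():
    return GeneratorSpec(n=415, seed=7)


@pytest.fixture(scope="session")
def synth_data(default_spec):
    """(Dataset, raw unclipped matrix) at the default study-like spec."""
    return generate_mixture_dataset(default_spec)


@pytest.fixture(scope="session")
def fitted_draws(synth_data):
    """Posterior draws fitted to the default synthetic table."""
    ds, _ = synth_data
    cfg = GibbsConfig(seed=11, **SHORT_CHAIN)
    return run_gibbs(ds.X, default_priors(ds.X), cfg, features=ds.features)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
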