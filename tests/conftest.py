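import numpy as np
import pandas as pd
import pytest

from circmeth.simulate import SimConfig, simulate_bundle


@pytest.fixture(scope="session")
def default_bundle():
    """One default synthetic bundle shared across read-only tests."""
    return simulate_bundle(SimConfig(seed=11))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def nb_counts(rng, n_features, n_samples, mu_range=(20, 1000), alpha=0.1, lfc=None, condition=None):
    """Plain NB count matrix generator used as test scaffolding."""
    mu = np.exp(rng.uniform(np.log(mu_range[0]), np.log(mu_range[1]), n_features))
    mean = np.tile(mu[:, None], (1, n_samples))
    if lfc is not None and condition is not None:
        mean = mu[:, None] * 2.0 ** (np.asarray(lfc)[:, None] * np.asarray(condition)[None, :])
    r = 1.0 / alpha
    counts = rng.negative_binomial(r, r / (r + mean))
    return pd.DataFrame(counts)
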