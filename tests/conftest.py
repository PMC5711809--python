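import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import mstbayes as mb

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def fast_mcmc():
    """Reduced sampler size for unit tests; plenty for a stable median."""
    return mb.McmcConfig(n_iterations=1000, n_tune=400, rng_seed=0)


@pytest.fixture(scope="session")
def clean_params():
    """Noise-free, error-free generator: every response on the true curve."""
    return mb.TestCaseParams(
        kd_true=500.0, b_true=780.0, u_true=800.0,
        noise_sd=0.0, pipette_cov=0.0, outlier_fraction=0.0, repeats=3, rng_seed=11,
    )


@pytest.fixture(scope="session")
def clean_dataset(clean_params):
    return mb.generate_dataset(clean_params)


@pytest.fixture(scope="session")
def case2_dataset():
    return mb.generate_dataset(mb.TABLE_CASES[1])


@pytest.fixture(scope="session")
def clean_posterior(clean_dataset, fast_mcmc):
    return mb.fit_bayes(clean_dataset, mcmc=fast_mcmc)


@pytest.fixture(scope="session")
def case2_posterior(case2_dataset, fast_mcmc):
    return mb.fit_bayes(case2_dataset, mcmc=fast_mcmc)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
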