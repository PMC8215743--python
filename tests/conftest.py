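import numpy as np
import pytest

from icumort.pipeline import prepare_table
from icumort.registry import RegistryConfig, generate_registry


@pytest.fixture(scope="session")
def small_cohort():
    """A modest default-structure cohort shared across tests (fixed seed)."""
    table, truth = generate_registry(RegistryConfig(n_patients=4000, n_sites=40, seed=20))
    return prepare_table(table), truth


@pytest.fixture(scope="session")
def exogenous_cohort():
    """A cohort with no error correlations and no site effects: every
    single-equation estimator is correctly specified on it."""
    cfg = RegistryConfig(n_patients=4000, n_sites=40, seed=21,
                         corr_vm=0.0, corr_hm=0.0, corr_vh=0.0, site_sd=0.0)
    table, truth = generate_registry(cfg)
    return prepare_table(table), truth


def make_logistic_data(n, beta=(0.0, 0.5), seed=0, k=1):
    """Simple logistic-model data: x ~ N(0,1), logit P(y=1) = b0 + x'b."""
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, k))
    eta = beta[0] + X @ np.asarray(beta[1:])
    p = 1.0 / (1.0 + np.exp(-eta))
    y = (rng.random(n) < p).astype(float)
    return X, y, p
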