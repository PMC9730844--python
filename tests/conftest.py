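import numpy as np
import pandas as pd
import pytest

from streamscreen import synthetic_data
from streamscreen.synthetic_data import ScenarioConfig


@pytest.fixture(scope="session")
def default_cohort():
    """One full cohort under the default study conditions."""
    return synthetic_data.simulate_cohort(seed=11)


@pytest.fixture(scope="session")
def small_cohort():
    """Reduced cohort for fast per-module tests."""
    cfg = ScenarioConfig(n_sites=12, n_suspects_per_cluster=4,
                         n_nontarget_per_cluster=2, n_background=40)
    return synthetic_data.simulate_cohort(cfg, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(123)


@pytest.fixture(scope="session")
def attribute_frame():
    """Deterministic 20-site attribute table."""
    sites = synthetic_data.generate_sites(20, seed=5)
    return synthetic_data.sites_frame(sites)
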