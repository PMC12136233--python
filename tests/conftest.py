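import numpy as np
import pytest

from gxeqtl import simgen


@pytest.fixture(scope="session")
def small_config():
    return simgen.SimConfig(n_donors=30, n_genes=20, n_snps_per_gene=5,
                            cells_per_donor_context=10, seed=11)


@pytest.fixture(scope="session")
def small_data(small_config):
    return simgen.simulate_all(small_config)


@pytest.fixture(scope="session")
def panel(small_data):
    return small_data["panel"]


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
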