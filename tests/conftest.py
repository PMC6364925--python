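import logging

import numpy as np
import pytest

from grsage.simulate import SimulationConfig, simulate_cohort, simulate_truth

logging.getLogger("grsage").setLevel(logging.ERROR)
logging.getLogger("grsage.genotype_io").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(n_subjects=300, seed=42)


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory, small_config):
    """A clean (artifact-free) simulated file bundle shared across tests."""
    outdir = tmp_path_factory.mktemp("bundle")
    paths = simulate_cohort(small_config, outdir)
    return paths


@pytest.fixture(scope="session")
def small_truth(small_config):
    return simulate_truth(small_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
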