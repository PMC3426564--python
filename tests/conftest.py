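import numpy as np
import pytest

from gapcircuit.model import NucleusGrid
from gapcircuit.simulate import initial_state_from_hb, run_pair
from gapcircuit.synthetic import default_ground_truth, simulate_dataset


@pytest.fixture(scope="session")
def truth():
    return default_ground_truth()


@pytest.fixture(scope="session")
def clean_dataset(truth):
    """Noise-free two-genotype dataset generated from the fixture circuit."""
    return simulate_dataset(truth, noise=None)


@pytest.fixture(scope="session")
def grid13():
    return NucleusGrid.c13()


@pytest.fixture(scope="session")
def truth_init(truth, grid13):
    return initial_state_from_hb(truth.hb_c12_positions,
                                 truth.hb_c12_levels, grid13)


@pytest.fixture(scope="session")
def truth_pair(truth, truth_init, grid13):
    """Reference wild-type and Kr-null trajectories of the fixture."""
    return run_pair(truth.params, truth.external, truth_init, grid=grid13)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
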