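import numpy as np
import pytest
from hypothesis import settings

import hybridtox as ht

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def worked_examples():
    return ht.generate_worked_examples()


@pytest.fixture(scope="session")
def small_dataset():
    """A compact synthetic study shared by the slower integration tests."""
    return ht.generate_dataset(ht.SimulationConfig(n_compounds=200, seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def make_profile(responses, compound_id="C1", cell_line="Jurkat"):
    grid = ht.default_concentration_grid(len(responses))
    return ht.ConcentrationResponseProfile(compound_id, cell_line, tuple(grid), tuple(responses))
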