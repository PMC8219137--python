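import numpy as np
import pytest

import mandimorph as mm


@pytest.fixture(scope="session")
def template():
    return mm.make_template()


@pytest.fixture(scope="session")
def default_dataset():
    """One paper-design synthetic dataset (n=160) shared across tests."""
    return mm.simulate_dataset(mm.SimulationSpec(seed=314159))


@pytest.fixture(scope="session")
def default_fit(default_dataset):
    return mm.gpa(default_dataset)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260101)


def random_config(rng, specimen_id="s", scale=0.05):
    coords = mm.make_template().coords + scale * rng.standard_normal((14, 3))
    return mm.LandmarkConfiguration(specimen_id, coords)
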