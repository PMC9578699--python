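import numpy as np
import pytest

from bdtask import AgentSpec, DESIGNS, Environment, NoiseSpec, generate_dataset


@pytest.fixture(scope="session")
def poor():
    return Environment.from_label("poor")


@pytest.fixture(scope="session")
def neutral():
    return Environment.from_label("neutral")


@pytest.fixture(scope="session")
def rich():
    return Environment.from_label("rich")


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture(scope="session")
def small_dataset():
    """Two simulated participants on the narrow between-subject design."""
    spec = AgentSpec(w=0.75, noise=NoiseSpec("binomial", p=0.9))
    records, truth = generate_dataset(
        DESIGNS["B10"], 2, spec, seed=11, envs=["neutral"]
    )
    return records, truth
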