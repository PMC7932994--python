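import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from tcrtrack.model import CloneCountTable, CloneKey, SampleMeta
from tcrtrack.simulate import SimConfig, simulate_experiment, toy_reference


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """Scaled-down study conditions for fast unit tests."""
    return SimConfig(n_clones=200, depth=3000, seed=1)


@pytest.fixture(scope="session")
def small_experiment(small_config):
    return simulate_experiment(small_config)


@pytest.fixture(scope="session")
def toy_refs():
    return toy_reference()


@pytest.fixture()
def tiny_table() -> CloneCountTable:
    """3 clones x 2 samples with library sizes (8, 10)."""
    return CloneCountTable(
        clones=[CloneKey("CASSF"), CloneKey("CAWSF"), CloneKey("CGGGF")],
        samples=[SampleMeta("s1", 0, 1), SampleMeta("s2", 0, 2)],
        counts=np.array([[5, 0], [3, 3], [0, 7]]),
    )
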