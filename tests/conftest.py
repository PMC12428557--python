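import numpy as np
import pytest

from splicedown.duplex import default_energy_model
from splicedown.intervals import GenomeSource
from splicedown.simulate import SyntheticConfig, make_dataset


@pytest.fixture(scope="session")
def model():
    return default_energy_model()


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory):
    """Small deterministic synthetic dataset shared across tests."""
    cfg = SyntheticConfig(
        seed=11,
        events_per_class={"SE": 8, "MXE": 4, "RI": 6, "A3SS": 4, "A5SS": 4},
        intron_size_range=(80, 1500),
    )
    return make_dataset(cfg, tmp_path_factory.mktemp("bundle"))


@pytest.fixture(scope="session")
def small_genome(small_bundle):
    return GenomeSource(small_bundle.paths["genome"])


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
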