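import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("default", deadline=None, derandomize=True)
settings.load_profile("default")

from dpsir_eri import SyntheticConfig, default_hierarchy, write_dataset


@pytest.fixture(scope="session")
def h():
    return default_hierarchy()


@pytest.fixture(scope="session")
def dataset(tmp_path_factory):
    """One seeded synthetic dataset on disk, shared across tests."""
    out = tmp_path_factory.mktemp("data")
    cfg = SyntheticConfig(seed=42)
    paths = write_dataset(cfg, out)
    return cfg, paths


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)
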