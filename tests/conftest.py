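import numpy as np
import pytest

from simnet.config import NetworkConfig


@pytest.fixture
def cfg() -> NetworkConfig:
    """Full-size anatomical configuration."""
    return NetworkConfig()


@pytest.fixture
def small_cfg() -> NetworkConfig:
    """Scaled-down but geometry-consistent network for fast unit tests."""
    return NetworkConfig(
        n_microstrips=9,
        fields_per_microstrip=20,
        microzone_length_um=4000.0,
        sectors_per_microzone=20,
        mf_per_field=40,
        terminals_per_field=150,
        granule_per_field=400,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
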