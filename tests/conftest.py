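import numpy as np
import pytest

from fcdlif import (
    canonical_schedule,
    default_phantom_spec,
    generate_phantom,
)
from fcdlif.network import Network, NetworkConfig


@pytest.fixture(scope="session")
def schedule():
    return canonical_schedule()


@pytest.fixture(scope="session")
def noiseless_phantom():
    """One reduced-grid noiseless phantom shared across tests."""
    spec = default_phantom_spec()
    image, aif, masks = generate_phantom(spec, seed=11)
    return image, aif, masks


@pytest.fixture(scope="session")
def tiny_network():
    """A small but structurally complete network for fast structural tests."""
    config = NetworkConfig(
        sfe_channels=(4, 3), tfe_channels=(5,), tfe_kernel=3, input_shape=(16, 8, 8)
    )
    return Network(config, seed=3)


@pytest.fixture(scope="session")
def reduced_network():
    """Untrained seeded network at the reduced phantom scale."""
    from fcdlif import reduced_config

    return Network(reduced_config(), seed=0)
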