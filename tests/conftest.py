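import numpy as np
import pytest

from hemisim.network import BilateralNetwork, NetworkConfig
from hemisim.scene import SceneConfig, build_dataset, sample_target_grid


@pytest.fixture(scope="session")
def tiny_scene():
    """Small scene config used by unit tests (fast to render)."""
    return SceneConfig(resolution=16)


@pytest.fixture(scope="session")
def tiny_net_config():
    """Very small bilateral architecture for gradient and wiring tests."""
    return NetworkConfig(
        resolution=8, conv_maps=(1, 2, 2, 2, 1), fc_nodes=(7, 5, 6), batch_size=4, l2=1e-3
    )


@pytest.fixture()
def tiny_net(tiny_net_config):
    return BilateralNetwork(tiny_net_config, seed=3)


@pytest.fixture(scope="session")
def tiny_dataset(tiny_scene):
    """A rendered dataset of 6 positions x 2 variants x 4 HSP modes."""
    positions = sample_target_grid(6, seed=11)
    return build_dataset(positions, n_variants=2, config=tiny_scene)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
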