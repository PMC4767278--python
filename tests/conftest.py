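import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from wcresonance import (
    ConnectivityConfig,
    LatticeSpec,
    SubnetworkMask,
    UnitParams,
    build_network,
)


@pytest.fixture(scope="session")
def default_params() -> UnitParams:
    return UnitParams()


@pytest.fixture(scope="session")
def tiny_network():
    """3x3 delayed network, small enough for brute-force oracles."""
    spec = LatticeSpec(side=3, macrocolumn_side=2)
    cfg = ConnectivityConfig(k_exc=2, k_inh=2, long_range_fraction=0.0, seed=11)
    return build_network(spec, cfg, delay_per_step=3.0)


@pytest.fixture(scope="session")
def tiny_mask(tiny_network):
    return SubnetworkMask.centred_square(tiny_network.spec, 2)


@pytest.fixture(scope="session")
def medium_network():
    """30x30 network at the default operating point (delay 10/unit)."""
    spec = LatticeSpec(side=30)
    return build_network(spec, ConnectivityConfig(seed=7), delay_per_step=10.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
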