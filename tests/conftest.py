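import numpy as np
import pytest

from arcflux import (
    CultureParams,
    ToyNetworkOptions,
    make_core_network,
)


@pytest.fixture(scope="session")
def toy():
    """Default xylose core network."""
    return make_core_network()


@pytest.fixture(scope="session")
def toy_glucose():
    return make_core_network(ToyNetworkOptions(carbon_source="glucose"))


@pytest.fixture(scope="session")
def params():
    return CultureParams()


@pytest.fixture(scope="session")
def coarse_axes():
    """Small matched grid used across phase-plane tests."""
    return np.linspace(0.0, 10.0, 11), np.linspace(0.0, 12.0, 13)


@pytest.fixture(scope="session")
def toy_grid(toy, coarse_axes):
    from arcflux import compute_phpp

    carbon_axis, o2_axis = coarse_axes
    return compute_phpp(toy, "EX_xyl", "EX_o2", carbon_axis, o2_axis)


@pytest.fixture(scope="session")
def glucose_grid(toy_glucose, coarse_axes):
    from arcflux import compute_phpp

    carbon_axis, o2_axis = coarse_axes
    return compute_phpp(toy_glucose, "EX_glc", "EX_o2", carbon_axis, o2_axis)
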