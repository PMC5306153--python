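import pytest

from spinemk import fixtures
from spinemk.model_core import Component


@pytest.fixture(scope="session")
def lif_component() -> Component:
    return fixtures.lif_component()


@pytest.fixture(scope="session")
def lif_properties() -> dict:
    return {"tau_m": 25.0, "R": 1.0, "theta": 1.0, "v_reset": 0.0,
            "t_ref": 2.0, "I_offset": 0.0}


@pytest.fixture()
def selection_project():
    return fixtures.build_selection_network()


@pytest.fixture(scope="session")
def small_selection_project():
    """Two-channel variant, cheap enough for repeated simulation."""
    return fixtures.build_selection_network(
        fixtures.SelectionNetworkConfig(n_channels=2))
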