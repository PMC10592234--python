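import numpy as np
import pytest

from m1circuit import default_config
from m1circuit.cells import make_template


@pytest.fixture(scope="session")
def cfg():
    return default_config()


@pytest.fixture(scope="session")
def pt_template(cfg):
    return make_template("PT5B", cfg)


@pytest.fixture(scope="session")
def it_deep_template(cfg):
    return make_template("IT5B", cfg)


@pytest.fixture(scope="session")
def small_network():
    """A small (8% density) but complete fixture network, built once."""
    from m1circuit.scenarios import build_fixture_network

    return build_fixture_network(scale=0.08, seed=7)


def passive_template(n_comp=1, leak=5e-5):
    """A purely passive test cell (no voltage-gated channels)."""
    from m1circuit.cells import CellTemplate, Compartment

    bio = {
        "ra_ohm_cm": 120.0, "cm_uf_cm2": 1.0, "e_na_mv": 55.0, "e_k_mv": -90.0,
        "e_ca_mv": 120.0, "e_h_mv": -30.0, "e_leak_mv": -70.0,
    }
    comps = [Compartment(0, -1, "soma", "soma", 20.0, 20.0)]
    if n_comp > 1:
        comps.append(Compartment(1, 0, "dend", "apical_trunk", 150.0, 2.0))
    gbar = {ch: np.zeros(n_comp) for ch in
            ("leak", "Na", "Kdr", "Ka", "Kd", "HCN", "CaL", "CaN", "KCa")}
    gbar["leak"][:] = leak
    return CellTemplate("IT5B", "passive_test", tuple(comps), gbar, bio, (0.0, 0.0))
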