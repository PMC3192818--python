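import numpy as np
import pytest

import cmenoise as cn


@pytest.fixture(scope="session")
def toggle_set1():
    """Asymmetric toggle switch (r_u=10, r_v=9) with its direct solution."""
    network, space = cn.load_builtin_model("toggle_table1_set1")
    dist = cn.solve_steady_state(cn.build_generator(network, space), space)
    return network, space, dist


@pytest.fixture(scope="session")
def toggle_set2():
    network, space = cn.load_builtin_model("toggle_table1_set2")
    dist = cn.solve_steady_state(cn.build_generator(network, space), space)
    return network, space, dist


@pytest.fixture(scope="session")
def toggle_symmetric():
    """Fully symmetric toggle (r_u=r_v=10)."""
    network, space = cn.load_builtin_model("toggle_fig4b")
    dist = cn.solve_steady_state(cn.build_generator(network, space), space)
    return network, space, dist


@pytest.fixture(scope="session")
def t7_solutions():
    """Direct solutions of the three T7 circuit conditions."""
    out = {}
    for name in ("t7_base", "t7_mu013", "t7_iptg100"):
        network, space = cn.load_builtin_model(name)
        out[name] = (network, space, cn.solve_steady_state(cn.build_generator(network, space), space))
    return out


@pytest.fixture(scope="session")
def product_birth_death():
    """Two independent birth-death species: product-form steady state, so
    the per-species detailed-balance conditional is exact."""
    network = cn.ReactionNetwork(
        species=["u", "v"],
        reactions=[
            cn.Reaction("synth_u", "k_su", change=np.array([1, 0])),
            cn.Reaction("deg_u", "d_u * u", change=np.array([-1, 0])),
            cn.Reaction("synth_v", "k_sv", change=np.array([0, 1])),
            cn.Reaction("deg_v", "d_v * v", change=np.array([0, -1])),
        ],
        parameters={"k_su": 8.0, "d_u": 1.0, "k_sv": 5.0, "d_v": 1.0},
    )
    space = cn.StateSpace([40, 40])
    dist = cn.solve_steady_state(cn.build_generator(network, space), space)
    return network, space, dist


@pytest.fixture()
def two_state_chain():
    """Two-state chain, rate 1 for 0->1 and 2 for 1->0."""
    network = cn.ReactionNetwork(
        species=["n"],
        reactions=[
            cn.Reaction("up", "k01 * (1 - n)", change=np.array([1])),
            cn.Reaction("down", "k10 * n", change=np.array([-1])),
        ],
        parameters={"k01": 1.0, "k10": 2.0},
    )
    return network, cn.StateSpace([1])
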