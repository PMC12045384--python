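import numpy as np
import pytest

import cytolearn as cl


@pytest.fixture(scope="session")
def tiny_bundle():
    return cl.make_fixture("tiny", seed=0)


@pytest.fixture(scope="session")
def net8():
    """A mid-sized disordered patch shared by read-only tests."""
    return cl.generate_disordered_network(8, jitter=0.3, seed=1)


@pytest.fixture
def two_node_state():
    """Minimal two-node, one-edge state for hand-checkable dynamics."""
    return cl.NetworkState(
        positions=np.array([[0.0, 0.0], [1.2, 0.0]]),
        edges=np.array([[0, 1]]),
        stiffness=np.array([1.0]),
        rest_length=np.array([1.0]),
        motor=np.array([1.0]),
        protein=np.array([1.0]),
        prev_strain=np.array([0.2]),
        severed=np.array([False]),
        pinned=np.array([False, False]),
        boundary_nodes=np.array([0, 1]),
    )
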