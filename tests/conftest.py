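import numpy as np
import pytest

from entrainmeg.sensors import make_sensor_array


@pytest.fixture(scope="session")
def sensors20():
    """Small 20-site array; neighbour radius enlarged to keep the adjacency
    graph connected at this density."""
    return make_sensor_array(20, neighbor_radius=0.09)


@pytest.fixture(scope="session")
def sensors30():
    return make_sensor_array(30, neighbor_radius=0.075)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def chain_adjacency():
    def _make(n):
        adj = np.zeros((n, n), dtype=bool)
        for i in range(n - 1):
            adj[i, i + 1] = adj[i + 1, i] = True
        return adj
    return _make
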