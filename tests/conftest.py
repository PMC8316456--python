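import numpy as np
import pytest

import dynor as dy


@pytest.fixture(scope="session")
def k2():
    """Single unit-weight edge."""
    return dy.WeightedGraph(2, [[0, 1]], [1.0], [1.0])


@pytest.fixture(scope="session")
def path3():
    return dy.generate_canonical("path", n=3)


@pytest.fixture(scope="session")
def dense_ssbm():
    """One dense two-block SBM realisation (n=100, p_in=0.5, p_out=0.1)."""
    graph, part = dy.generate_ssbm(100, 0.5, 0.1, seed=1)
    assert graph.is_connected
    return graph, part


@pytest.fixture(scope="session")
def multiscale():
    graph, fine, coarse = dy.generate_multiscale_sbm(seed=0)
    assert graph.is_connected
    return graph, fine, coarse


def random_connected(n, p, seed):
    rng = np.random.default_rng(seed)
    for _ in range(50):
        g = dy.generate_canonical("erdos_renyi", n=n, p=p,
                                  seed=int(rng.integers(2**31)))
        if g.is_connected:
            return g
    raise RuntimeError("no connected sample")
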