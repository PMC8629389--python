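import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from prosofix import GraphStructure

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=30,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def random_connected_graph(rng: np.random.Generator, N: int, *, weighted: bool = False,
                           extra_edge_prob: float = 0.3) -> GraphStructure:
    """Random connected symmetric graph: a random spanning path plus extra edges."""
    order = rng.permutation(N)
    W = np.zeros((N, N))
    for a, b in zip(order[:-1], order[1:]):
        w = rng.uniform(0.2, 5.0) if weighted else 1.0
        W[a, b] = W[b, a] = w
    for i in range(N):
        for j in range(i + 1, N):
            if W[i, j] == 0 and rng.random() < extra_edge_prob:
                w = rng.uniform(0.2, 5.0) if weighted else 1.0
                W[i, j] = W[j, i] = w
    return GraphStructure(W)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
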