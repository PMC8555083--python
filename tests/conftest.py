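import numpy as np
import pytest

from braintopo.connectome import AdjacencyMatrix
from braintopo.timeseries import RoiTimeSeries


def adjacency_from_edges(n: int, edges: list[tuple[int, int]], sparsity: float = 0.2):
    a = np.zeros((n, n), dtype=int)
    for i, j in edges:
        a[i, j] = a[j, i] = 1
    return AdjacencyMatrix(entries=a, sparsity=sparsity)


@pytest.fixture
def complete_graph():
    def make(n):
        a = np.ones((n, n), dtype=int) - np.eye(n, dtype=int)
        return AdjacencyMatrix(entries=a, sparsity=0.9)

    return make


@pytest.fixture
def path_graph():
    def make(n):
        return adjacency_from_edges(n, [(i, i + 1) for i in range(n - 1)])

    return make


@pytest.fixture
def white_noise_ts():
    def make(t, n, seed=0, tr=2.0):
        rng = np.random.default_rng(seed)
        return RoiTimeSeries(
            data=rng.standard_normal((t, n)),
            region_labels=[f"R{i:03d}" for i in range(n)],
            tr_seconds=tr,
        )

    return make


@pytest.fixture(scope="session")
def chain_precision():
    """Chain 1-2-3-4: only consecutive regions are conditionally dependent."""
    p = np.array(
        [
            [1.0, -0.7, 0.0, 0.0],
            [-0.7, 1.6, -0.7, 0.0],
            [0.0, -0.7, 1.6, -0.7],
            [0.0, 0.0, -0.7, 1.0],
        ]
    )
    assert np.linalg.eigvalsh(p).min() > 0
    return p
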