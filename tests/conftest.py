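import numpy as np
import pytest

from fcnet.connectome import ThresholdedNetwork


def net_from(weights: np.ndarray, density: float = 0.16) -> ThresholdedNetwork:
    """Wrap a symmetric weight matrix as a ThresholdedNetwork for metric calls."""
    w = np.asarray(weights, dtype=float)
    return ThresholdedNetwork(density=density, weights=w)


def graph_from_edges(n: int, edges, weight: float | dict = 1.0) -> np.ndarray:
    w = np.zeros((n, n))
    for e in edges:
        i, j = e
        val = weight[e] if isinstance(weight, dict) else weight
        w[i, j] = w[j, i] = val
    return w


@pytest.fixture
def triangle():
    return graph_from_edges(3, [(0, 1), (0, 2), (1, 2)])


@pytest.fixture
def star5():
    """Hub node 0 with four leaves."""
    return graph_from_edges(5, [(0, i) for i in range(1, 5)])


@pytest.fixture
def path3():
    return graph_from_edges(3, [(0, 1), (1, 2)])


@pytest.fixture
def two_cliques_bridge():
    """Two unit-weight 4-cliques joined by a single edge (8 nodes, 13 edges)."""
    edges = [(i, j) for i in range(4) for j in range(i + 1, 4)]
    edges += [(i, j) for i in range(4, 8) for j in range(i + 1, 8)]
    edges += [(3, 4)]
    return graph_from_edges(8, edges)


@pytest.fixture
def signed_synthetic_z():
    """Full signed Fisher-z matrix from the cohort generator (60 nodes)."""
    import fcnet as f

    spec = f.CohortSpec(
        groups=("g",), n_per_group=1, rho_within=0.5, rho_between=0.05, seed=3
    )
    subj = f.make_cohort(spec)[0]
    return f.correlation_matrix(
        f.SubjectTimeseries(subj.subject_id, subj.timeseries)
    )
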