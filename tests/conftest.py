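import numpy as np
import pytest

from edgeprior import GeneratorSpec, Network, generate_network


@pytest.fixture
def triangle() -> Network:
    return Network.from_edges([(0, 1), (1, 2), (0, 2)])


@pytest.fixture
def path3() -> Network:
    return Network.from_edges([(0, 1), (1, 2)])


@pytest.fixture
def four_cycle() -> Network:
    return Network.from_edges([(0, 1), (1, 2), (2, 3), (0, 3)])


@pytest.fixture
def k4() -> Network:
    return Network.from_edges([(i, j) for i in range(4) for j in range(i + 1, 4)])


@pytest.fixture(scope="session")
def sparse_config_model() -> Network:
    """~300-node power-law graph, density ~0.02."""
    return generate_network(
        GeneratorSpec(kind="configuration_model", n_nodes=300, exponent=2.2, min_degree=2, seed=11)
    )


@pytest.fixture(scope="session")
def small_config_model() -> Network:
    """50-node graph for brute-force feature comparisons."""
    return generate_network(
        GeneratorSpec(kind="configuration_model", n_nodes=50, exponent=2.3, min_degree=2, seed=5)
    )


@pytest.fixture(scope="session")
def bipartite_net() -> Network:
    return generate_network(
        GeneratorSpec(kind="bipartite", n_source=20, n_target=30, density=0.1, seed=3)
    )


@pytest.fixture(scope="session")
def directed_net() -> Network:
    return generate_network(GeneratorSpec(kind="directed", n_nodes=60, m=240, seed=4))


def brute_force_auroc(scores, labels) -> float:
    """All-pairs comparison oracle: ties count half."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, bool)
    pos = scores[labels]
    neg = scores[~labels]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))
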