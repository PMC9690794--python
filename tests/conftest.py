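import numpy as np
import pytest

import ordnet


@pytest.fixture(scope="session")
def model17():
    """Default study-emulating true model: 17 nodes, 3 blocks, density 0.4."""
    return ordnet.generate_true_ggm(seed=7)


@pytest.fixture(scope="session")
def data1000(model17):
    return ordnet.sample_ordinal(model17, 1000, seed=17)


@pytest.fixture(scope="session")
def net1000(data1000):
    return ordnet.select_network(ordnet.correlation_matrix(data1000))


def make_network(weights, labels=None):
    """Wrap a raw symmetric weight matrix as a NetworkModel for unit tests."""
    weights = np.asarray(weights, dtype=float)
    p = weights.shape[0]
    return ordnet.NetworkModel(
        weights=weights,
        node_labels=labels or [f"V{i + 1}" for i in range(p)],
        lambda_selected=np.nan,
        gamma=0.5,
        n_effective=np.nan,
    )
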