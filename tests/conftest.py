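import numpy as np
import pandas as pd
import pytest

import symptomnet as sn


@pytest.fixture(scope="session")
def chain_truth():
    """9-node chain with all edge weights 0.3 (known sparse ground truth)."""
    P = np.zeros((9, 9))
    for i in range(8):
        P[i, i + 1] = P[i + 1, i] = 0.3
    return sn.simulate._network_from_partials(P)


@pytest.fixture(scope="session")
def random_truth():
    return sn.make_true_network(
        sn.TrueNetworkSpec(p=9, density=0.3, weight_range=(0.2, 0.4), seed=11)
    )


@pytest.fixture(scope="session")
def medium_dataset(random_truth):
    em = sn.default_emulation(p=9, n=800)
    return sn.sample_ordinal_dataset(random_truth, em, seed=5)


@pytest.fixture()
def small_csv(tmp_path):
    """Well-formed 6-subject CSV with all 11 canonical columns."""
    rng = np.random.default_rng(0)
    df = pd.DataFrame(
        {f"PHQ{i}": rng.integers(0, 4, 6) for i in range(1, 10)}
        | {"AA": rng.uniform(1, 5, 6).round(2), "IA": rng.uniform(1, 5, 6).round(2)}
        | {"group": ["urban", "rural"] * 3}
    )
    path = tmp_path / "items.csv"
    df.to_csv(path, index=False)
    return path, df


def toy_network(weights, nodes=None):
    W = np.asarray(weights, dtype=float)
    nodes = nodes or [f"N{i}" for i in range(W.shape[0])]
    return sn.NetworkModel(list(nodes), W)
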