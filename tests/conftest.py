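import networkx as nx
import numpy as np
import pandas as pd
import pytest

from asvnet.feature_table import FeatureTable


@pytest.fixture
def toy_table() -> FeatureTable:
    data = pd.DataFrame(
        [[5, 0, 3, 2], [1, 4, 0, 7], [2, 2, 2, 2]],
        index=["s1", "s2", "s3"],
        columns=["a1", "a2", "a3", "a4"],
    )
    return FeatureTable(data)


@pytest.fixture
def two_cliques() -> nx.Graph:
    """Two disconnected K4 cliques (natural partition has Q = 0.5)."""
    g = nx.complete_graph(4)
    h = nx.complete_graph(4)
    return nx.disjoint_union(g, h)


def random_count_table(rng: np.random.Generator, n_samples: int, n_asvs: int,
                       max_count: int = 50) -> FeatureTable:
    counts = rng.integers(0, max_count, size=(n_samples, n_asvs))
    return FeatureTable(pd.DataFrame(
        counts,
        index=[f"s{i}" for i in range(n_samples)],
        columns=[f"a{j}" for j in range(n_asvs)],
    ))
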