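import numpy as np
import pytest

from simlabel.preprocess import PEARSON_RAW, UNIT, SimilarityMatrix
from simlabel.simulate import GraphSpec, graph_similarity, make_component_graph


def random_unit_similarity(rng, n):
    """Random symmetric similarity on [0, 1] with unit diagonal."""
    m = rng.random((n, n))
    s = (m + m.T) / 2.0
    np.fill_diagonal(s, 1.0)
    return SimilarityMatrix(s, [f"s{i + 1}" for i in range(n)], UNIT)


def random_signed_similarity(rng, n):
    m = rng.uniform(-1.0, 1.0, size=(n, n))
    s = (m + m.T) / 2.0
    np.fill_diagonal(s, 1.0)
    return SimilarityMatrix(s, [f"s{i + 1}" for i in range(n)], PEARSON_RAW)


@pytest.fixture
def three_component_graph():
    """The 15-node graph of three complete 5-node components and its
    adjacency-row correlation similarity."""
    adj = make_component_graph(GraphSpec((5, 5, 5)))
    return adj, graph_similarity(adj)
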