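import logging

import numpy as np
import pytest

from egolink.graph import CategorySpace, ProteinGraph
from egolink.synthetic import easy_setting, generate

logging.getLogger("egolink").setLevel(logging.ERROR)


@pytest.fixture
def categories() -> CategorySpace:
    return CategorySpace()


@pytest.fixture
def path_graph(categories) -> ProteinGraph:
    """a-b-c-d-e path with one label per edge."""
    labels = np.zeros((4, 7), dtype=np.uint8)
    labels[np.arange(4), [0, 1, 2, 3]] = 1
    return ProteinGraph(protein_ids=list("abcde"),
                        edges=np.array([[0, 1], [1, 2], [2, 3], [3, 4]]),
                        labels=labels, categories=categories,
                        features=np.eye(5, 3))


@pytest.fixture
def star_graph(categories) -> ProteinGraph:
    """K_{1,5}: center 0 with 5 leaves."""
    edges = np.array([[0, i] for i in range(1, 6)])
    labels = np.zeros((5, 7), dtype=np.uint8)
    labels[:, 0] = 1
    return ProteinGraph(protein_ids=[f"p{i}" for i in range(6)],
                        edges=edges, labels=labels, categories=categories)


def random_multigraph(n: int, p: float, seed: int, t: int = 7) -> ProteinGraph:
    """Erdos-Renyi graph with random multi-labels (>= 1 per edge)."""
    rng = np.random.default_rng(seed)
    iu, ju = np.triu_indices(n, k=1)
    keep = rng.random(iu.shape) < p
    edges = np.column_stack([iu[keep], ju[keep]])
    if edges.shape[0] == 0:
        edges = np.array([[0, 1]])
    labels = (rng.random((edges.shape[0], t)) < 0.3).astype(np.uint8)
    empty = labels.sum(axis=1) == 0
    labels[empty, rng.integers(0, t, size=int(empty.sum()))] = 1
    feats = rng.normal(size=(n, 4))
    return ProteinGraph(protein_ids=[f"p{i}" for i in range(n)], edges=edges,
                        labels=labels, features=feats)


@pytest.fixture
def random_graph() -> ProteinGraph:
    return random_multigraph(30, 0.15, seed=0)


@pytest.fixture(scope="session")
def easy_graph():
    graph, truth = generate(easy_setting(seed=7))
    return graph, truth
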