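import networkx as nx
import numpy as np
import pytest

from molentropy import LabeledGraph, make_labeled_cycle


@pytest.fixture
def path3():
    """Path a-b-c, all carbon, single bonds."""
    return LabeledGraph.from_labels(["C", "C", "C"], [(0, 1, "s"), (1, 2, "s")])


@pytest.fixture
def coc():
    """Path C-O-C, single bonds."""
    return LabeledGraph.from_labels(["C", "O", "C"], [(0, 1, "s"), (1, 2, "s")])


@pytest.fixture
def c6():
    return make_labeled_cycle(6, "uniform", "uniform")


@pytest.fixture
def k3():
    return LabeledGraph.from_labels(
        ["C", "C", "C"], [(0, 1, "s"), (0, 2, "s"), (1, 2, "s")]
    )


@pytest.fixture
def star4():
    """Star: center 0 with leaves 1, 2, 3."""
    return LabeledGraph.from_labels(
        ["C", "C", "C", "C"], [(0, 1, "s"), (0, 2, "s"), (0, 3, "s")]
    )


def random_labeled_graph(rng: np.random.Generator, n: int) -> LabeledGraph:
    """Small random connected graph with random atom/bond labels."""
    while True:
        g = nx.gnp_random_graph(n, 0.45, seed=int(rng.integers(2**31)))
        if n == 1 or nx.is_connected(g):
            break
    labels = rng.choice(["C", "N", "O", "S"], size=n)
    edges = [(u, v, str(rng.choice(["s", "d"]))) for u, v in g.edges]
    return LabeledGraph.from_labels([str(l) for l in labels], edges)
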