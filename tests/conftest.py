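import networkx as nx
import numpy as np
import pandas as pd
import pytest

from econet.netbuild import EcoNetwork
from econet.tables import AbundanceTable, CountTable


def make_network(edges, st=0.5, provenance="test"):
    """EcoNetwork from (u, v) or (u, v, weight) tuples."""
    g = nx.Graph()
    for e in edges:
        if len(e) == 2:
            u, v = e
            w = 0.9
        else:
            u, v, w = e
        g.add_edge(u, v, weight=float(w), sign=1 if w >= 0 else -1)
    return EcoNetwork(g, st=st, provenance=provenance)


@pytest.fixture
def triangle():
    return make_network([("a", "b"), ("b", "c"), ("a", "c")])


@pytest.fixture
def path3():
    return make_network([("a", "b"), ("b", "c")])


@pytest.fixture
def star4():
    # center + 3 leaves
    return make_network([("c", "l1"), ("c", "l2"), ("c", "l3")])


@pytest.fixture
def star5():
    # center + 4 leaves
    return make_network([("c", f"l{i}") for i in range(1, 5)])


@pytest.fixture
def k4():
    g = nx.complete_graph(4)
    return make_network(list(g.edges))


@pytest.fixture
def two_disjoint_edges():
    return make_network([("a", "b"), ("c", "d")])


@pytest.fixture
def small_counts():
    df = pd.DataFrame(
        {
            "s1": [10, 0, 30],
            "s2": [5, 5, 10],
            "s3": [0, 20, 20],
        },
        index=["otuA", "otuB", "otuC"],
    )
    meta = pd.DataFrame(
        {"dph": [12, 20, 27], "stage": ["S1", "S1", "S2"], "tank": ["T1", "T2", "T1"]},
        index=["s1", "s2", "s3"],
    )
    return CountTable(df, metadata=meta)


def random_econetwork(rng, n=20, p=0.2):
    """Random signed network with every node having degree >= 1."""
    while True:
        g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31 - 1)))
        g.remove_nodes_from(list(nx.isolates(g)))
        if g.number_of_nodes() >= 4 and g.number_of_edges() >= 3:
            break
    h = nx.Graph()
    for u, v in g.edges:
        w = float(rng.uniform(0.5, 1.0)) * (1 if rng.random() < 0.5 else -1)
        h.add_edge(f"n{u}", f"n{v}", weight=w, sign=1 if w >= 0 else -1)
    return EcoNetwork(h, st=0.5)


def relative_table(values, otu_ids=None, sample_ids=None):
    arr = np.asarray(values, dtype=float)
    arr = arr / arr.sum(axis=0, keepdims=True)
    otu_ids = otu_ids or [f"o{i}" for i in range(arr.shape[0])]
    sample_ids = sample_ids or [f"s{j}" for j in range(arr.shape[1])]
    return AbundanceTable(pd.DataFrame(arr, index=otu_ids, columns=sample_ids))
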