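import networkx as nx
import pytest

from moddens import Partition


@pytest.fixture
def two_triangles():
    """Two disconnected triangles with their planted 2-module partition."""
    g = nx.Graph([("a", "b"), ("b", "c"), ("a", "c"),
                  ("d", "e"), ("e", "f"), ("d", "f")])
    p = Partition.from_modules({"1": "abc", "2": "def"})
    return g, p


@pytest.fixture
def path4():
    """Path a-b-c-d split down the middle."""
    g = nx.Graph([("a", "b"), ("b", "c"), ("c", "d")])
    p = Partition.from_modules({"1": "ab", "2": "cd"})
    return g, p


@pytest.fixture
def bridged_k5s():
    """Two 5-cliques joined by a single edge; D- and Q-optimum is the clique split."""
    g = nx.disjoint_union(nx.complete_graph(5), nx.complete_graph(5))
    g = nx.relabel_nodes(g, lambda i: f"v{i}")
    g.add_edge("v0", "v5")
    split = Partition.from_modules(
        {"left": [f"v{i}" for i in range(5)], "right": [f"v{i}" for i in range(5, 10)]}
    )
    return g, split


@pytest.fixture
def triangle_ring():
    """Ring of 4 triangles, each linked to the next by one edge.

    The D-optimal partition is the four triangles (D = 16/3), established by
    exhaustive enumeration of all 4,213,597 partitions with the test oracle.
    """
    g = nx.Graph()
    for t in range(4):
        g.add_edges_from([(f"t{t}a", f"t{t}b"), (f"t{t}b", f"t{t}c"),
                          (f"t{t}a", f"t{t}c")])
    for t in range(4):
        g.add_edge(f"t{t}c", f"t{(t + 1) % 4}a")
    triangles = Partition.from_modules(
        {str(t): [f"t{t}a", f"t{t}b", f"t{t}c"] for t in range(4)}
    )
    return g, triangles


def random_graph_and_partition(seed: int, n: int = 8, p: float = 0.45, kmax: int = 3):
    """Seeded connected-ish random graph plus a random partition of it."""
    import random

    rng = random.Random(seed)
    g = nx.gnp_random_graph(n, p, seed=seed)
    g.add_edges_from((i, (i + 1) % n) for i in range(n))  # ensure edges exist
    labels = {v: str(rng.randrange(1, kmax + 1)) for v in g.nodes}
    return g, Partition(labels)
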