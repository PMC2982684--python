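"""Planted-clique benchmark networks.

An instance consists of 2m cliques — m of size n1 and m of size n2 — plus
external edges placed uniformly at random between cliques.  The number of
external edges is fixed at round(m*(n1+n2)*k_out/2), so the mean external
degree per node equals k_out by construction and the total edge count is
exactly the expectation

    m*(n1*(n1-1)/2 + n2*(n2-1)/2) + round(m*(n1+n2)*k_out/2).

The planted partition (one module per clique) is attached to the instance.
Low-k_out instances may be disconnected; downstream code tolerates that.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .graph_core import Partition

__all__ = ["BenchmarkInstance", "expected_edge_count", "generate", "relax_to_dense_modules"]


@dataclass(frozen=True)
class BenchmarkInstance:
    network: nx.Graph
    planted: Partition
    m: int
    n1: int
    n2: int
    k_out: float
    seed: int

    @property
    def nc(self) -> int:
        """Number of cliques (planted modules)."""
        return 2 * self.m


def expected_edge_count(m: int, n1: int, n2: int, k_out: float) -> float:
    """Expected total edges: all internal clique edges plus k_out/2 per node."""
    if m < 1 or n1 < 2 or n2 < 2 or k_out < 0:
        raise ValueError("require m >= 1, n1, n2 >= 2, k_out >= 0")
    internal = m * (n1 * (n1 - 1) / 2 + n2 * (n2 - 1) / 2)
    return internal + m * (n1 + n2) * k_out / 2


def _clique_layout(m: int, n1: int, n2: int):
    """Clique label / node-name layout: cliques c000..c(2m-1), sizes
    alternating n1, n2; nodes named c{i}_n{j}."""
    width = max(3, len(str(2 * m - 1)))
    cliques = []
    for i in range(2 * m):
        size = n1 if i % 2 == 0 else n2
        label = f"c{i:0{width}d}"
        cliques.append((label, [f"{label}_n{j:02d}" for j in range(size)]))
    return cliques


def generate(m: int, n1: int = 10, n2: int = 15, k_out: float = 0.0, seed: int = 0) -> BenchmarkInstance:
    """Generate one planted-clique benchmark instance (deterministic per seed)."""
    n_total = m * (n1 + n2)
    n_ext = round(m * (n1 + n2) * k_out / 2)
    cliques = _clique_layout(m, n1, n2)
    internal_pairs = m * (n1 * (n1 - 1) // 2 + n2 * (n2 - 1) // 2)
    available = n_total * (n_total - 1) // 2 - internal_pairs
    if n_ext > available:
        raise ValueError(
            f"k_out={k_out} needs {n_ext} external edges but only "
            f"{available} inter-clique pairs exist"
        )
    net = nx.Graph()
    assignment: dict[str, str] = {}
    all_nodes: list[str] = []
    clique_of: list[int] = []
    for ci, (label, members) in enumerate(cliques):
        for v in members:
            assignment[v] = label
            all_nodes.append(v)
            clique_of.append(ci)
        for a in range(len(members)):
            for b in range(a + 1, len(members)):
                net.add_edge(members[a], members[b])
    # external edges: fixed count, uniform without replacement over
    # inter-clique pairs (rejection sampling on the pair universe)
    rng = np.random.default_rng(seed)
    chosen: set[tuple[int, int]] = set()
    while len(chosen) < n_ext:
        draw = rng.integers(0, n_total, size=2 * (n_ext - len(chosen)) + 8)
        for idx in range(0, len(draw) - 1, 2):
            i, j = int(draw[idx]), int(draw[idx + 1])
            if i == j or clique_of[i] == clique_of[j]:
                continue
            pair = (i, j) if i < j else (j, i)
            if pair not in chosen:
                chosen.add(pair)
                if len(chosen) >= n_ext:
                    break
    for i, j in sorted(chosen):
        net.add_edge(all_nodes[i], all_nodes[j])
    return BenchmarkInstance(
        network=net, planted=Partition(assignment),
        m=m, n1=n1, n2=n2, k_out=k_out, seed=seed,
    )


def relax_to_dense_modules(instance: BenchmarkInstance, p_in: float, seed: int = 0) -> BenchmarkInstance:
    """Thin each clique to a dense module: keep each internal edge w.p. p_in.

    External edges and the planted partition are untouched; p_in = 1 is the
    identity.
    """
    if not 0.0 < p_in <= 1.0:
        raise ValueError(f"p_in must be in (0, 1], got {p_in}")
    if p_in == 1.0:
        return instance
    rng = np.random.default_rng(seed)
    a = instance.planted.assignment
    net = instance.network.copy()
    internal = sorted(
        tuple(sorted(e)) for e in net.edges if a[e[0]] == a[e[1]]
    )
    drop = [e for e in internal if rng.random() >= p_in]
    net.remove_edges_from(drop)
    return BenchmarkInstance(
        network=net, planted=instance.planted,
        m=instance.m, n1=instance.n1, n2=instance.n2,
        k_out=instance.k_out, seed=instance.seed,
    )
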