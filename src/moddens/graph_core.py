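"""Graph and partition data model plus edge-list / partition file I/O.

Networks are plain :class:`networkx.Graph` objects: undirected, simple,
unweighted, with opaque string node identifiers.  A :class:`Partition`
assigns every node of a network to exactly one module label.  All other
modules in the package operate on these two objects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import cached_property
from typing import Iterable, Mapping

import networkx as nx

logger = logging.getLogger(__name__)

__all__ = [
    "Partition",
    "read_edge_list",
    "write_edge_list",
    "giant_component",
    "read_partition",
    "write_partition",
    "induced_subgraph_connected",
]


class EdgeListParseError(ValueError):
    """A malformed line in an edge-list or partition file."""


@dataclass(frozen=True)
class Partition:
    """A disjoint assignment of every node to exactly one module.

    Parameters
    ----------
    assignment:
        Mapping node identifier -> module label.  Labels are opaque
        strings; ints are accepted and coerced by :meth:`from_modules`.
    """

    assignment: Mapping[str, str]

    @cached_property
    def modules(self) -> dict[str, frozenset]:
        """Derived map module label -> frozenset of member nodes."""
        groups: dict[str, set] = {}
        for node, label in self.assignment.items():
            groups.setdefault(label, set()).add(node)
        return {lab: frozenset(members) for lab, members in groups.items()}

    @property
    def m(self) -> int:
        """Number of modules."""
        return len(self.modules)

    @property
    def nodes(self) -> frozenset:
        return frozenset(self.assignment)

    @classmethod
    def from_modules(cls, modules: Mapping[str, Iterable]) -> "Partition":
        assignment: dict[str, str] = {}
        for label, members in modules.items():
            for node in members:
                if node in assignment:
                    raise ValueError(
                        f"node {node!r} assigned to both module "
                        f"{assignment[node]!r} and {label!r}"
                    )
                assignment[node] = str(label)
        return cls(assignment)

    def validate_against(self, net: nx.Graph) -> None:
        """Raise ValueError unless this partition covers ``net`` exactly."""
        missing = set(net.nodes) - set(self.assignment)
        extra = set(self.assignment) - set(net.nodes)
        if missing:
            raise ValueError(f"{len(missing)} network nodes unassigned, e.g. {sorted(missing)[:3]}")
        if extra:
            raise ValueError(f"{len(extra)} assigned nodes not in network, e.g. {sorted(extra)[:3]}")

    def relabel_canonical(self) -> "Partition":
        """Rename module labels to m000.. in order of smallest member node."""
        order = sorted(self.modules, key=lambda lab: min(self.modules[lab]))
        width = max(3, len(str(len(order) - 1))) if order else 3
        mapping = {lab: f"m{idx:0{width}d}" for idx, lab in enumerate(order)}
        return Partition({node: mapping[lab] for node, lab in self.assignment.items()})


def _parse_rows(path, delimiter: str | None, min_fields: int):
    """Yield (lineno, fields) for non-comment, non-blank lines."""
    n_lines = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split(delimiter) if delimiter else line.split()
            if len(fields) < min_fields:
                raise EdgeListParseError(
                    f"{path}: line {lineno}: expected >= {min_fields} fields, got {len(fields)}: {line!r}"
                )
            n_lines += 1
            yield lineno, fields
    if n_lines == 0:
        raise EdgeListParseError(f"{path}: no records found")


def read_edge_list(path, delimiter: str | None = None) -> nx.Graph:
    """Read a 2-column edge list into a simple undirected graph.

    Lines starting with '#' and blank lines are skipped; extra columns are
    ignored; self-loops are dropped and duplicate / reversed pairs collapse
    to a single edge (a count of dropped records is logged).  ``delimiter``
    of None splits on any whitespace.
    """
    net = nx.Graph()
    dropped_self = dropped_dup = 0
    for _, fields in _parse_rows(path, delimiter, 2):
        u, v = fields[0], fields[1]
        if u == v:
            dropped_self += 1
            net.add_node(u)
            continue
        if net.has_edge(u, v):
            dropped_dup += 1
            continue
        net.add_edge(u, v)
    if dropped_self or dropped_dup:
        logger.info(
            "read_edge_list(%s): dropped %d self-loops and %d duplicate pairs",
            path, dropped_self, dropped_dup,
        )
    return net


def write_edge_list(net: nx.Graph, path, delimiter: str = "\t") -> None:
    with open(path, "w") as fh:
        fh.write(f"# node_a{delimiter}node_b\n")
        for u, v in sorted(tuple(sorted(e)) for e in net.edges):
            fh.write(f"{u}{delimiter}{v}\n")


def giant_component(net: nx.Graph) -> nx.Graph:
    """Induced subgraph on the largest connected component.

    Ties between equal-size components are broken by the smallest
    lexicographic node label, so the result is deterministic.
    """
    if net.number_of_nodes() == 0:
        raise ValueError("empty network has no giant component")
    best = min(
        nx.connected_components(net),
        key=lambda comp: (-len(comp), min(map(str, comp))),
    )
    return net.subgraph(best).copy()


def read_partition(path, delimiter: str | None = None) -> Partition:
    """Read a 2-column (node_id, module_id) TSV into a Partition."""
    assignment: dict[str, str] = {}
    for lineno, fields in _parse_rows(path, delimiter, 2):
        node, label = fields[0], fields[1]
        if not label:
            raise EdgeListParseError(f"{path}: line {lineno}: empty module label")
        if node in assignment:
            raise EdgeListParseError(
                f"{path}: line {lineno}: node {node!r} assigned twice "
                f"({assignment[node]!r} and {label!r})"
            )
        assignment[node] = label
    return Partition(assignment)


def write_partition(p: Partition, path, delimiter: str = "\t") -> None:
    with open(path, "w") as fh:
        fh.write(f"# node_id{delimiter}module_id\n")
        for node in sorted(p.assignment, key=str):
            fh.write(f"{node}{delimiter}{p.assignment[node]}\n")


def induced_subgraph_connected(net: nx.Graph, nodes) -> bool:
    """True iff the subgraph induced by ``nodes`` is connected.

    Singleton sets count as connected.  Raises on empty or non-subset input.
    """
    nodes = set(nodes)
    if not nodes:
        raise ValueError("empty node set")
    if not nodes <= set(net.nodes):
        raise ValueError("nodes not contained in network")
    if len(nodes) == 1:
        return True
    # BFS restricted to `nodes`; avoids building a subgraph object.
    start = next(iter(nodes))
    seen = {start}
    stack = [start]
    while stack:
        u = stack.pop()
        for w in net.adj[u]:
            if w in nodes and w not in seen:
                seen.add(w)
                stack.append(w)
    return len(seen) == len(nodes)
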