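"""Undirected PPI network container and edge-list I/O.

A network is a simple undirected graph with string node labels. Self-loops in
input files are dropped from the edge set (the node label is retained); the
self-covering A_ii = 1 convention of the domination constraints is applied
uniformly later, via :func:`closed_adjacency`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx

logger = logging.getLogger(__name__)

__all__ = [
    "Network",
    "NetworkFormatError",
    "read_edge_list",
    "write_edge_list",
    "largest_connected_component",
    "closed_adjacency",
]


class NetworkFormatError(ValueError):
    """Raised for malformed edge-list input."""


def _canonical_edge(u: str, v: str) -> tuple[str, str]:
    return (u, v) if u <= v else (v, u)


@dataclass(frozen=True)
class Network:
    """Simple undirected graph: ordered unique node labels plus an edge set.

    Invariants: no self-edges, each edge stored once as an unordered pair,
    every endpoint present in ``nodes``. Node order is first-appearance order
    and is the canonical variable order for the integer programs.
    """

    nodes: tuple[str, ...]
    edges: frozenset[tuple[str, str]]
    _adj: Mapping[str, frozenset[str]] = field(
        init=False, repr=False, compare=False, hash=False, default=None
    )

    def __post_init__(self) -> None:
        node_set = set(self.nodes)
        if len(node_set) != len(self.nodes):
            raise ValueError("duplicate node labels")
        adj: dict[str, set[str]] = {u: set() for u in self.nodes}
        for u, v in self.edges:
            if u == v:
                raise ValueError(f"self-edge on {u!r} in edge set")
            if u not in node_set or v not in node_set:
                raise ValueError(f"edge ({u!r}, {v!r}) has endpoint outside nodes")
            if (u, v) != _canonical_edge(u, v):
                raise ValueError(f"edge ({u!r}, {v!r}) not stored canonically")
            adj[u].add(v)
            adj[v].add(u)
        object.__setattr__(self, "_adj", {u: frozenset(s) for u, s in adj.items()})

    @classmethod
    def from_edges(
        cls, edges: Iterable[tuple[str, str]], extra_nodes: Iterable[str] = ()
    ) -> "Network":
        """Build a Network, collapsing duplicates and dropping self-loops.

        Node order is first appearance in the edge stream (then extra_nodes).
        """
        order: list[str] = []
        seen: set[str] = set()
        edge_set: set[tuple[str, str]] = set()
        for u, v in edges:
            for w in (u, v):
                if w not in seen:
                    seen.add(w)
                    order.append(w)
            if u != v:
                edge_set.add(_canonical_edge(u, v))
        for w in extra_nodes:
            if w not in seen:
                seen.add(w)
                order.append(w)
        return cls(tuple(order), frozenset(edge_set))

    @property
    def n(self) -> int:
        return len(self.nodes)

    @property
    def m(self) -> int:
        return len(self.edges)

    def neighbors(self, u: str) -> frozenset[str]:
        return self._adj[u]

    def degree(self, u: str) -> int:
        return len(self._adj[u])

    def has_node(self, u: str) -> bool:
        return u in self._adj

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g

    @classmethod
    def from_networkx(cls, g: nx.Graph, order: Iterable[str] | None = None) -> "Network":
        nodes = tuple(order) if order is not None else tuple(g.nodes())
        return cls(
            nodes, frozenset(_canonical_edge(str(u), str(v)) for u, v in g.edges())
        )

    def induced_subgraph(self, keep: Iterable[str]) -> "Network":
        keep_set = set(keep)
        nodes = tuple(u for u in self.nodes if u in keep_set)
        edges = frozenset(e for e in self.edges if e[0] in keep_set and e[1] in keep_set)
        return Network(nodes, edges)


def read_edge_list(path: str | Path, delimiter: str | None = None, sif: bool = False) -> Network:
    """Read a two-column edge list (or SIF with ``sif=True``) into a Network.

    Lines beginning with ``#`` are ignored; fields are whitespace-split unless
    an explicit delimiter is given. Duplicate and reversed-duplicate edges are
    collapsed; self-loop lines contribute the node but no edge.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"network file not found: {path}")
    edges: list[tuple[str, str]] = []
    extra: list[str] = []
    n_lines = 0
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split(delimiter) if delimiter else line.split()
            fields = [f.strip() for f in fields if f.strip()]
            if sif:
                if len(fields) == 1:
                    extra.append(fields[0])
                    continue
                if len(fields) < 3:
                    raise NetworkFormatError(
                        f"{path}:{lineno}: SIF line needs 3 fields, got {len(fields)}"
                    )
                u, v = fields[0], fields[2]
            else:
                if len(fields) < 2:
                    raise NetworkFormatError(
                        f"{path}:{lineno}: expected at least 2 fields, got {len(fields)}"
                    )
                u, v = fields[0], fields[1]
            edges.append((u, v))
            n_lines += 1
    net = Network.from_edges(edges, extra_nodes=extra)
    collapsed = n_lines - net.m
    if collapsed:
        logger.info("read %s: collapsed %d duplicate/self-loop edge lines", path, collapsed)
    return net


def write_edge_list(net: Network, path: str | Path, delimiter: str = "\t") -> None:
    """Write one edge per line, endpoints in canonical order, edges sorted.

    Isolated nodes are emitted as self-loop lines so a read round-trip
    recovers the full node set (the reader keeps the label, drops the loop).
    """
    isolated = [u for u in net.nodes if not net.neighbors(u)]
    with Path(path).open("w") as fh:
        for u, v in sorted(net.edges):
            fh.write(f"{u}{delimiter}{v}\n")
        for u in sorted(isolated):
            fh.write(f"{u}{delimiter}{u}\n")


def largest_connected_component(net: Network) -> Network:
    """Induced subgraph on the largest component.

    Equal-size ties are broken by the component containing the earliest
    first-appearance node, so the result is deterministic.
    """
    if net.n == 0:
        raise ValueError("empty network has no connected component")
    rank = {u: i for i, u in enumerate(net.nodes)}
    components = list(nx.connected_components(net.to_networkx()))
    best = max(components, key=lambda c: (len(c), -min(rank[u] for u in c)))
    return net.induced_subgraph(best)


def closed_adjacency(net: Network) -> dict[str, frozenset[str]]:
    """Closed neighborhoods N[i] = {i} | neighbors(i) (the A_ii = 1 convention)."""
    return {u: net.neighbors(u) | {u} for u in net.nodes}
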