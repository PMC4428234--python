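"""Synthetic inputs: the 10-node toy network, seeded random graphs, and
annotation sets with planted enrichment.

The toy network is a two-hub barbell-like graph on nodes 1..10 in which the
minimum dominating sets are exactly {1,6}, {5,10}, {1,10} and {5,6}: node 1
and node 5 are the only common closed neighbors of nodes 2-4, and nodes 6 and
10 the only common closed neighbors of nodes 7-9, so every 2-node dominating
set pairs one of {1,5} with one of {6,10}. Nodes 5 and 6 have the highest
degree-times-betweenness product, so any centrality-corrected solve with
gamma > 0 picks {5,6} among the four.
"""

from __future__ import annotations

import networkx as nx
import numpy as np

from .network import Network

__all__ = [
    "FIGURE1_EDGES",
    "make_figure1_fixture",
    "random_network",
    "planted_annotation",
]

FIGURE1_EDGES: tuple[tuple[str, str], ...] = (
    ("1", "2"),
    ("1", "3"),
    ("1", "4"),
    ("1", "5"),
    ("5", "2"),
    ("5", "3"),
    ("5", "4"),
    ("5", "6"),
    ("6", "7"),
    ("6", "8"),
    ("6", "9"),
    ("6", "10"),
    ("10", "7"),
    ("10", "8"),
    ("10", "9"),
)


def make_figure1_fixture() -> Network:
    """The deterministic 10-node, 15-edge toy network described above."""
    return Network.from_edges(FIGURE1_EDGES)


def random_network(
    model: str,
    n: int,
    density: float | int,
    seed: int,
) -> Network:
    """Seeded random test graph, reduced to its largest connected component.

    model "uniform-random": Erdos-Renyi G(n, p) with p = ``density``.
    model "preferential-attachment": Barabasi-Albert growth attaching each
    new node to ``density`` (an integer m >= 1) existing nodes, giving the
    heavy-tailed degree distribution typical of PPI networks.

    Identical (model, n, density, seed) always yields the same network.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if model == "uniform-random":
        if not 0 < density <= 1:
            raise ValueError("uniform-random density must be a probability in (0, 1]")
        g = nx.gnp_random_graph(n, density, seed=seed)
    elif model == "preferential-attachment":
        m = int(density)
        if m < 1 or m >= n:
            raise ValueError("preferential-attachment parameter must satisfy 1 <= m < n")
        g = nx.barabasi_albert_graph(n, m, seed=seed)
    else:
        raise ValueError(f"unknown model {model!r}")
    relabeled = nx.relabel_nodes(g, {u: f"n{u}" for u in g.nodes()})
    net = Network.from_networkx(
        relabeled, order=sorted(relabeled.nodes(), key=lambda s: int(s[1:]))
    )
    from .network import largest_connected_component

    return largest_connected_component(net)


def planted_annotation(
    net: Network,
    target: set | frozenset,
    inside_rate: float,
    outside_rate: float,
    seed: int,
) -> frozenset[str]:
    """Random gene list enriched in ``target``.

    Each target node is annotated with probability ``inside_rate`` and every
    other node with probability ``outside_rate``; with equal rates there is
    no planted signal (null behavior for type-I checks).
    """
    target = set(target)
    if not target <= set(net.nodes):
        raise ValueError("target must be a subset of the network nodes")
    for name, rate in (("inside_rate", inside_rate), ("outside_rate", outside_rate)):
        if not 0 <= rate <= 1:
            raise ValueError(f"{name} must be in [0, 1]")
    rng = np.random.default_rng(seed)
    annotated = set()
    for u in net.nodes:  # node order fixed => draws reproducible per seed
        rate = inside_rate if u in target else outside_rate
        if rng.random() < rate:
            annotated.add(u)
    return frozenset(annotated)
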