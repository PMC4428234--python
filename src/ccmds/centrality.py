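"""Degree and betweenness centrality, and the centrality-correction weights.

The weighted dominating-set objective uses per-node weights

    omega_j = (d_j * b_j) ** (-gamma),

where ``d_j`` is the number of interaction partners of node j and ``b_j`` its
betweenness centrality normalized by (n-1)(n-2)/2, the number of unordered
pairs excluding j. gamma = 0 recovers the unweighted problem; gamma > 0 makes
high-degree, high-betweenness nodes cheaper to select.

``b_j = 0`` (every degree-1 node, among others) would make the weight
infinite, so a floor is applied: b'_j = max(b_j, eps) with
eps = 0.5 / ((n-1)(n-2)/2), half the normalized value of a single geodesic
pair. The floor keeps all weights finite while ranking every zero-betweenness
node strictly below any positive-betweenness node of the same degree.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx

from .network import Network

__all__ = [
    "CentralityTable",
    "WeightVector",
    "degree_centrality",
    "betweenness_centrality",
    "centrality_table",
    "compute_weights",
    "default_betweenness_floor",
]


@dataclass(frozen=True)
class CentralityTable:
    """Per-node degree and normalized betweenness, in network node order."""

    nodes: tuple[str, ...]
    degree: dict[str, int]
    betweenness: dict[str, float]

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "node": list(self.nodes),
                "degree": [self.degree[u] for u in self.nodes],
                "betweenness": [self.betweenness[u] for u in self.nodes],
            }
        )


@dataclass(frozen=True)
class WeightVector:
    """Weights omega_j for one gamma, plus the betweenness floor used."""

    weights: dict[str, float]
    gamma: float
    betweenness_floor: float

    def __getitem__(self, node: str) -> float:
        return self.weights[node]


def degree_centrality(net: Network) -> dict[str, int]:
    """Number of distinct interaction partners of each node (self excluded)."""
    return {u: net.degree(u) for u in net.nodes}


def betweenness_centrality(net: Network) -> dict[str, float]:
    """Betweenness normalized by (n-1)(n-2)/2, endpoints excluded.

    Sum over unordered pairs {i,k} with i != j != k of sigma_ik(j)/sigma_ik.
    Requires a connected network (extract the largest component first);
    networks with fewer than 3 nodes get b_j = 0 throughout.
    """
    if net.n < 3:
        return {u: 0.0 for u in net.nodes}
    g = net.to_networkx()
    if not nx.is_connected(g):
        raise ValueError(
            "betweenness is defined here on connected networks; "
            "extract the largest connected component first"
        )
    # networkx's normalized undirected betweenness divides the unordered-pair
    # sum by (n-1)(n-2)/2 — exactly the normalizer used here.
    return dict(nx.betweenness_centrality(g, normalized=True))


def centrality_table(net: Network) -> CentralityTable:
    return CentralityTable(
        nodes=net.nodes,
        degree=degree_centrality(net),
        betweenness=betweenness_centrality(net),
    )


def default_betweenness_floor(n: int) -> float:
    """eps = 0.5 / ((n-1)(n-2)/2); 0.5 for degenerate n < 3."""
    pairs = (n - 1) * (n - 2) / 2
    return 0.5 / pairs if pairs > 0 else 0.5


def compute_weights(
    cent: CentralityTable,
    gamma: float,
    betweenness_floor: float | None = None,
) -> WeightVector:
    """omega_j = (d_j * max(b_j, eps)) ** (-gamma).

    Every node must have degree >= 1 (true on the largest component of any
    network with >= 2 nodes). gamma must be non-negative.
    """
    if gamma < 0:
        raise ValueError(f"gamma must be >= 0, got {gamma}")
    eps = (
        betweenness_floor
        if betweenness_floor is not None
        else default_betweenness_floor(len(cent.nodes))
    )
    if eps <= 0:
        raise ValueError("betweenness floor must be positive")
    weights: dict[str, float] = {}
    for u in cent.nodes:
        d = cent.degree[u]
        if d < 1:
            raise ValueError(f"node {u!r} has degree 0; weights need d_j >= 1")
        weights[u] = (d * max(cent.betweenness[u], eps)) ** (-gamma)
    return WeightVector(weights=weights, gamma=gamma, betweenness_floor=eps)
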