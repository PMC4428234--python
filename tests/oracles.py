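"""Independent brute-force oracles used only by the tests.

These deliberately avoid the library code paths they check: betweenness by
explicit enumeration of all shortest paths, the hypergeometric tail by direct
summation of the pmf, and the rank-sum null by literal enumeration of every
group assignment.
"""

from __future__ import annotations

from collections import deque
from itertools import combinations
from math import comb

from ccmds.network import Network


def all_shortest_paths(net: Network, source: str, target: str) -> list[tuple[str, ...]]:
    """Every geodesic from source to target, by BFS + predecessor DAG walk."""
    dist = {source: 0}
    preds: dict[str, list[str]] = {source: []}
    queue = deque([source])
    while queue:
        u = queue.popleft()
        for v in sorted(net.neighbors(u)):
            if v not in dist:
                dist[v] = dist[u] + 1
                preds[v] = [u]
                queue.append(v)
            elif dist[v] == dist[u] + 1:
                preds[v].append(u)
    if target not in dist:
        return []
    paths: list[tuple[str, ...]] = []

    def walk(node: str, tail: list[str]) -> None:
        if node == source:
            paths.append(tuple(reversed(tail + [source])))
            return
        for p in preds[node]:
            walk(p, tail + [node])

    walk(target, [])
    return paths


def betweenness_by_enumeration(net: Network) -> dict[str, float]:
    """Normalized betweenness from explicit geodesic enumeration (small n)."""
    n = net.n
    if n < 3:
        return {u: 0.0 for u in net.nodes}
    norm = (n - 1) * (n - 2) / 2
    b = {u: 0.0 for u in net.nodes}
    for i, k in combinations(net.nodes, 2):
        paths = all_shortest_paths(net, i, k)
        if not paths:
            continue
        for j in net.nodes:
            if j in (i, k):
                continue
            through = sum(1 for p in paths if j in p)
            b[j] += through / len(paths)
    return {u: b[u] / norm for u in net.nodes}


def hypergeom_upper_tail(k: int, n_universe: int, n_annotated: int, n_draw: int) -> float:
    """P(X >= k) for X ~ Hypergeom(N, K, n), by direct pmf summation."""
    total = comb(n_universe, n_draw)
    hi = min(n_draw, n_annotated)
    return sum(
        comb(n_annotated, i) * comb(n_universe - n_annotated, n_draw - i)
        for i in range(max(k, 0), hi + 1)
    ) / total


def ranksum_pvalue_by_enumeration(group_in: list[float], group_out: list[float]) -> float:
    """Two-sided rank-sum p by literal enumeration of all group assignments."""
    from scipy.stats import rankdata

    pooled = list(group_in) + list(group_out)
    ranks = rankdata(pooled)
    n_in = len(group_in)
    n = len(pooled)
    w_obs = sum(ranks[:n_in])
    mean = n_in * (n + 1) / 2
    dev = abs(w_obs - mean)
    hits = total = 0
    for subset in combinations(range(n), n_in):
        w = sum(ranks[i] for i in subset)
        total += 1
        if abs(w - mean) >= dev - 1e-9:
            hits += 1
    return hits / total


def dominating_sets_by_brute_force(net: Network) -> list[frozenset[str]]:
    """All minimum dominating sets by direct definition checking."""

    def dominates(cand: set[str]) -> bool:
        return all(u in cand or net.neighbors(u) & cand for u in net.nodes)

    for size in range(1, net.n + 1):
        found = [
            frozenset(c) for c in combinations(net.nodes, size) if dominates(set(c))
        ]
        if found:
            return found
    return []
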