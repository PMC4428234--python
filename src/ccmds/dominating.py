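"""Minimum dominating set solvers: exact integer programs, an exhaustive
oracle for small graphs, and a greedy degree-ranked comparator.

The unweighted problem minimizes sum_j x_j subject to
sum_j A_ij x_j >= 1 for every node i, with x_j binary and A_ii = 1 (each node
covers itself). The centrality-corrected variant replaces the objective by
sum_j omega_j x_j with the same constraints, so any optimum is still a
dominating set; with well-chosen weights it is also minimum-cardinality.

Both programs are solved by HiGHS branch-and-bound through
``scipy.optimize.milp``, which proves optimality (zero gap). Variables are
created in canonical node order, so a given backend is deterministic across
runs.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy.optimize import Bounds, LinearConstraint, milp
from scipy.sparse import lil_matrix

from .centrality import WeightVector
from .network import Network, closed_adjacency

__all__ = [
    "DominatingSet",
    "SolverError",
    "is_dominating",
    "solve_mds",
    "solve_ccmds",
    "enumerate_minimum_dominating_sets",
    "enumerate_weighted_optima",
    "greedy_dominating_set",
]

SOLVER_ID = "scipy-highs"


class SolverError(RuntimeError):
    """MILP backend failed to prove an optimum."""


@dataclass(frozen=True)
class DominatingSet:
    """A solver result: members, objective, and provenance.

    ``objective`` is |members| for the unweighted program and
    sum of member weights for the weighted one. ``proven_optimal`` is True
    only for exact branch-and-bound results.
    """

    members: frozenset[str]
    objective: float
    gamma: float | None
    proven_optimal: bool
    solver_id: str


def is_dominating(net: Network, candidate: frozenset[str] | set[str]) -> bool:
    """True iff every node's closed neighborhood intersects ``candidate``."""
    unknown = set(candidate) - set(net.nodes)
    if unknown:
        raise ValueError(f"candidate contains unknown labels: {sorted(unknown)}")
    cand = set(candidate)
    for u in net.nodes:
        if u in cand or net.neighbors(u) & cand:
            continue
        return False
    return True


def _solve_binary_program(net: Network, costs: np.ndarray) -> tuple[frozenset[str], float]:
    """Minimize costs @ x subject to closed-neighborhood cover constraints."""
    n = net.n
    index = {u: j for j, u in enumerate(net.nodes)}
    closed = closed_adjacency(net)
    a = lil_matrix((n, n), dtype=np.int8)
    for i, u in enumerate(net.nodes):
        for v in closed[u]:
            a[i, index[v]] = 1
    res = milp(
        c=costs,
        constraints=LinearConstraint(a.tocsr(), lb=np.ones(n), ub=np.inf),
        integrality=np.ones(n),
        bounds=Bounds(0, 1),
    )
    if not res.success or res.status != 0:
        raise SolverError(f"MILP backend failed: status={res.status} ({res.message})")
    x = np.rint(res.x).astype(int)
    members = frozenset(u for u, j in index.items() if x[j] == 1)
    return members, float(costs @ x)


def solve_mds(net: Network) -> DominatingSet:
    """Exact minimum-cardinality dominating set via branch-and-bound."""
    members, obj = _solve_binary_program(net, np.ones(net.n))
    ds = DominatingSet(
        members=members,
        objective=obj,
        gamma=None,
        proven_optimal=True,
        solver_id=SOLVER_ID,
    )
    assert is_dominating(net, ds.members)
    return ds


def solve_ccmds(net: Network, weights: WeightVector) -> DominatingSet:
    """Exact minimum-weight dominating set under the centrality weights."""
    missing = set(net.nodes) - set(weights.weights)
    if missing:
        raise ValueError(f"nodes missing a weight: {sorted(missing)}")
    costs = np.array([weights[u] for u in net.nodes], dtype=float)
    members, obj = _solve_binary_program(net, costs)
    ds = DominatingSet(
        members=members,
        objective=obj,
        gamma=weights.gamma,
        proven_optimal=True,
        solver_id=SOLVER_ID,
    )
    assert is_dominating(net, ds.members)
    return ds


def enumerate_minimum_dominating_sets(
    net: Network, max_n: int = 20
) -> list[frozenset[str]]:
    """All dominating sets of minimum cardinality, by exhaustive subset search.

    Brute-force oracle for small graphs; subsets are tested in increasing
    size and results returned in canonical sorted order.
    """
    if net.n > max_n:
        raise ValueError(f"enumeration guard: n={net.n} exceeds max_n={max_n}")
    nodes = net.nodes
    for k in range(1, net.n + 1):
        found = [
            frozenset(c) for c in combinations(nodes, k) if is_dominating(net, set(c))
        ]
        if found:
            return sorted(found, key=lambda s: tuple(sorted(s)))
    return [frozenset()] if net.n == 0 else []


def enumerate_weighted_optima(
    net: Network, weights: WeightVector, max_n: int = 20
) -> list[frozenset[str]]:
    """Among all dominating sets, those minimizing the weighted objective.

    Exhaustive oracle used to verify the weighted integer program on small
    graphs. Searches all subset sizes (a weighted optimum need not be
    minimum-cardinality for arbitrary weights).
    """
    if net.n > max_n:
        raise ValueError(f"enumeration guard: n={net.n} exceeds max_n={max_n}")
    best: list[frozenset[str]] = []
    best_obj = float("inf")
    for k in range(1, net.n + 1):
        for c in combinations(net.nodes, k):
            if not is_dominating(net, set(c)):
                continue
            obj = sum(weights[u] for u in c)
            if obj < best_obj - 1e-12:
                best, best_obj = [frozenset(c)], obj
            elif abs(obj - best_obj) <= 1e-12:
                best.append(frozenset(c))
    return sorted(best, key=lambda s: tuple(sorted(s)))


def greedy_dominating_set(net: Network, ranking: dict[str, float]) -> DominatingSet:
    """Degree-ranked greedy comparator (the DS-DC heuristic style).

    Repeatedly picks the node covering the most not-yet-dominated nodes;
    ties broken by higher ranking score, then label order. Not guaranteed
    minimal.
    """
    missing = set(net.nodes) - set(ranking)
    if missing:
        raise ValueError(f"nodes missing a ranking score: {sorted(missing)}")
    closed = closed_adjacency(net)
    uncovered = set(net.nodes)
    members: set[str] = set()
    while uncovered:
        best = max(
            (u for u in net.nodes if u not in members),
            key=lambda u: (len(closed[u] & uncovered), ranking[u], _neg_label(u)),
        )
        members.add(best)
        uncovered -= closed[best]
    ds = DominatingSet(
        members=frozenset(members),
        objective=float(len(members)),
        gamma=None,
        proven_optimal=False,
        solver_id="greedy",
    )
    assert is_dominating(net, ds.members)
    return ds


class _neg_label(str):
    """Reverse-ordering wrapper so max() prefers the smaller label on ties."""

    def __lt__(self, other):  # type: ignore[override]
        return str.__gt__(self, other)

    def __gt__(self, other):  # type: ignore[override]
        return str.__lt__(self, other)
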