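"""Grid search over the centrality-correction exponent gamma.

The exponent is selected by two criteria: it should be as large as possible
(so the model favors high-degree, high-betweenness nodes), while the weighted
optimum must stay the same size as the plain minimum dominating set — i.e.
the selected solution is still an MDS, just the one with the most central
members. The scan solves one weighted program per grid point with
centralities computed once.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np

from .centrality import centrality_table, compute_weights
from .dominating import DominatingSet, solve_ccmds, solve_mds
from .evaluation import jaccard
from .network import Network

logger = logging.getLogger(__name__)

__all__ = ["GammaScan", "default_grid", "gamma_scan", "select_gamma"]


def default_grid() -> tuple[float, ...]:
    """gamma in {0, 0.05, 0.10, ..., 1.00}."""
    return tuple(round(0.05 * i, 2) for i in range(21))


@dataclass(frozen=True)
class GammaScan:
    """Per-grid-point weighted solutions, sizes, and pairwise overlap."""

    grid: tuple[float, ...]
    solutions: tuple[DominatingSet, ...]
    size_profile: tuple[int, ...]
    overlap: np.ndarray  # pairwise Jaccard matrix, grid order

    def solution_at(self, gamma: float) -> DominatingSet:
        for g, sol in zip(self.grid, self.solutions):
            if math.isclose(g, gamma, abs_tol=1e-9):
                return sol
        raise KeyError(f"gamma {gamma} not in scanned grid")


def gamma_scan(net: Network, grid: tuple[float, ...] | None = None) -> GammaScan:
    """Solve the weighted program at each grid gamma and record overlaps."""
    grid = tuple(grid) if grid is not None else default_grid()
    if not grid:
        raise ValueError("gamma grid must be non-empty")
    if any(g < 0 for g in grid):
        raise ValueError("gamma grid values must be >= 0")
    cent = centrality_table(net)
    solutions: list[DominatingSet] = []
    for g in grid:
        try:
            solutions.append(solve_ccmds(net, compute_weights(cent, g)))
        except Exception as exc:
            raise RuntimeError(f"weighted solve failed at gamma={g}") from exc
    k = len(grid)
    overlap = np.ones((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            overlap[i, j] = overlap[j, i] = jaccard(
                solutions[i].members, solutions[j].members
            )
    return GammaScan(
        grid=grid,
        solutions=tuple(solutions),
        size_profile=tuple(len(s.members) for s in solutions),
        overlap=overlap,
    )


def select_gamma(scan: GammaScan) -> float:
    """Largest grid gamma whose solution size equals the plain MDS size.

    All grid points are checked; no monotonicity of the size profile is
    assumed. If no positive gamma qualifies, 0 is returned with a warning
    (the correction then degenerates to the plain model).
    """
    try:
        i0 = next(i for i, g in enumerate(scan.grid) if math.isclose(g, 0.0, abs_tol=1e-9))
    except StopIteration:
        raise ValueError("scan must include gamma = 0 (the plain MDS size)") from None
    mds_size = scan.size_profile[i0]
    candidates = [
        g for g, size in zip(scan.grid, scan.size_profile) if size == mds_size
    ]
    gamma_star = max(candidates)
    if gamma_star == 0.0 and len(scan.grid) > 1:
        warnings.warn(
            "no gamma > 0 preserves the minimum dominating set size; "
            "returning 0 (correction disabled)",
            stacklevel=2,
        )
    return gamma_star


def auto_solve(net: Network, grid: tuple[float, ...] | None = None):
    """Scan, select gamma*, and return (scan, gamma*, solution at gamma*).

    Convenience wrapper used by the pipeline; guarantees the returned
    solution has plain-MDS cardinality.
    """
    scan = gamma_scan(net, grid)
    gamma_star = select_gamma(scan)
    sol = scan.solution_at(gamma_star)
    mds = solve_mds(net)
    if len(sol.members) != int(mds.objective):
        raise AssertionError(
            "selection invariant violated: weighted optimum at gamma* "
            "is not minimum-cardinality"
        )
    return scan, gamma_star, sol
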