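"""Evaluation battery for driver-protein sets.

Covers the comparisons applied to dominating-set models on PPI networks:
Jaccard overlap between driver sets, targeted-attack robustness curves,
two-sided Wilcoxon rank-sum comparison of centrality populations,
hypergeometric (one-sided Fisher) enrichment against gene lists,
Bonferroni-corrected per-term enrichment, and per-protein membership counts
in annotation sets (complexes, GO terms).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
from scipy import stats

from .network import Network

__all__ = [
    "AttackCurve",
    "AttackRecord",
    "EnrichmentResult",
    "RankSumResult",
    "AnnotationMap",
    "jaccard",
    "attack_curve",
    "rank_sum_compare",
    "enrichment_test",
    "term_enrichment",
    "membership_counts",
    "read_annotation",
]

EXACT_RANKSUM_LIMIT = 400  # exact null when n_in * n_out <= this


def jaccard(a: set | frozenset, b: set | frozenset) -> float:
    """|a & b| / |a | b|; two empty sets overlap perfectly (1.0)."""
    a, b = set(a), set(b)
    union = a | b
    if not union:
        return 1.0
    return len(a & b) / len(union)


@dataclass(frozen=True)
class AttackRecord:
    k: int  # number of nodes deleted so far
    components: int
    lcc_fraction: float  # LCC size / original node count


@dataclass(frozen=True)
class AttackCurve:
    records: tuple[AttackRecord, ...]

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            [(r.k, r.components, r.lcc_fraction) for r in self.records],
            columns=["deleted", "components", "lcc_fraction"],
        )


def attack_curve(net: Network, targets: list[str]) -> AttackCurve:
    """Successively delete ``targets`` and track fragmentation.

    The caller orders the targets (for driver sets: by degree descending,
    ties by label). After each single deletion the number of connected
    components and the largest-component fraction of the *original* node
    count are recorded; the k = 0 record describes the intact network.
    Unknown or repeated labels are an error, not a no-op.
    """
    seen: set[str] = set()
    for t in targets:
        if not net.has_node(t):
            raise ValueError(f"attack target {t!r} not in network")
        if t in seen:
            raise ValueError(f"attack target {t!r} repeated")
        seen.add(t)
    n0 = net.n
    g = net.to_networkx()
    records = [_attack_record(0, g, n0)]
    for k, t in enumerate(targets, start=1):
        g.remove_node(t)
        records.append(_attack_record(k, g, n0))
    return AttackCurve(tuple(records))


def _attack_record(k: int, g: nx.Graph, n0: int) -> AttackRecord:
    if g.number_of_nodes() == 0:
        return AttackRecord(k, 0, 0.0)
    comps = list(nx.connected_components(g))
    return AttackRecord(k, len(comps), max(len(c) for c in comps) / n0)


def sort_for_attack(net: Network, members: set | frozenset) -> list[str]:
    """Driver set ordered by degree descending, ties by label."""
    return sorted(members, key=lambda u: (-net.degree(u), u))


@dataclass(frozen=True)
class RankSumResult:
    statistic: float  # rank sum of group_in over the pooled mid-ranks
    p_value: float
    two_sided: bool
    n_in: int
    n_out: int
    exact: bool
    median_difference: float  # median(group_in) - median(group_out)


def rank_sum_compare(group_in: list[float], group_out: list[float]) -> RankSumResult:
    """Two-sided Wilcoxon rank-sum test with mid-ranks for ties.

    The null distribution is exact (full enumeration of rank assignments,
    computed by dynamic programming) when n_in * n_out <= 400; otherwise the
    tie-corrected normal approximation with continuity correction is used.
    """
    x = np.asarray(group_in, dtype=float)
    y = np.asarray(group_out, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    w = float(ranks[: x.size].sum())
    exact = x.size * y.size <= EXACT_RANKSUM_LIMIT
    if exact:
        p = _exact_ranksum_pvalue(ranks, x.size, w)
    else:
        p = float(
            stats.mannwhitneyu(
                x, y, alternative="two-sided", method="asymptotic"
            ).pvalue
        )
    return RankSumResult(
        statistic=w,
        p_value=min(1.0, p),
        two_sided=True,
        n_in=int(x.size),
        n_out=int(y.size),
        exact=exact,
        median_difference=float(np.median(x) - np.median(y)),
    )


def _exact_ranksum_pvalue(ranks: np.ndarray, n_in: int, w_obs: float) -> float:
    """P(|W - E[W]| >= |w_obs - E[W]|) under uniform group assignment.

    Counts, for every achievable rank sum, the number of size-n_in subsets of
    the pooled mid-ranks attaining it — a subset-sum dynamic program that is
    mathematically identical to enumerating all C(N, n_in) assignments.
    Mid-ranks are doubled so sums are integers even with ties.
    """
    scaled = np.rint(2 * ranks).astype(np.int64)
    total = int(scaled.sum())
    n = len(scaled)
    # table[c, s] = number of subsets of size c with scaled rank sum s
    table = np.zeros((n_in + 1, total + 1))
    table[0, 0] = 1.0
    for r in scaled:
        table[1:, r:] += table[:-1, : total + 1 - r]
    counts = table[n_in]
    n_subsets = counts.sum()  # = C(n, n_in)
    mean = n_in * (total / n)
    dev = abs(2 * w_obs - mean)
    sums = np.arange(total + 1)
    extreme = np.abs(sums - mean) >= dev - 1e-9
    return float(counts[extreme].sum() / n_subsets)


@dataclass(frozen=True)
class EnrichmentResult:
    """One-sided over-representation test on a 2x2 membership table."""

    term: str | None
    overlap_count: int  # k = |driver & annotated|
    set_size: int  # K = |driver|
    annotated_in_universe: int  # n_a
    universe_size: int  # N
    odds_ratio: float
    p_value: float
    corrected_p: float | None = None
    significant: bool | None = None


def enrichment_test(
    driver: set | frozenset,
    annotated: set | frozenset,
    universe: set | frozenset,
    term: str | None = None,
) -> EnrichmentResult:
    """Fisher's exact over-representation test of ``annotated`` in ``driver``.

    ``annotated`` is intersected with ``universe`` first; ``driver`` must be
    a subset of ``universe``. The p-value is the hypergeometric upper tail
    P(X >= k) of the overlap. The sample odds ratio carries a 0.5 continuity
    correction whenever a table cell is zero.
    """
    driver, universe = set(driver), set(universe)
    if not driver <= universe:
        raise ValueError("driver set must be a subset of the universe")
    annotated = set(annotated) & universe
    n_univ = len(universe)
    n_a = len(annotated)
    k_set = len(driver)
    k = len(driver & annotated)
    p = float(stats.hypergeom.sf(k - 1, n_univ, n_a, k_set))
    a, b = k, k_set - k
    c, d = n_a - k, n_univ - k_set - (n_a - k)
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    odds = (a * d) / (b * c)
    return EnrichmentResult(
        term=term,
        overlap_count=k,
        set_size=k_set,
        annotated_in_universe=n_a,
        universe_size=n_univ,
        odds_ratio=float(odds),
        p_value=min(1.0, p),
    )


@dataclass(frozen=True)
class AnnotationMap:
    """Bidirectional term <-> protein annotation index."""

    term_to_proteins: dict[str, frozenset[str]]
    protein_to_terms: dict[str, frozenset[str]]

    @classmethod
    def from_pairs(cls, pairs: list[tuple[str, str]]) -> "AnnotationMap":
        """Build from (protein, term) pairs."""
        t2p: dict[str, set[str]] = {}
        p2t: dict[str, set[str]] = {}
        for protein, term in pairs:
            t2p.setdefault(term, set()).add(protein)
            p2t.setdefault(protein, set()).add(term)
        return cls(
            {t: frozenset(s) for t, s in t2p.items()},
            {p: frozenset(s) for p, s in p2t.items()},
        )

    @property
    def terms(self) -> tuple[str, ...]:
        return tuple(sorted(self.term_to_proteins))


def read_annotation(path: str | Path, flat_term: str | None = None) -> AnnotationMap:
    """Read a two-column (protein TAB term) file, or a one-gene-per-line flat
    list treated as the single term ``flat_term`` (default: the file stem)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"annotation file not found: {path}")
    pairs: list[tuple[str, str]] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) == 1:
                pairs.append((fields[0], flat_term or path.stem))
            elif len(fields) >= 2:
                pairs.append((fields[0], fields[1]))
            else:
                raise ValueError(f"{path}:{lineno}: empty annotation line")
    return AnnotationMap.from_pairs(pairs)


def term_enrichment(
    driver: set | frozenset,
    annotations: AnnotationMap,
    universe: set | frozenset,
    alpha: float = 0.01,
) -> list[EnrichmentResult]:
    """Per-term over-representation with Bonferroni correction.

    Terms with no annotated member inside the universe are skipped; the
    Bonferroni factor m is the number of terms actually tested. A term is
    flagged significant when m * p < alpha (corrected p capped at 1).
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    universe = set(universe)
    tested = [
        (term, proteins & universe)
        for term, proteins in sorted(annotations.term_to_proteins.items())
        if proteins & universe
    ]
    m = len(tested)
    results = []
    for term, annotated in tested:
        r = enrichment_test(driver, annotated, universe, term=term)
        corrected = min(1.0, m * r.p_value)
        results.append(
            EnrichmentResult(
                term=r.term,
                overlap_count=r.overlap_count,
                set_size=r.set_size,
                annotated_in_universe=r.annotated_in_universe,
                universe_size=r.universe_size,
                odds_ratio=r.odds_ratio,
                p_value=r.p_value,
                corrected_p=corrected,
                significant=corrected < alpha,
            )
        )
    return results


def membership_counts(
    proteins: set | frozenset, annotations: AnnotationMap
) -> dict[str, int]:
    """Number of annotation terms (e.g. complexes) containing each protein;
    proteins absent from the map count 0."""
    return {p: len(annotations.protein_to_terms.get(p, ())) for p in proteins}
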