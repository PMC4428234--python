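"""Overlap, attack robustness, rank-sum and enrichment statistics."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ccmds.evaluation import (
    AnnotationMap,
    attack_curve,
    enrichment_test,
    jaccard,
    membership_counts,
    rank_sum_compare,
    read_annotation,
    sort_for_attack,
    term_enrichment,
)
from ccmds.network import Network
from oracles import hypergeom_upper_tail, ranksum_pvalue_by_enumeration


class TestJaccard:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            ({"x", "y"}, {"x", "y"}, 1.0),
            ({"x"}, {"y"}, 0.0),
            (set(), set(), 1.0),
            ({"x", "y", "z"}, {"y", "z", "w"}, 0.5),
        ],
    )
    def test_values(self, a, b, expected):
        assert jaccard(a, b) == pytest.approx(expected)

    @given(st.sets(st.integers(0, 20)), st.sets(st.integers(0, 20)))
    @settings(deadline=None, derandomize=True)
    def test_symmetric_and_reflexive(self, a, b):
        assert jaccard(a, b) == jaccard(b, a)
        assert jaccard(a, a) == 1.0
        assert 0.0 <= jaccard(a, b) <= 1.0

    def test_driver_set_overlap_scale(self):
        """Two 1,407-member driver sets sharing 965 proteins overlap 0.5219."""
        a = {f"p{i}" for i in range(1407)}
        b = {f"p{i}" for i in range(965)} | {f"q{i}" for i in range(442)}
        assert jaccard(a, b) == pytest.approx(965 / 1849)
        assert round(jaccard(a, b), 4) == 0.5219


class TestAttackCurve:
    def test_star_center_deletion(self):
        net = Network.from_edges([("c", f"l{i}") for i in range(4)])  # n = 5
        curve = attack_curve(net, ["c"])
        assert curve.records[0].components == 1
        assert curve.records[0].lcc_fraction == 1.0
        assert curve.records[1].components == 4
        assert curve.records[1].lcc_fraction == pytest.approx(0.2)

    def test_fig1_driver_deletion(self, fig1):
        curve = attack_curve(fig1, ["5", "6"])
        last = curve.records[-1]
        assert last.components == 2
        assert last.lcc_fraction == pytest.approx(0.4)

    def test_monotone_lcc_and_component_bounds(self, fig1):
        targets = sort_for_attack(fig1, set(fig1.nodes[:6]))
        curve = attack_curve(fig1, targets)
        fracs = [r.lcc_fraction for r in curve.records]
        assert all(a >= b for a, b in zip(fracs, fracs[1:]))
        for r in curve.records[:-1]:
            assert 1 <= r.components <= fig1.n - r.k

    def test_sort_for_attack_degree_desc_then_label(self, fig1):
        order = sort_for_attack(fig1, {"1", "5", "6", "2"})
        assert order == ["5", "6", "1", "2"]

    def test_unknown_and_repeated_targets_rejected(self, fig1):
        with pytest.raises(ValueError):
            attack_curve(fig1, ["zz"])
        with pytest.raises(ValueError):
            attack_curve(fig1, ["5", "5"])


class TestRankSum:
    def test_clear_separation_exact(self):
        r = rank_sum_compare([1, 2, 3], [4, 5, 6])
        assert r.exact
        assert r.p_value == pytest.approx(0.1)  # 2 / C(6,3)

    def test_identical_values_p_one(self):
        assert rank_sum_compare([5], [5]).p_value == pytest.approx(1.0)
        same = list(range(1, 11))
        assert rank_sum_compare(same, same).p_value == pytest.approx(1.0)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            rank_sum_compare([], [1.0])

    def test_exact_branch_matches_literal_enumeration(self):
        """DP null distribution == brute-force enumeration, ties included."""
        cases = [
            ([1, 2, 3], [4, 5, 6]),
            ([1, 1, 2], [2, 3, 3]),  # ties across groups
            ([3, 1, 4, 1], [5, 9, 2, 6]),
            ([2.5, 2.5], [2.5, 7, 8, 9]),
            ([10, 20, 30, 40, 50, 60], [15, 25, 35, 45, 55, 65]),
        ]
        for x, y in cases:
            got = rank_sum_compare(x, y)
            assert got.exact
            assert got.p_value == pytest.approx(
                ranksum_pvalue_by_enumeration(x, y), abs=1e-12
            )

    def test_asymptotic_branch_engages_and_is_sane(self):
        x = list(range(50))
        y = [v + 5 for v in range(50)]
        r = rank_sum_compare(x, y)
        assert not r.exact
        assert 0 < r.p_value <= 1
        assert r.median_difference == pytest.approx(-5.0)

    def test_exact_and_asymptotic_agree_roughly(self):
        x = [1, 4, 6, 9, 12, 15, 18, 21, 24, 27]
        y = [2, 5, 7, 10, 13, 16, 19, 22, 25, 28]
        exact = rank_sum_compare(x, y)
        assert exact.exact
        from scipy.stats import mannwhitneyu

        approx = mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        assert exact.p_value == pytest.approx(approx.pvalue, rel=0.15)


class TestEnrichment:
    def test_small_worked_example(self, fig1):
        universe = set(fig1.nodes)
        r = enrichment_test({"5", "6"}, {"5", "6"}, universe)
        assert r.overlap_count == 2
        assert r.p_value == pytest.approx(1 / 45)

    def test_zero_overlap_p_one(self, fig1):
        universe = set(fig1.nodes)
        r = enrichment_test({"5", "6"}, {"7"}, universe)
        assert r.p_value == pytest.approx(1.0)

    def test_driver_outside_universe_rejected(self, fig1):
        with pytest.raises(ValueError):
            enrichment_test({"zz"}, set(), set(fig1.nodes))

    def test_annotated_restricted_to_universe(self, fig1):
        universe = set(fig1.nodes)
        r = enrichment_test({"5"}, {"5", "external1", "external2"}, universe)
        assert r.annotated_in_universe == 1

    def test_matches_hypergeometric_summation_oracle(self):
        """Exhaustive 2x2 sweep, N <= 60, against direct tail summation."""
        for n_univ in (5, 11, 23, 41, 60):
            ordered = [f"u{i}" for i in range(n_univ)]
            universe = set(ordered)
            for k_set, n_a in itertools.product((1, 2, n_univ // 2, n_univ - 1), repeat=2):
                for k in range(0, min(k_set, n_a) + 1):
                    driver = set(ordered[:k]) | {
                        f"u{i}" for i in range(n_a, n_a + k_set - k)
                    }
                    if len(driver) != k_set or not driver <= universe:
                        continue
                    annotated = set(ordered[:n_a])
                    r = enrichment_test(driver, annotated, universe)
                    assert r.overlap_count == k
                    assert r.p_value == pytest.approx(
                        hypergeom_upper_tail(k, n_univ, n_a, k_set), abs=1e-10
                    )

    def test_odds_ratio_continuity_correction(self, fig1):
        universe = set(fig1.nodes)
        r = enrichment_test({"5", "6"}, {"5", "6"}, universe)  # two zero cells
        assert r.odds_ratio == pytest.approx((2.5 * 8.5) / (0.5 * 0.5))


class TestTermEnrichment:
    def test_single_term_correction_is_identity(self, fig1):
        amap = AnnotationMap.from_pairs([("5", "T"), ("6", "T")])
        res = term_enrichment({"5", "6"}, amap, set(fig1.nodes))
        assert len(res) == 1
        assert res[0].corrected_p == pytest.approx(res[0].p_value)

    def test_bonferroni_factor_counts_tested_terms(self, fig1):
        pairs = [("5", "T0"), ("6", "T0")]
        pairs += [(str(i), f"T{i}") for i in range(1, 5)]
        pairs += [("external", "Tx")]  # zero members in universe: skipped
        amap = AnnotationMap.from_pairs(pairs)
        res = term_enrichment({"5", "6"}, amap, set(fig1.nodes))
        assert len(res) == 5  # Tx dropped
        t0 = next(r for r in res if r.term == "T0")
        assert t0.corrected_p == pytest.approx(min(1.0, 5 * t0.p_value))

    def test_significance_flag_arithmetic(self, fig1):
        # m * p = 5 * (1/45) = 1/9 > 0.01 -> not significant at alpha = 0.01
        pairs = [("5", "T0"), ("6", "T0")] + [
            (str(i), f"T{i}") for i in range(1, 5)
        ]
        amap = AnnotationMap.from_pairs(pairs)
        res = term_enrichment({"5", "6"}, amap, set(fig1.nodes), alpha=0.2)
        t0 = next(r for r in res if r.term == "T0")
        assert t0.significant == (t0.corrected_p < 0.2)

    def test_alpha_validated(self, fig1):
        amap = AnnotationMap.from_pairs([("5", "T")])
        with pytest.raises(ValueError):
            term_enrichment({"5"}, amap, set(fig1.nodes), alpha=1.5)


class TestAnnotationMap:
    def test_bidirectional_consistency(self):
        amap = AnnotationMap.from_pairs(
            [("p1", "A"), ("p1", "B"), ("p2", "A"), ("p3", "C")]
        )
        for term, proteins in amap.term_to_proteins.items():
            for p in proteins:
                assert term in amap.protein_to_terms[p]
        for p, terms in amap.protein_to_terms.items():
            for term in terms:
                assert p in amap.term_to_proteins[term]

    def test_membership_counts(self):
        amap = AnnotationMap.from_pairs([("p1", "A"), ("p1", "B"), ("p1", "C"), ("p2", "A")])
        counts = membership_counts({"p1", "p2", "p9"}, amap)
        assert counts == {"p1": 3, "p2": 1, "p9": 0}

    def test_read_two_column_and_flat(self, tmp_path):
        two = tmp_path / "complexes.tsv"
        two.write_text("p1\tA\np2\tA\np1\tB\n")
        amap = read_annotation(two)
        assert amap.term_to_proteins["A"] == {"p1", "p2"}
        flat = tmp_path / "essential.txt"
        flat.write_text("g1\ng2\n# comment\ng3\n")
        amap2 = read_annotation(flat)
        assert amap2.term_to_proteins["essential"] == {"g1", "g2", "g3"}
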