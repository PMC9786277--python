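"""Annotation scoring: EASE enrichment, evidence assembly, classification,
coverage percentages."""

from math import comb

import numpy as np
import pytest

from genodrug.annotate import (
    classify_risk_genes,
    coverage_report,
    criterion_coverage,
    ease_score,
    enrich_sets,
    assemble_evidence,
    round_half_up,
    score_genes,
)
from genodrug.datasets import (
    CRITERION_COUNTS,
    SCORE_DISTRIBUTION,
    figure1_evidence,
    figure1_scores,
)
from genodrug.records import AnnotationTable, GeneEvidence, GeneScore


def hypergeom_upper_tail(x_min: int, N: int, K: int, n: int) -> float:
    """Independent oracle: P(X >= x_min) by exhaustive pmf summation."""
    total = comb(N, n)
    return sum(
        comb(K, x) * comb(N - K, n - x)
        for x in range(max(x_min, 0), min(K, n) + 1)
        if n - x <= N - K
    ) / total


class TestEaseScore:
    def test_overlap_of_one_or_zero_is_exactly_one(self):
        assert ease_score(1, 10, 5, 100) == 1.0
        assert ease_score(0, 10, 5, 100) == 1.0

    def test_small_example_matches_enumeration(self):
        # k=3, n=5, K=4, N=20: EASE tail starts at x = 2
        assert ease_score(3, 5, 4, 20) == pytest.approx(
            hypergeom_upper_tail(2, 20, 4, 5), abs=1e-12
        )

    def test_fisher_variant_matches_enumeration(self):
        assert ease_score(3, 5, 4, 20, method="fisher") == pytest.approx(
            hypergeom_upper_tail(3, 20, 4, 5), abs=1e-12
        )
        assert ease_score(0, 5, 4, 20, method="fisher") == 1.0

    def test_monotone_nonincreasing_in_k(self):
        n, K, N = 12, 9, 40
        values = [ease_score(k, n, K, N) for k in range(0, min(n, K) + 1)]
        assert all(a >= b - 1e-12 for a, b in zip(values, values[1:]))

    def test_invalid_arguments_raise(self):
        with pytest.raises(ValueError):
            ease_score(5, 4, 10, 20)  # k > n
        with pytest.raises(ValueError):
            ease_score(1, 5, 25, 20)  # K > N
        with pytest.raises(ValueError):
            ease_score(1, 2, 3, 4, method="bogus")


class TestEnrichSets:
    BACKGROUND = {f"B{i}" for i in range(40)} | {"X1", "X2", "X3", "X4"}

    def test_disjoint_sets_give_empty_result(self):
        res = enrich_sets({"X1", "X2"}, {"s": {"B1", "B2"}}, self.BACKGROUND)
        assert res == []

    def test_whole_list_set_matches_enumeration(self):
        query = {"X1", "X2", "X3", "X4"}
        res = enrich_sets(query, {"s": query}, self.BACKGROUND, p_cut=1.0)
        (r,) = res
        N, K, n, k = len(self.BACKGROUND), 4, 4, 4
        assert r.ease_p == pytest.approx(hypergeom_upper_tail(3, N, K, n), abs=1e-12)

    def test_p_cut_one_returns_every_overlapping_set(self):
        sets = {"a": {"X1"}, "b": {"X2", "B1"}, "c": {"B5"}}
        res = enrich_sets({"X1", "X2"}, sets, self.BACKGROUND, p_cut=1.0)
        assert {r.set_id for r in res} == {"a", "b"}
        assert all(r.ease_p == 1.0 for r in res)  # overlaps of one

    def test_results_sorted_by_p_then_id(self):
        query = {"X1", "X2", "X3", "X4"}
        sets = {"big": query, "alt": query, "tiny": {"X1"}}
        res = enrich_sets(query, sets, self.BACKGROUND, p_cut=1.0)
        assert [r.set_id for r in res] == ["alt", "big", "tiny"]

    def test_empty_background_raises(self):
        with pytest.raises(ValueError):
            enrich_sets(set(), {}, set())

    def test_query_outside_background_raises(self):
        with pytest.raises(ValueError):
            enrich_sets({"NOPE"}, {}, self.BACKGROUND)


class TestAssembleEvidence:
    def _table(self):
        return AnnotationTable(
            missense_genes=frozenset({"A"}),
            eqtl_rows=(
                ("A", "whole blood", True),
                ("B", "liver", True),
                ("C", "whole blood", False),
            ),
            go_rows=(("A", "GO:1", "BP"), ("A", "GO:2", "MF"), ("B", "GO:3", "CC")),
            background_genes=frozenset({"A", "B", "C", "Z"}),
            kegg_sets={"path1": frozenset({"A", "Z"})},
        )

    def test_absent_gene_is_all_false(self):
        (e,) = assemble_evidence(["UNSEEN"], self._table(), [])
        assert e.criteria() == (False,) * 6

    def test_tissue_gate_excludes_other_tissues_and_nonsignificant(self):
        ev = {e.gene: e for e in assemble_evidence(["A", "B", "C"], self._table(), [])}
        assert ev["A"].cis_eqtl is True
        assert ev["B"].cis_eqtl is False  # liver only
        assert ev["C"].cis_eqtl is False  # not significant

    def test_kegg_requires_enriched_set_membership(self):
        from genodrug.records import EnrichmentResult

        table = self._table()
        without = assemble_evidence(["A"], table, [])
        assert without[0].kegg is False
        hit = EnrichmentResult("path1", 2, 3, 2, 4, 0.01)
        with_hit = assemble_evidence(["A"], table, [hit])
        assert with_hit[0].kegg is True

    def test_go_namespaces_fill_independently(self):
        (e,) = assemble_evidence(["A"], self._table(), [])
        assert (e.go_bp, e.go_cc, e.go_mf) == (True, False, True)


class TestScoring:
    def test_all_false_scores_zero(self):
        (s,) = score_genes([GeneEvidence("G1")])
        assert s.score == 0 and not s.is_risk_gene

    def test_five_criteria_score_five(self):
        (s,) = score_genes(
            [GeneEvidence("ARID5B", True, True, True, True, True, False)]
        )
        assert s.score == 5 and s.is_risk_gene

    def test_all_true_scores_six(self):
        (s,) = score_genes([GeneEvidence("G1", *([True] * 6))])
        assert s.score == 6

    def test_sorted_by_score_then_gene(self):
        ev = [
            GeneEvidence("B", True, True, False, False, False, False),
            GeneEvidence("A", True, True, False, False, False, False),
            GeneEvidence("C", True, True, True, False, False, False),
        ]
        assert [s.gene for s in score_genes(ev)] == ["C", "A", "B"]

    def test_classify_matches_brute_force_on_random_scores(self, rng):
        for _ in range(20):
            scores = [
                GeneScore(f"G{i}", int(s), bool(s >= 2))
                for i, s in enumerate(rng.integers(0, 7, size=40))
            ]
            assert classify_risk_genes(scores) == {s.gene for s in scores if s.score >= 2}

    def test_classify_empty_input(self):
        assert classify_risk_genes([]) == set()


class TestCoverage:
    def test_published_marginals_and_percentages(self):
        cov = coverage_report(figure1_evidence())
        assert cov["kegg"] == (5, 8.8)
        assert cov["missense"] == (7, 12.3)
        assert cov["cis_eqtl"] == (12, 21.1)
        assert cov["go_bp"] == (30, 52.6)
        assert cov["go_cc"] == (36, 63.2)
        assert cov["go_mf"] == (47, 82.5)
        assert cov["risk_genes"] == (42, 73.7)

    def test_zero_coverage(self):
        cov = criterion_coverage([GeneEvidence("G1"), GeneEvidence("G2")])
        assert cov["kegg"] == (0, 0.0)

    def test_half_up_rounding(self):
        assert round_half_up(7.25, 1) == 7.3
        assert round_half_up(7.24, 1) == 7.2
        assert round_half_up(0.05, 1) == 0.1

    def test_bp_cc_mf_counts_uniquely_invert_published_percentages(self):
        """Only one count in 0..57 rounds to each published percentage."""
        for target, expected in ((52.6, 30), (63.2, 36), (82.5, 47)):
            matches = [
                c for c in range(58) if round_half_up(100.0 * c / 57, 1) == target
            ]
            assert matches == [expected]

    def test_empty_evidence_raises(self):
        with pytest.raises(ValueError):
            criterion_coverage([])


class TestScoreFixture:
    def test_histogram_matches_published_distribution(self):
        scores = [s for _, s in figure1_scores()]
        hist = {v: scores.count(v) for v in range(7)}
        assert hist == SCORE_DISTRIBUTION
        assert sum(hist.values()) == 57

    def test_evidence_matrix_realizes_both_marginals(self):
        ev = figure1_evidence()
        by_gene = {e.gene: e.score for e in ev}
        for gene, score in figure1_scores():
            assert by_gene[gene] == score
        for crit, count in CRITERION_COUNTS.items():
            assert sum(1 for e in ev if getattr(e, crit)) == count

    def test_top_gene_is_arid5b_at_five(self):
        ranked = score_genes(figure1_evidence())
        assert ranked[0].gene == "ARID5B"
        assert ranked[0].score == 5
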