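"""Variant stage: threshold filtering, dedup, LD expansion, gene summary."""

import numpy as np
import pytest

from genodrug.datasets import TABLE1_ROWS, table1_associations
from genodrug.records import AssociationRecord, LDProxyRecord, VariantFilterConfig
from genodrug.variants import (
    UNKNOWN_LABEL,
    collect_genes,
    dedupe_variants,
    expand_ld,
    filter_associations,
    summarize_gene_hits,
)
from _tables import random_associations, random_proxies


def _assoc(rsid="rs1", genes=("A",), p=1e-6, orv=1.3):
    return AssociationRecord(rsid=rsid, genes=genes, p_value=p, odds_ratio=orv)


class TestFilter:
    def test_threshold_cases(self):
        kept = filter_associations([_assoc(p=2e-6, orv=1.3), _assoc(rsid="rs2", p=1e-4, orv=1.3)])
        assert [r.rsid for r in kept] == ["rs1"]

    def test_or_bound_is_exclusive_and_p_inclusive(self):
        assert filter_associations([_assoc(p=1e-5, orv=1.0)]) == []
        assert len(filter_associations([_assoc(p=1e-5, orv=1.0 + 1e-9)])) == 1

    def test_missing_or_dropped(self):
        assert filter_associations([_assoc(orv=None)]) == []

    def test_matches_brute_force_on_random_records(self, rng):
        cfg = VariantFilterConfig()
        for _ in range(10):
            records = random_associations(rng, 500)
            expected = [
                r
                for r in records
                if r.p_value <= cfg.p_max
                and r.odds_ratio is not None
                and r.odds_ratio > cfg.or_min
            ]
            assert filter_associations(records, cfg) == expected


class TestDedupe:
    def test_merges_genes_and_counts_hits(self):
        rows = [
            _assoc(genes=("A",)),
            _assoc(genes=("A",)),
            _assoc(genes=("B",)),
        ]
        (out,) = dedupe_variants(rows)
        assert out.genes == ("A", "B")
        assert out.n_hits == 3

    def test_unique_input_is_identity(self):
        rows = [_assoc(rsid=f"rs{i}") for i in range(1, 6)]
        assert dedupe_variants(rows) == rows

    def test_rsid_set_preserved_on_random_input(self, rng):
        for _ in range(20):
            records = random_associations(rng, 80)
            out = dedupe_variants(records)
            assert {r.rsid for r in out} == {r.rsid for r in records}
            assert len({r.rsid for r in out}) == len(out)
            assert sum(r.n_hits for r in out) == len(records)


class TestExpandLD:
    def test_empty_proxy_table_is_identity(self):
        rsids, genes = expand_ld({"rs1"}, [])
        assert rsids == {"rs1"} and genes == set()

    def test_r2_boundary_inclusive_vs_exclusive(self):
        proxy = LDProxyRecord("rs1", "rs2", 0.8, ("B",))
        inc, genes = expand_ld({"rs1"}, [proxy], VariantFilterConfig(r2_inclusive=True))
        assert inc == {"rs1", "rs2"} and genes == {"B"}
        exc, genes = expand_ld({"rs1"}, [proxy], VariantFilterConfig(r2_inclusive=False))
        assert exc == {"rs1"} and genes == set()

    def test_single_hop_only(self):
        proxies = [
            LDProxyRecord("rs1", "rs2", 0.9, ("B",)),
            LDProxyRecord("rs2", "rs3", 0.9, ("C",)),
        ]
        rsids, genes = expand_ld({"rs1"}, proxies)
        assert rsids == {"rs1", "rs2"}
        assert genes == {"B"}

    def test_matches_brute_force_on_random_proxies(self, rng):
        cfg = VariantFilterConfig()
        for _ in range(20):
            base = {f"rs{int(i) + 1}" for i in rng.choice(60, size=10, replace=False)}
            proxies = random_proxies(rng, 40)
            expected_rs = set(base) | {
                p.proxy_rsid for p in proxies if p.index_rsid in base and p.r2 >= cfg.r2_min
            }
            expected_genes = set()
            for p in proxies:
                if p.index_rsid in base and p.r2 >= cfg.r2_min:
                    expected_genes.update(p.proxy_genes)
            assert expand_ld(base, proxies, cfg) == (expected_rs, expected_genes)


class TestCollectGenes:
    def test_shared_gene_appears_once(self):
        genes, unknown = collect_genes([_assoc(), _assoc(rsid="rs2", genes=("IKZF1",)),
                                        _assoc(rsid="rs3", genes=("IKZF1",))])
        assert genes.count("IKZF1") == 1
        assert unknown == 0

    def test_empty_gene_record_counts_as_unknown(self):
        genes, unknown = collect_genes([_assoc(genes=())])
        assert genes == [] and unknown == 1

    def test_extra_genes_are_pooled_and_sorted(self):
        genes, _ = collect_genes([_assoc(genes=("B",))], extra_genes={"A"})
        assert genes == ["A", "B"]


class TestSummary:
    def test_published_hit_table_totals(self):
        summary = summarize_gene_hits(dedupe_variants(table1_associations()))
        assert summary.total_snps == 74
        assert summary.total_hits == 128

    def test_published_hit_table_top_rows(self):
        summary = summarize_gene_hits(dedupe_variants(table1_associations()))
        by_label = {label: (s, h) for label, s, h in summary.rows}
        for label, n_snps, n_hits in TABLE1_ROWS:
            assert by_label[label] == (n_snps, n_hits)
        assert by_label[UNKNOWN_LABEL] == (2, 3)

    def test_single_record_single_gene(self):
        summary = summarize_gene_hits([_assoc()])
        assert summary.rows == (("A", 1, 1),)
        assert (summary.total_snps, summary.total_hits) == (1, 1)


def test_stage_is_idempotent(rng):
    """filter -> dedupe applied twice equals applied once."""
    cfg = VariantFilterConfig()
    for _ in range(10):
        records = random_associations(rng, 200)
        once = dedupe_variants(filter_associations(records, cfg))
        twice = dedupe_variants(filter_associations(once, cfg))
        assert twice == once


def test_total_snps_equals_distinct_rsids(rng):
    for _ in range(10):
        records = dedupe_variants(random_associations(rng, 150))
        summary = summarize_gene_hits(records)
        assert summary.total_snps == len({r.rsid for r in records})
        assert summary.total_hits == sum(r.n_hits for r in records)
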