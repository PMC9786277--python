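"""Synthetic-data generator: determinism, planted-truth contracts, marginals."""

import math

import numpy as np
import pytest

from genodrug.annotate import assemble_evidence, enrich_sets, score_genes
from genodrug.records import CRITERIA, VariantFilterConfig
from genodrug.simulate import (
    SimConfig,
    generate_annotations,
    generate_catalog,
    generate_network_drugs_scores,
    simulate,
)
from genodrug.variants import collect_genes, dedupe_variants, expand_ld, filter_associations


def _evidence_dict(evidence):
    return {e.gene: {c: getattr(e, c) for c in CRITERIA} for e in evidence}


class TestCatalog:
    def test_survivors_equal_planted_truth(self):
        cfg = SimConfig(seed=1)
        table, proxies, truth = generate_catalog(cfg)
        kept = dedupe_variants(filter_associations(table))
        assert sorted(r.rsid for r in kept) == truth["keep_rsids"]
        expanded, extra = expand_ld({r.rsid for r in kept}, proxies)
        assert sorted(expanded) == truth["expanded_rsids"]
        genes, _ = collect_genes(kept, extra)
        assert genes == truth["genes"]

    def test_hit_count_near_configured_inflation(self):
        cfg = SimConfig(seed=3)
        table, _proxies, truth = generate_catalog(cfg)
        kept = filter_associations(table)
        assert len(kept) == truth["n_survivor_rows"] == 128

    def test_same_seed_identical_tables(self):
        a = generate_catalog(SimConfig(seed=11))
        b = generate_catalog(SimConfig(seed=11))
        assert a[0] == b[0] and a[1] == b[1] and a[2] == b[2]

    def test_planted_gene_count_matches_config(self):
        for n_genes, n_variants in ((57, 74), (30, 25), (5, 40)):
            cfg = SimConfig(seed=2, n_genes=n_genes, n_variants=n_variants)
            table, proxies, truth = generate_catalog(cfg)
            kept = dedupe_variants(filter_associations(table))
            expanded, extra = expand_ld({r.rsid for r in kept}, proxies)
            genes, _ = collect_genes(kept, extra)
            assert len(genes) == n_genes


class TestAnnotations:
    def test_probs_zero_gives_all_zero_scores(self):
        cfg = SimConfig(seed=4, criterion_probs=(0.0,) * 6)
        genes = cfg.gene_symbols()
        table, sets, truth = generate_annotations(cfg, genes)
        ev = assemble_evidence(genes, table, [])
        assert all(e.score == 0 for e in ev)
        assert all(not any(t.values()) for t in truth.values())

    def test_probs_one_gives_all_six_scores(self):
        cfg = SimConfig(seed=4, criterion_probs=(1.0,) * 6)
        genes = cfg.gene_symbols()
        table, _sets, truth = generate_annotations(cfg, genes)
        enriched = enrich_sets(genes, table.kegg_sets, table.background_genes)
        ev = assemble_evidence(genes, table, enriched)
        assert all(e.score == 6 for e in ev)

    def test_pipeline_recovers_planted_evidence(self):
        cfg = SimConfig(seed=5)
        genes = cfg.gene_symbols()
        table, _sets, truth = generate_annotations(cfg, genes)
        enriched = enrich_sets(genes, table.kegg_sets, table.background_genes)
        ev = assemble_evidence(genes, table, enriched)
        assert _evidence_dict(ev) == truth

    def test_large_replicate_coverage_within_3_binomial_se(self):
        """10,000-gene draw: per-criterion coverage near configured probs."""
        cfg = SimConfig(seed=6, n_genes=10_000)
        genes = cfg.gene_symbols()
        _table, _sets, truth = generate_annotations(cfg, genes)
        n = len(genes)
        for c, p in zip(CRITERIA, cfg.criterion_probs):
            count = sum(truth[g][c] for g in genes)
            se = math.sqrt(p * (1 - p) / n)
            assert abs(count / n - p) <= 3 * se + 1e-12, c


class TestNetworkDrugsScores:
    def test_planted_interactors_distinct_from_42_seeds_give_92(self):
        seeds = [f"SEED{i:02d}" for i in range(42)]
        cfg = SimConfig(seed=7)
        edges, _targets, _scores, truth = generate_network_drugs_scores(cfg, seeds)
        from genodrug.network import expand_network

        expanded = expand_network(seeds, edges)
        assert len(expanded) == 92
        assert sorted(expanded) == truth["expanded_genes"]

    def test_planted_strong_candidates_recovered_exactly(self):
        from genodrug.connectivity import rank_candidates

        cfg = SimConfig(seed=8)
        _e, _t, scores, truth = generate_network_drugs_scores(
            cfg, [f"SEED{i:02d}" for i in range(42)]
        )
        ranked = rank_candidates(scores)
        assert sorted(r.drug for r in ranked) == sorted(truth["strong_candidates"])

    def test_negative_correlation_plants_no_strong_candidates(self):
        cfg = SimConfig(seed=9, comparator_correlation=-0.5)
        _e, _t, scores, truth = generate_network_drugs_scores(
            cfg, [f"SEED{i:02d}" for i in range(10)]
        )
        assert truth["strong_candidates"] == {}
        assert all(r.score <= 80 for r in scores if r.drug != cfg.comparator)


class TestBundle:
    def test_same_seed_byte_identical_files(self, tmp_path):
        d1, d2 = tmp_path / "a", tmp_path / "b"
        simulate(SimConfig(seed=12), d1)
        simulate(SimConfig(seed=12), d2)
        for f in sorted(d1.iterdir()):
            assert f.read_bytes() == (d2 / f.name).read_bytes(), f.name

    def test_truth_sidecar_written(self, tmp_path):
        truth = simulate(SimConfig(seed=13), tmp_path)
        assert (tmp_path / "truth.json").exists()
        assert (tmp_path / "config.yaml").exists()
        assert set(truth["risk_genes"]) <= set(truth["genes"])
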