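"""End-to-end pipeline orchestration and run reporting.

The stages run in the study's workflow order: variant selection → LD
expansion → gene collection → six-criterion annotation scoring → risk-gene
classification → network expansion → druggability overlap → connectivity
ranking.  A run is driven by a declarative YAML config that names every
input table and every threshold; no threshold is hard-coded in stage logic.

Outputs per run: one TSV per stage, a machine-readable ``run_summary.json``
with the counts at every step, and a human-readable log.  On a stage
failure the partial outputs are retained next to a ``FAILED`` marker file.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import yaml

from . import io as gio
from .annotate import (
    DEFAULT_EQTL_TISSUE,
    DEFAULT_P_CUT,
    DEFAULT_SCORE_THRESHOLD,
    assemble_evidence,
    classify_risk_genes,
    coverage_report,
    enrich_sets,
    score_genes,
)
from .connectivity import attach_targets, rank_candidates
from .drugs import DEFAULT_GROUPS, filter_drug_targets, overlap_druggable
from .network import expand_network, rank_interactors
from .records import (
    CRITERIA,
    AnnotationTable,
    AssociationRecord,
    ConnectivityRecord,
    DrugTargetRecord,
    ExpansionConfig,
    GeneSetRecord,
    InteractionEdge,
    LDProxyRecord,
    RankingConfig,
    VariantFilterConfig,
    gene_sets_as_mapping,
)
from .variants import (
    collect_genes,
    dedupe_variants,
    expand_ld,
    filter_associations,
    summarize_gene_hits,
)

__all__ = [
    "Settings",
    "InputBundle",
    "StageResults",
    "execute",
    "run_pipeline",
    "load_run_config",
    "write_run_config",
]

log = logging.getLogger(__name__)

_INPUT_KEYS = (
    "associations",
    "ld_proxies",
    "annotations",
    "gene_sets",
    "edges",
    "drug_targets",
    "connectivity",
)


@dataclass(frozen=True)
class Settings:
    """Every tunable threshold of the pipeline, with the study defaults."""

    p_max: float = 1e-5
    or_min: float = 1.0
    r2_min: float = 0.8
    r2_inclusive: bool = True
    enrichment_p_cut: float = DEFAULT_P_CUT
    enrichment_method: str = "ease"
    eqtl_tissue: str = DEFAULT_EQTL_TISSUE
    score_threshold: int = DEFAULT_SCORE_THRESHOLD
    max_interactors: int = 50
    min_confidence: float = 0.4
    allowed_groups: tuple[str, ...] = tuple(sorted(DEFAULT_GROUPS))
    comparator: str = "dasatinib"
    score_min: float = 80.0
    top_k: int | None = None

    def variant_cfg(self) -> VariantFilterConfig:
        return VariantFilterConfig(self.p_max, self.or_min, self.r2_min, self.r2_inclusive)

    def expansion_cfg(self) -> ExpansionConfig:
        return ExpansionConfig(self.max_interactors, self.min_confidence)

    def ranking_cfg(self) -> RankingConfig:
        return RankingConfig(self.comparator, self.score_min, self.top_k)


@dataclass
class InputBundle:
    """All input tables, already parsed and validated."""

    associations: list[AssociationRecord]
    ld_proxies: list[LDProxyRecord]
    annotations: AnnotationTable
    gene_sets: list[GeneSetRecord]
    edges: list[InteractionEdge]
    drug_targets: list[DrugTargetRecord]
    connectivity: list[ConnectivityRecord]

    @classmethod
    def read(cls, paths: dict) -> "InputBundle":
        missing = [k for k in _INPUT_KEYS if k not in paths]
        if missing:
            raise KeyError(f"config is missing input path(s): {missing}")
        absent = [k for k in _INPUT_KEYS if not Path(paths[k]).exists()]
        if absent:
            raise FileNotFoundError(
                f"input file(s) not found: {[str(paths[k]) for k in absent]}"
            )
        return cls(
            associations=gio.read_table(paths["associations"], "associations"),
            ld_proxies=gio.read_table(paths["ld_proxies"], "ld_proxies"),
            annotations=gio.read_table(paths["annotations"], "annotations"),
            gene_sets=gio.read_table(paths["gene_sets"], "gmt"),
            edges=gio.read_table(paths["edges"], "edges"),
            drug_targets=gio.read_table(paths["drug_targets"], "drug_targets"),
            connectivity=gio.read_table(paths["connectivity"], "connectivity"),
        )


@dataclass
class StageResults:
    """Everything the pipeline computed, stage by stage."""

    kept: list[AssociationRecord]
    deduped: list[AssociationRecord]
    expanded_rsids: set[str]
    proxy_genes: set[str]
    genes: list[str]
    n_unknown: int
    gene_summary: object
    enriched: list
    evidence: list
    scores: list
    risk_genes: set[str]
    expanded_genes: list[str]
    interactor_ranking: list
    overlap: object
    ranked: list[ConnectivityRecord]
    ranked_rows: list
    summary: dict = field(default_factory=dict)


def execute(bundle: InputBundle, settings: Settings | None = None) -> StageResults:
    """Run every stage in order on in-memory tables."""
    settings = settings or Settings()
    vcfg = settings.variant_cfg()

    # stage 1: variant selection, dedup, LD expansion, gene collection
    kept = filter_associations(bundle.associations, vcfg)
    deduped = dedupe_variants(kept)
    expanded_rsids, proxy_genes = expand_ld(
        {r.rsid for r in deduped}, bundle.ld_proxies, vcfg
    )
    genes, n_unknown = collect_genes(deduped, proxy_genes)
    gene_summary = summarize_gene_hits(deduped)

    # stage 2: annotation scoring and risk-gene classification
    ann = bundle.annotations.with_kegg_sets(gene_sets_as_mapping(bundle.gene_sets))
    if genes:
        universe = ann.background_genes | set(genes)
        enriched = enrich_sets(
            [g for g in genes],
            ann.kegg_sets,
            universe,
            p_cut=settings.enrichment_p_cut,
            method=settings.enrichment_method,
        )
        evidence = assemble_evidence(genes, ann, enriched, settings.eqtl_tissue)
        scores = score_genes(evidence, settings.score_threshold)
        risk_genes = classify_risk_genes(scores)
    else:
        log.warning("no genes survived the variant stage; downstream stages are empty")
        enriched, evidence, scores, risk_genes = [], [], [], set()

    # stage 3: network expansion
    if risk_genes:
        expanded_genes = expand_network(risk_genes, bundle.edges, settings.expansion_cfg())
        interactor_ranking = rank_interactors(
            risk_genes, bundle.edges, settings.expansion_cfg()
        )[: settings.max_interactors]
    else:
        expanded_genes, interactor_ranking = [], []

    # stage 4: druggability overlap
    filtered_targets = filter_drug_targets(
        bundle.drug_targets, frozenset(settings.allowed_groups)
    )
    overlap = overlap_druggable(expanded_genes, filtered_targets)

    # stage 5: connectivity ranking
    ranked = rank_candidates(bundle.connectivity, settings.ranking_cfg())
    ranked_rows = attach_targets(ranked, overlap.gene_to_drugs)

    summary = {
        "associations_in": len(bundle.associations),
        "associations_kept": len(kept),
        "variants": len(deduped),
        "hits": sum(r.n_hits for r in deduped),
        "variants_after_ld": len(expanded_rsids),
        "genes": len(genes),
        "unknown_gene_records": n_unknown,
        "enriched_sets": len(enriched),
        "risk_genes": len(risk_genes),
        "expanded_genes": len(expanded_genes),
        "druggable_genes": overlap.n_druggable_genes,
        "drugs": overlap.n_drugs,
        "ranked_drugs": len(ranked),
    }
    return StageResults(
        kept=kept,
        deduped=deduped,
        expanded_rsids=expanded_rsids,
        proxy_genes=proxy_genes,
        genes=genes,
        n_unknown=n_unknown,
        gene_summary=gene_summary,
        enriched=enriched,
        evidence=evidence,
        scores=scores,
        risk_genes=risk_genes,
        expanded_genes=expanded_genes,
        interactor_ranking=interactor_ranking,
        overlap=overlap,
        ranked=ranked,
        ranked_rows=ranked_rows,
        summary=summary,
    )


# ---------------------------------------------------------------------------
# file-level driver


def load_run_config(path) -> tuple[dict, Settings]:
    """Parse a run config: an ``inputs`` path map and optional ``thresholds``."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    inputs = raw.get("inputs", {})
    thresholds = raw.get("thresholds", {})
    base = Path(path).parent
    paths = {k: str((base / v) if not Path(v).is_absolute() else v) for k, v in inputs.items()}
    known = set(Settings.__dataclass_fields__)
    unknown = set(thresholds) - known
    if unknown:
        raise KeyError(f"unknown threshold key(s) in config: {sorted(unknown)}")
    if "allowed_groups" in thresholds:
        thresholds["allowed_groups"] = tuple(thresholds["allowed_groups"])
    return paths, Settings(**thresholds)


def write_run_config(path, paths: dict, comparator: str = "dasatinib") -> Path:
    """Write a run config with the study-default thresholds spelled out."""
    settings = Settings(comparator=comparator)
    cfg = {
        "inputs": {k: str(v) for k, v in paths.items()},
        "thresholds": {
            **{k: v for k, v in asdict(settings).items()},
            "allowed_groups": list(settings.allowed_groups),
        },
    }
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
    return path


def _write_tsv(path: Path, header: Sequence[str], rows) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(header)
        writer.writerows(rows)


def write_outputs(results: StageResults, outdir: Path) -> dict:
    """Write every per-stage TSV plus the JSON run summary; returns paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["gene_hits"] = outdir / "stage1_gene_hits.tsv"
    gs = results.gene_summary
    _write_tsv(
        paths["gene_hits"],
        ["gene", "n_snps", "n_hits"],
        list(gs.rows) + [("TOTAL", gs.total_snps, gs.total_hits)],
    )
    paths["genes"] = outdir / "stage1_genes.tsv"
    _write_tsv(paths["genes"], ["gene"], [(g,) for g in results.genes])

    paths["gene_scores"] = outdir / "stage2_gene_scores.tsv"
    ev_by_gene = {e.gene: e for e in results.evidence}
    _write_tsv(
        paths["gene_scores"],
        ["gene", *CRITERIA, "score", "is_risk_gene"],
        [
            (
                s.gene,
                *[str(getattr(ev_by_gene[s.gene], c)).lower() for c in CRITERIA],
                s.score,
                str(s.is_risk_gene).lower(),
            )
            for s in results.scores
        ],
    )
    paths["coverage"] = outdir / "stage2_coverage.tsv"
    if results.evidence:
        cov = coverage_report(results.evidence)
        _write_tsv(
            paths["coverage"],
            ["criterion", "n_genes", "percent"],
            [(c, n, pct) for c, (n, pct) in cov.items()],
        )
    else:
        _write_tsv(paths["coverage"], ["criterion", "n_genes", "percent"], [])
    paths["enrichment"] = outdir / "stage2_enrichment.tsv"
    _write_tsv(
        paths["enrichment"],
        ["set_id", "k", "n", "K", "N", "ease_p"],
        [(r.set_id, r.k, r.n, r.K, r.N, repr(r.ease_p)) for r in results.enriched],
    )

    paths["expanded"] = outdir / "stage3_expanded_genes.tsv"
    rank_by_gene = {r.gene: r for r in results.interactor_ranking}
    rows = []
    for g in results.expanded_genes:
        if g in results.risk_genes:
            rows.append((g, "seed", "", ""))
        else:
            r = rank_by_gene.get(g)
            rows.append(
                (g, "interactor",
                 repr(r.max_confidence) if r else "",
                 repr(r.sum_confidence) if r else "")
            )
    _write_tsv(paths["expanded"], ["gene", "provenance", "max_confidence", "sum_confidence"], rows)

    paths["bipartite"] = outdir / "stage4_gene_drug.tsv"
    _write_tsv(
        paths["bipartite"],
        ["gene", "drug"],
        [
            (g, d)
            for g, ds in results.overlap.gene_to_drugs.items()
            for d in sorted(ds)
        ],
    )

    paths["ranked"] = outdir / "stage5_ranked_drugs.tsv"
    _write_tsv(
        paths["ranked"],
        ["drug", "original_indication", "target_genes", "score"],
        [
            (row.drug, row.indication, ", ".join(row.target_genes), repr(row.score))
            for row in results.ranked_rows
        ],
    )
    paths["adjacency"] = outdir / "stage5_drug_gene_adjacency.tsv"
    _write_tsv(
        paths["adjacency"],
        ["drug", "gene", "score"],
        [
            (row.drug, g, repr(row.score))
            for row in results.ranked_rows
            for g in row.target_genes
        ],
    )

    paths["summary"] = outdir / "run_summary.json"
    with open(paths["summary"], "w", encoding="utf-8") as fh:
        json.dump(results.summary, fh, indent=1, sort_keys=True)
    return paths


def run_pipeline(config_path, outdir) -> dict:
    """Load a run config, execute all stages and write the report bundle.

    Missing inputs raise before any stage runs.  A stage failure retains
    partial outputs and leaves a ``FAILED`` marker in ``outdir``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w", encoding="utf-8")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("genodrug")
    root.addHandler(handler)
    try:
        paths, settings = load_run_config(config_path)
        bundle = InputBundle.read(paths)
        try:
            results = execute(bundle, settings)
            write_outputs(results, outdir)
        except Exception as exc:
            (outdir / "FAILED").write_text(f"{type(exc).__name__}: {exc}\n", encoding="utf-8")
            raise
        log.info("pipeline finished: %s", results.summary)
        return results.summary
    finally:
        root.removeHandler(handler)
        handler.close()
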