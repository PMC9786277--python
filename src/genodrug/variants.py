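"""Variant-selection stage: threshold filtering, deduplication, LD-proxy
expansion, gene collection and the per-gene hit summary.

The selection rule keeps catalog rows with p <= p_max and odds ratio
strictly greater than or_min; rows with no reported odds ratio cannot
satisfy the rule and are dropped (and counted).  LD expansion is a single
hop: proxies of admitted proxies are not chased.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

from .records import AssociationRecord, LDProxyRecord, VariantFilterConfig

__all__ = [
    "filter_associations",
    "dedupe_variants",
    "expand_ld",
    "collect_genes",
    "summarize_gene_hits",
    "GeneHitSummary",
    "UNKNOWN_LABEL",
]

log = logging.getLogger(__name__)

#: summary label for catalog rows whose mapped gene is unknown/blank
UNKNOWN_LABEL = "Not known genes"


@dataclass(frozen=True)
class GeneHitSummary:
    """Per-gene-group SNP and catalog-hit counts (the Table-1 shape).

    Each row is ``(gene-group label, n_snps, n_hits)`` where the label is a
    comma-joined mapped-gene cell kept as printed (multi-gene cells are not
    exploded).  Totals are over distinct SNPs and all catalog hits.
    """

    rows: tuple[tuple[str, int, int], ...]
    total_snps: int
    total_hits: int

    def __post_init__(self) -> None:
        if self.total_snps != sum(r[1] for r in self.rows):
            raise ValueError("total_snps must equal the column sum of rows")
        if self.total_hits != sum(r[2] for r in self.rows):
            raise ValueError("total_hits must equal the column sum of rows")


def filter_associations(
    records: Sequence[AssociationRecord], cfg: VariantFilterConfig | None = None
) -> list[AssociationRecord]:
    """Keep associations with ``p_value <= p_max`` and ``odds_ratio > or_min``.

    Order is preserved. Drop counts are logged by reason (p-value, missing
    OR, OR at/below the bound).
    """
    cfg = cfg or VariantFilterConfig()
    kept: list[AssociationRecord] = []
    dropped = {"p_value": 0, "missing_or": 0, "odds_ratio": 0}
    for r in records:
        if r.p_value > cfg.p_max:
            dropped["p_value"] += 1
        elif r.odds_ratio is None:
            dropped["missing_or"] += 1
        elif r.odds_ratio <= cfg.or_min:
            dropped["odds_ratio"] += 1
        else:
            kept.append(r)
    log.info(
        "filter_associations: kept %d of %d (dropped: p>%g %d, missing OR %d, OR<=%g %d)",
        len(kept), len(records), cfg.p_max, dropped["p_value"],
        dropped["missing_or"], cfg.or_min, dropped["odds_ratio"],
    )
    return kept


def dedupe_variants(records: Sequence[AssociationRecord]) -> list[AssociationRecord]:
    """Collapse to one record per rsID.

    The first occurrence is kept; its gene list becomes the union (in first-
    seen order) over all occurrences, and ``n_hits`` accumulates the row
    multiplicity so summaries can still count catalog hits.
    """
    by_rsid: dict[str, AssociationRecord] = {}
    order: list[str] = []
    for r in records:
        if r.rsid not in by_rsid:
            by_rsid[r.rsid] = r
            order.append(r.rsid)
        else:
            prev = by_rsid[r.rsid]
            merged_genes = prev.genes + tuple(g for g in r.genes if g not in prev.genes)
            by_rsid[r.rsid] = replace(prev, genes=merged_genes, n_hits=prev.n_hits + r.n_hits)
    return [by_rsid[rsid] for rsid in order]


def expand_ld(
    variants: Iterable[str],
    proxies: Sequence[LDProxyRecord],
    cfg: VariantFilterConfig | None = None,
) -> tuple[set[str], set[str]]:
    """One-hop LD expansion of a variant set.

    Returns ``(expanded_rsids, proxy_genes)``: the input variants plus every
    proxy whose index SNP is in the set and whose r^2 passes the threshold
    (``>=`` by default, strict ``>`` when ``r2_inclusive`` is False), and
    the pooled mapped genes of the admitted proxies.  Proxies of proxies
    are not chased.
    """
    cfg = cfg or VariantFilterConfig()
    base = set(variants)
    expanded = set(base)
    genes: set[str] = set()
    for p in proxies:
        if p.index_rsid not in base:
            continue
        admitted = p.r2 >= cfg.r2_min if cfg.r2_inclusive else p.r2 > cfg.r2_min
        if admitted:
            expanded.add(p.proxy_rsid)
            genes.update(p.proxy_genes)
    return expanded, genes


def collect_genes(
    records: Sequence[AssociationRecord], extra_genes: Iterable[str] = ()
) -> tuple[list[str], int]:
    """Pool mapped genes across records plus ``extra_genes``.

    Returns the lexicographically sorted deduplicated gene list and the
    number of records contributing no known gene (blank mapped-gene cells).
    """
    genes: set[str] = set(extra_genes)
    unknown = 0
    for r in records:
        if r.genes:
            genes.update(r.genes)
        else:
            unknown += 1
    return sorted(genes), unknown


def summarize_gene_hits(records: Sequence[AssociationRecord]) -> GeneHitSummary:
    """Per-gene-group SNP and hit counts over deduplicated records.

    ``n_snps`` counts distinct rsIDs mapped to the group and ``n_hits`` the
    summed catalog-row multiplicity.  Records without a mapped gene are
    grouped under :data:`UNKNOWN_LABEL`.  Rows are ordered by descending
    hits, then descending SNPs, then label, with the unknown group last.
    """
    snps: dict[str, set[str]] = {}
    hits: dict[str, int] = {}
    for r in records:
        label = r.gene_label or UNKNOWN_LABEL
        snps.setdefault(label, set()).add(r.rsid)
        hits[label] = hits.get(label, 0) + r.n_hits
    rows = sorted(
        ((label, len(snps[label]), hits[label]) for label in snps),
        key=lambda row: (row[0] == UNKNOWN_LABEL, -row[2], -row[1], row[0]),
    )
    return GeneHitSummary(
        rows=tuple(rows),
        total_snps=sum(r[1] for r in rows),
        total_hits=sum(r[2] for r in rows),
    )
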