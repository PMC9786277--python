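"""Connectivity-score ranking of candidate drugs against a comparator.

Connectivity scores (range -100..100, where a high positive value means the
candidate's transcriptional signature strongly mimics the comparator's) are
consumed as an input table — this stage never computes or rescales them.
Candidates above the strong-positive threshold (> +80 by default, strictly
exclusive) are ranked by descending score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

from .records import ConnectivityRecord, RankingConfig

__all__ = ["rank_candidates", "attach_targets", "RankedDrugRow"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class RankedDrugRow:
    """One row of the final candidate table: drug, optional original
    indication, target genes and the unmodified connectivity score."""

    drug: str
    indication: str
    target_genes: tuple[str, ...]
    score: float


def rank_candidates(
    records: Sequence[ConnectivityRecord], cfg: RankingConfig | None = None
) -> list[ConnectivityRecord]:
    """Filter to scores strictly above ``score_min`` and sort.

    The comparator drug itself is removed (case-insensitively) if present.
    Ordering is descending score, ties by drug name; ``top_k`` truncates
    when set.
    """
    cfg = cfg or RankingConfig()
    comparator = cfg.comparator.strip().casefold()
    candidates = []
    for r in records:
        if r.drug.casefold() == comparator:
            log.info("rank_candidates: comparator %r removed from candidates", r.drug)
            continue
        candidates.append(r)
    kept = [r for r in candidates if r.score > cfg.score_min]
    kept.sort(key=lambda r: (-r.score, r.drug))
    if cfg.top_k is not None:
        kept = kept[: cfg.top_k]
    return kept


def attach_targets(
    ranked: Sequence[ConnectivityRecord],
    bipartite: Mapping[str, frozenset[str] | set[str]],
    indications: Mapping[str, str] | None = None,
) -> list[RankedDrugRow]:
    """Join ranked drugs with their target genes from the gene→drugs map.

    The bipartite map is inverted; a ranked drug absent from it gets an
    empty gene tuple but is never dropped.  ``indications`` optionally
    supplies the original-indication column.
    """
    indications = indications or {}
    inv: dict[str, set[str]] = {}
    for gene, drug_set in bipartite.items():
        for d in drug_set:
            inv.setdefault(d.casefold(), set()).add(gene)
    return [
        RankedDrugRow(
            drug=r.drug,
            indication=indications.get(r.drug, ""),
            target_genes=tuple(sorted(inv.get(r.drug.casefold(), ()))),
            score=r.score,
        )
        for r in ranked
    ]
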