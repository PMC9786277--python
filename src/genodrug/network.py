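"""Risk-gene network expansion over a confidence-weighted interaction network.

The seed set is expanded by its strongest first-shell interactors: non-seed
genes adjacent to at least one seed through an edge at or above the
confidence floor, ranked by (max edge confidence to any seed, sum of such
confidences, gene symbol) and truncated to the interactor budget.  The
default budget of 50 interactors mirrors the common web-tool default for
"max number of interactors to show".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

from .records import ExpansionConfig, InteractionEdge

__all__ = ["expand_network", "rank_interactors", "RankedInteractor"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class RankedInteractor:
    """A candidate interactor with its ranking key components."""

    gene: str
    max_confidence: float
    sum_confidence: float


def rank_interactors(
    seeds: Iterable[str],
    edges: Sequence[InteractionEdge],
    cfg: ExpansionConfig | None = None,
) -> list[RankedInteractor]:
    """Rank all candidate first-shell interactors of ``seeds``.

    A candidate is a non-seed gene linked to >= 1 seed by an edge with
    confidence >= ``min_confidence``.  Ordering is by descending max
    confidence, then descending sum of qualifying confidences, then gene
    symbol — deterministic under any edge-list permutation.
    """
    cfg = cfg or ExpansionConfig()
    seed_set = set(seeds)
    best: dict[str, float] = {}
    total: dict[str, float] = {}
    for e in edges:
        if e.confidence < cfg.min_confidence:
            continue
        for seed_end, cand in ((e.gene_a, e.gene_b), (e.gene_b, e.gene_a)):
            if seed_end in seed_set and cand not in seed_set:
                best[cand] = max(best.get(cand, 0.0), e.confidence)
                total[cand] = total.get(cand, 0.0) + e.confidence
    ranked = [
        RankedInteractor(gene=g, max_confidence=best[g], sum_confidence=total[g])
        for g in best
    ]
    ranked.sort(key=lambda r: (-r.max_confidence, -r.sum_confidence, r.gene))
    return ranked


def expand_network(
    seeds: Iterable[str],
    edges: Sequence[InteractionEdge],
    cfg: ExpansionConfig | None = None,
) -> list[str]:
    """Append the top-``max_interactors`` ranked interactors to the seeds.

    Returns the sorted seed genes followed by the admitted interactors in
    rank order.  An empty edge list returns the seeds unchanged (warned).
    """
    cfg = cfg or ExpansionConfig()
    seed_list = sorted(set(seeds))
    if not edges:
        log.warning("expand_network: empty edge list, returning seeds unchanged")
        return seed_list
    ranked = rank_interactors(seed_list, edges, cfg)
    admitted = [r.gene for r in ranked[: cfg.max_interactors]]
    return seed_list + admitted
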