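"""Six-criterion functional annotation scoring and risk-gene classification.

A gene earns one point for each criterion it fulfils — missense variant,
whole-blood cis-eQTL, annotation in each of the three GO roots (BP, CC, MF),
and membership in an enriched KEGG pathway — giving a 0–6 score.  Genes
scoring at or above the threshold (default 2) are classified as biological
risk genes.

Pathway enrichment uses the EASE score: the one-tailed hypergeometric upper
tail with the list-overlap count reduced by one, a deliberately conservative
variant of Fisher's exact test.  Plain Fisher is available via
``method="fisher"``.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

from scipy.stats import hypergeom

from .records import (
    CRITERIA,
    AnnotationTable,
    EnrichmentResult,
    GeneEvidence,
    GeneScore,
)

__all__ = [
    "ease_score",
    "enrich_sets",
    "assemble_evidence",
    "score_genes",
    "classify_risk_genes",
    "criterion_coverage",
    "coverage_report",
    "round_half_up",
]

#: default risk-gene score threshold (inclusive)
DEFAULT_SCORE_THRESHOLD = 2

#: default enrichment p-value cut
DEFAULT_P_CUT = 0.05

#: default eQTL tissue gate
DEFAULT_EQTL_TISSUE = "whole blood"


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal half-up rounding (7.25 -> 7.3), matching printed percentages."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def ease_score(k: int, n: int, K: int, N: int, method: str = "ease") -> float:
    """Enrichment p-value of a k-gene overlap between an n-gene list and a
    K-gene set drawn from an N-gene background.

    ``method="ease"`` (default) computes P(X >= k-1) for
    X ~ Hypergeometric(N, K, n) — the EASE convention of penalizing the
    overlap by one, so k <= 1 returns exactly 1.0.  ``method="fisher"``
    computes the plain one-tailed Fisher p, P(X >= k).
    """
    k, n, K, N = int(k), int(n), int(K), int(N)
    if N < 1 or n > N or K > N or not (0 <= k <= min(n, K)):
        raise ValueError(
            f"invalid enrichment arguments: k={k}, n={n}, K={K}, N={N} "
            "(need 0 <= k <= min(n, K), n <= N, K <= N, N >= 1)"
        )
    if method == "ease":
        if k <= 1:
            return 1.0
        # sf(x) = P(X > x), so P(X >= k-1) = sf(k-2)
        return float(hypergeom.sf(k - 2, N, K, n))
    if method == "fisher":
        if k == 0:
            return 1.0
        return float(hypergeom.sf(k - 1, N, K, n))
    raise ValueError(f"method must be 'ease' or 'fisher', got {method!r}")


def enrich_sets(
    list_genes: Iterable[str],
    sets: Mapping[str, frozenset[str] | set[str]],
    background: Iterable[str],
    p_cut: float = DEFAULT_P_CUT,
    method: str = "ease",
) -> list[EnrichmentResult]:
    """Test every gene set for over-representation in ``list_genes``.

    Returns one result per set overlapping the list (k >= 1), filtered to
    ``ease_p <= p_cut`` and sorted by ascending p then set id.  The query
    list must be contained in the background universe.
    """
    background = frozenset(background)
    if not background:
        raise ValueError("background universe must be non-empty")
    query = frozenset(list_genes)
    stray = query - background
    if stray:
        raise ValueError(
            f"list genes outside the background universe: {sorted(stray)[:5]}"
        )
    N = len(background)
    n = len(query)
    results = []
    for set_id, members in sets.items():
        annotated = frozenset(members) & background
        k = len(annotated & query)
        if k < 1:
            continue
        p = ease_score(k, n, len(annotated), N, method=method)
        results.append(
            EnrichmentResult(set_id=set_id, k=k, n=n, K=len(annotated), N=N, ease_p=p)
        )
    results = [r for r in results if r.ease_p <= p_cut]
    results.sort(key=lambda r: (r.ease_p, r.set_id))
    return results


def assemble_evidence(
    genes: Sequence[str],
    ann: AnnotationTable,
    enriched: Sequence[EnrichmentResult],
    eqtl_tissue: str = DEFAULT_EQTL_TISSUE,
) -> list[GeneEvidence]:
    """Build the six-boolean evidence vector for each gene.

    missense: the gene carries a missense variant; cis_eqtl: a significant
    eQTL in ``eqtl_tissue`` (case-insensitive match); go_bp/cc/mf: at least
    one GO annotation in the namespace; kegg: membership in at least one
    enriched KEGG set (as named by ``enriched``).
    """
    if not genes:
        raise ValueError("genes must be non-empty")
    tissue = eqtl_tissue.strip().lower()
    eqtl_ok = {g for g, t, sig in ann.eqtl_rows if sig and t == tissue}
    go_by_ns: dict[str, set[str]] = {"BP": set(), "CC": set(), "MF": set()}
    for g, _term, ns in ann.go_rows:
        go_by_ns[ns].add(g)
    kegg_ok: set[str] = set()
    for res in enriched:
        kegg_ok.update(ann.kegg_sets.get(res.set_id, frozenset()))
    return [
        GeneEvidence(
            gene=g,
            missense=g in ann.missense_genes,
            cis_eqtl=g in eqtl_ok,
            go_bp=g in go_by_ns["BP"],
            go_cc=g in go_by_ns["CC"],
            go_mf=g in go_by_ns["MF"],
            kegg=g in kegg_ok,
        )
        for g in genes
    ]


def score_genes(
    evidence: Sequence[GeneEvidence], threshold: int = DEFAULT_SCORE_THRESHOLD
) -> list[GeneScore]:
    """Count fulfilled criteria per gene and call risk genes at ``score >= threshold``.

    Output is sorted by descending score, ties broken by gene symbol.
    """
    scores = [
        GeneScore(gene=e.gene, score=e.score, is_risk_gene=e.score >= threshold)
        for e in evidence
    ]
    scores.sort(key=lambda s: (-s.score, s.gene))
    return scores


def classify_risk_genes(scores: Sequence[GeneScore]) -> set[str]:
    """The set of genes whose score met the risk-gene threshold."""
    return {s.gene for s in scores if s.is_risk_gene}


def criterion_coverage(
    evidence: Sequence[GeneEvidence],
) -> dict[str, tuple[int, float]]:
    """Per-criterion fulfilment count and percentage of genes (one decimal,
    half-up rounding)."""
    if not evidence:
        raise ValueError("evidence list must be non-empty")
    total = len(evidence)
    out: dict[str, tuple[int, float]] = {}
    for c in CRITERIA:
        count = sum(1 for e in evidence if getattr(e, c))
        out[c] = (count, round_half_up(100.0 * count / total, 1))
    return out


def coverage_report(
    evidence: Sequence[GeneEvidence], threshold: int = DEFAULT_SCORE_THRESHOLD
) -> dict[str, tuple[int, float]]:
    """:func:`criterion_coverage` plus a ``risk_genes`` row for the fraction
    of genes at or above the score threshold."""
    out = criterion_coverage(evidence)
    total = len(evidence)
    n_risk = sum(1 for e in evidence if e.score >= threshold)
    out["risk_genes"] = (n_risk, round_half_up(100.0 * n_risk / total, 1))
    return out
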