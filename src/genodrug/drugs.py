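"""Druggability filtering and the gene–drug bipartite overlap.

A drug–target record survives when the drug's pharmacological action on the
target is known, the record is for humans, and the drug carries at least
one allowed development-status annotation (approved / investigational /
experimental by default).  Surviving targets are intersected with the
expanded gene list to give the bipartite druggable-gene → drugs map.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .records import DrugTargetRecord, normalize_gene

__all__ = ["filter_drug_targets", "overlap_druggable", "DruggableOverlap", "DEFAULT_GROUPS"]

#: status groups accepted by default
DEFAULT_GROUPS = frozenset({"approved", "investigational", "experimental"})


@dataclass(frozen=True)
class DruggableOverlap:
    """Bipartite gene→drugs map plus its summary counts.

    ``n_drugs`` counts distinct drugs after trimming and case-folding the
    names; ``non_druggable`` lists input genes hit by no drug.
    """

    gene_to_drugs: dict[str, frozenset[str]]
    non_druggable: tuple[str, ...]

    @property
    def n_druggable_genes(self) -> int:
        return len(self.gene_to_drugs)

    @property
    def n_drugs(self) -> int:
        return len({d.casefold() for drugs in self.gene_to_drugs.values() for d in drugs})

    def drug_to_genes(self) -> dict[str, frozenset[str]]:
        inv: dict[str, set[str]] = {}
        for gene, drugs in self.gene_to_drugs.items():
            for d in drugs:
                inv.setdefault(d, set()).add(gene)
        return {d: frozenset(gs) for d, gs in inv.items()}


def filter_drug_targets(
    records: Sequence[DrugTargetRecord],
    allowed_groups: frozenset[str] = DEFAULT_GROUPS,
) -> list[DrugTargetRecord]:
    """Keep records with known action, human organism and an allowed status group."""
    allowed = frozenset(g.strip().lower() for g in allowed_groups)
    return [
        r
        for r in records
        if r.action_known
        and r.organism.strip().lower() == "humans"
        and (r.groups & allowed)
    ]


def overlap_druggable(
    genes: Iterable[str], records: Sequence[DrugTargetRecord]
) -> DruggableOverlap:
    """Intersect a gene list with (already filtered) drug–target records.

    The map contains only genes present in both inputs; genes with no drug
    are reported in ``non_druggable``.
    """
    gene_list = [normalize_gene(g) for g in genes]
    gene_set = set(gene_list)
    mapping: dict[str, set[str]] = {}
    for r in records:
        if r.gene in gene_set:
            mapping.setdefault(r.gene, set()).add(r.drug)
    gene_to_drugs = {g: frozenset(mapping[g]) for g in sorted(mapping)}
    non_druggable = tuple(g for g in sorted(gene_set) if g not in mapping)
    return DruggableOverlap(gene_to_drugs=gene_to_drugs, non_druggable=non_druggable)
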