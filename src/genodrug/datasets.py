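"""Packaged study fixtures, constructed programmatically.

These reproduce the published summary tables of the childhood acute
lymphoblastic leukemia (ALL) repurposing analysis in record form:

* the per-gene GWAS-catalog hit table (74 SNPs, 128 catalog hits, grouped
  by mapped-gene cell),
* the 57-gene six-criterion score distribution (4 genes at 0, 11 at 1,
  12 at 2, 19 at 3, 10 at 4 and ARID5B alone at 5, i.e. 42 risk genes),
* the top-five connectivity-ranked repurposing candidates with their
  printed scores and target genes, with dasatinib as comparator.

Where the publication aggregates rows ("other genes with 1 hit") or omits
the full gene list, the missing identifiers are synthetic placeholders
(``ALLSYN*``, ``OTHERSYN*``, ``rs9*``) — only the published counts and
marginals are authoritative.  The per-gene evidence matrix is likewise a
synthetic realization: it matches the published per-criterion marginals
(7 missense, 12 cis-eQTL, 30 BP, 36 CC, 47 MF, 5 KEGG) and the score
distribution exactly, via a Gale–Ryser greedy construction, but the
individual boolean entries beyond those margins are not published data.
"""

from __future__ import annotations

from .records import CRITERIA, AssociationRecord, ConnectivityRecord, GeneEvidence

__all__ = [
    "TABLE1_ROWS",
    "table1_associations",
    "RISK_GENE_SYMBOLS",
    "SCORE_DISTRIBUTION",
    "CRITERION_COUNTS",
    "figure1_scores",
    "figure1_evidence",
    "TOP5_DRUGS",
    "table2_connectivity",
    "table2_targets",
    "table2_indications",
    "table2_bipartite",
]

# ---------------------------------------------------------------------------
# GWAS-catalog per-gene hit table: (mapped-gene cell, n_snps, n_hits)

TABLE1_ROWS: tuple[tuple[str, int, int], ...] = (
    ("IKZF1", 3, 13),
    ("ARID5B", 4, 12),
    ("GATA3", 1, 11),
    ("SLC7A8, CEBPE", 2, 7),
    ("CDKN2A", 3, 4),
    ("LHPP", 3, 4),
    ("PIP4K2A", 3, 4),
    ("CCDC26", 3, 3),
    ("ELK3", 1, 3),
    ("GPATCH2L", 1, 3),
    ("OR5AL1, OR5AL2P", 1, 3),
    ("PDE4B", 3, 3),
    ("RNU6-366P, CPSF2", 1, 3),
    ("TP63", 1, 3),
    ("CSGALNACT1, INTS10", 1, 2),
    ("DDC, FIGNL1", 1, 2),
    ("ERG", 1, 2),
    ("AGBL1", 1, 2),
    ("PTPRJ", 1, 2),
    ("RN7SL361P, BCL11A", 1, 2),
    ("RNU6-1091P, IKZF1", 2, 2),
    ("RPL6P5", 1, 2),
)

_N_OTHER_SINGLE_HIT = 33  # aggregated "other genes with 1 hit" row
_N_UNKNOWN_SNPS = 2  # SNPs with no known mapped gene
_N_UNKNOWN_HITS = 3


def _other_gene_symbols() -> list[str]:
    # four published top-scoring genes not named in the hit table, then
    # synthetic placeholders for the aggregated remainder
    named = ["SP4", "ZNF222", "ZNF223", "ORMDL3"]
    return named + [f"OTHERSYN{i:02d}" for i in range(1, _N_OTHER_SINGLE_HIT - len(named) + 1)]


def table1_associations() -> list[AssociationRecord]:
    """The catalog-style association rows behind the per-gene hit table.

    128 rows over 74 distinct SNPs; every row passes the selection
    thresholds (p <= 1e-5, OR > 1).  Hit multiplicity within a gene group
    is realized by duplicating the group's first SNP; rsIDs are synthetic
    sequential identifiers.
    """
    records: list[AssociationRecord] = []
    rs = iter(range(9_000_001, 9_999_999))

    def add_rows(genes: tuple[str, ...], n_snps: int, n_hits: int) -> None:
        snp_ids = [f"rs{next(rs)}" for _ in range(n_snps)]
        per_snp = [1] * n_snps
        per_snp[0] += n_hits - n_snps
        for rsid, reps in zip(snp_ids, per_snp):
            for j in range(reps):
                records.append(
                    AssociationRecord(
                        rsid=rsid,
                        genes=genes,
                        p_value=2e-6,
                        odds_ratio=1.5,
                        source_id=f"GCSTSYN{len(records):04d}",
                    )
                )

    for label, n_snps, n_hits in TABLE1_ROWS:
        add_rows(tuple(g.strip() for g in label.split(",")), n_snps, n_hits)
    for gene in _other_gene_symbols():
        add_rows((gene,), 1, 1)
    add_rows((), _N_UNKNOWN_SNPS, _N_UNKNOWN_HITS)
    return records


# ---------------------------------------------------------------------------
# six-criterion score fixture (57 genes)

#: published score histogram: {score: n_genes}; 42 genes at score >= 2
SCORE_DISTRIBUTION: dict[int, int] = {0: 4, 1: 11, 2: 12, 3: 19, 4: 10, 5: 1, 6: 0}

#: published per-criterion fulfilment counts out of 57 genes
CRITERION_COUNTS: dict[str, int] = {
    "missense": 7,
    "cis_eqtl": 12,
    "go_bp": 30,
    "go_cc": 36,
    "go_mf": 47,
    "kegg": 5,
}

#: the five top-scoring published genes, best first
_TOP_GENES = ("ARID5B", "SP4", "ZNF222", "ZNF223", "ORMDL3")


def _all_gene_symbols() -> list[str]:
    symbols: list[str] = []
    for label, _s, _h in TABLE1_ROWS:
        for g in label.split(","):
            g = g.strip()
            if g not in symbols:
                symbols.append(g)
    for g in _TOP_GENES[1:]:
        if g not in symbols:
            symbols.append(g)
    i = 1
    while len(symbols) < 57:
        symbols.append(f"ALLSYN{i:02d}")
        i += 1
    return symbols


RISK_GENE_SYMBOLS: tuple[str, ...] = tuple(_all_gene_symbols())


def figure1_scores() -> list[tuple[str, int]]:
    """Deterministic (gene, score) assignment matching the published
    histogram, with ARID5B at 5 and the other named top genes at 4."""
    symbols = list(RISK_GENE_SYMBOLS)
    scores: dict[str, int] = {"ARID5B": 5}
    for g in _TOP_GENES[1:]:
        scores[g] = 4
    remaining = [g for g in symbols if g not in scores]
    quota = {s: n for s, n in SCORE_DISTRIBUTION.items()}
    quota[5] -= 1
    quota[4] -= len(_TOP_GENES) - 1
    fill_order = [s for s in (4, 3, 2, 1, 0, 6) for _ in range(quota[s])]
    for g, s in zip(remaining, fill_order):
        scores[g] = s
    return [(g, scores[g]) for g in symbols]


def figure1_evidence() -> list[GeneEvidence]:
    """A 57x6 boolean evidence matrix with the published row and column
    marginals, built by the Gale–Ryser max-remaining-capacity greedy.

    Genes are processed in descending score order; each takes its criteria
    from the columns with the most remaining capacity (ties broken in a
    fixed criterion order).  The construction is deterministic and fills
    every column marginal exactly.
    """
    capacity = dict(CRITERION_COUNTS)
    priority = {c: i for i, c in enumerate(("go_mf", "go_cc", "go_bp", "cis_eqtl", "missense", "kegg"))}
    rows = sorted(figure1_scores(), key=lambda gs: (-gs[1], RISK_GENE_SYMBOLS.index(gs[0])))
    chosen: dict[str, set[str]] = {}
    for gene, score in rows:
        cols = sorted(capacity, key=lambda c: (-capacity[c], priority[c]))[:score]
        if any(capacity[c] <= 0 for c in cols):
            raise RuntimeError("greedy construction failed: marginals not graphical")
        for c in cols:
            capacity[c] -= 1
        chosen[gene] = set(cols)
    assert all(v == 0 for v in capacity.values())
    return [
        GeneEvidence(gene=g, **{c: c in chosen[g] for c in CRITERIA})
        for g in RISK_GENE_SYMBOLS
    ]


# ---------------------------------------------------------------------------
# top-five connectivity-ranked candidates (comparator: dasatinib)

#: (drug, original indication, mode of action, target genes, score)
TOP5_DRUGS: tuple[tuple[str, str, str, tuple[str, ...], float], ...] = (
    ("Chlorprothixene", "Schizophrenia", "inhibitor", ("HTR1B",), 88.76),
    ("Sirolimus", "Immunosuppressant", "inhibitor", ("FKBP1A",), 87.80),
    ("Dihydroergocristine", "Cerebrovascular Diseases", "antagonist", ("HTR1B",), 84.11),
    ("Papaverine", "Vascular spasm", "Inhibitor", ("PDE4B",), 83.98),
    ("Tamoxifen", "Breast cancer", "inhibitor", ("PRKC", "PRKCI"), 80.92),
)


def table2_connectivity() -> list[ConnectivityRecord]:
    """Connectivity records for the published top-five candidates."""
    return [ConnectivityRecord(drug=d, score=s) for d, _i, _m, _g, s in TOP5_DRUGS]


def table2_targets() -> dict[str, tuple[str, ...]]:
    """Published drug → target-gene mapping."""
    return {d: genes for d, _i, _m, genes, _s in TOP5_DRUGS}


def table2_indications() -> dict[str, str]:
    return {d: ind for d, ind, _m, _g, _s in TOP5_DRUGS}


def table2_bipartite() -> dict[str, frozenset[str]]:
    """The gene → drugs orientation of the published mapping."""
    out: dict[str, set[str]] = {}
    for drug, _i, _m, genes, _s in TOP5_DRUGS:
        for g in genes:
            out.setdefault(g, set()).add(drug)
    return {g: frozenset(ds) for g, ds in sorted(out.items())}
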