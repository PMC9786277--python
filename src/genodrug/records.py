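"""Domain record types shared by every pipeline stage.

All records are immutable dataclasses that validate their invariants at
construction time, so a record that exists is a record that is valid.
Gene symbols are treated as opaque case-insensitive identifiers: they are
stripped and upper-cased on entry and never resolved against an alias
database.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

__all__ = [
    "AssociationRecord",
    "LDProxyRecord",
    "InteractionEdge",
    "DrugTargetRecord",
    "ConnectivityRecord",
    "GeneSetRecord",
    "AnnotationTable",
    "GeneEvidence",
    "GeneScore",
    "EnrichmentResult",
    "VariantFilterConfig",
    "ExpansionConfig",
    "RankingConfig",
    "CRITERIA",
    "GO_NAMESPACES",
    "DRUG_GROUPS",
    "normalize_gene",
]

_RSID_RE = re.compile(r"^rs\d+$")

#: the six functional-annotation criteria, in canonical order
CRITERIA = ("missense", "cis_eqtl", "go_bp", "go_cc", "go_mf", "kegg")

#: the three Gene Ontology roots
GO_NAMESPACES = ("BP", "CC", "MF")

#: recognised drug status groups
DRUG_GROUPS = frozenset({"approved", "investigational", "experimental", "other"})


def normalize_gene(symbol: str) -> str:
    """Strip and upper-case a gene symbol; reject separators inside it."""
    s = symbol.strip().upper()
    if "\t" in s or "," in s:
        raise ValueError(f"gene symbol may not contain tabs or commas: {symbol!r}")
    return s


def _normalize_genes(genes) -> tuple[str, ...]:
    seen: dict[str, None] = {}
    for g in genes:
        s = normalize_gene(g)
        if s:
            seen.setdefault(s, None)
    return tuple(seen)


def _check_rsid(rsid: str, what: str) -> str:
    rsid = rsid.strip()
    if not _RSID_RE.match(rsid):
        raise ValueError(f"{what} is not an rsID ('rs' + digits): {rsid!r}")
    return rsid


def _check_finite(x: float, what: str) -> float:
    x = float(x)
    if not math.isfinite(x):
        raise ValueError(f"{what} must be finite, got {x!r}")
    return x


@dataclass(frozen=True)
class AssociationRecord:
    """One SNP–trait association row (GWAS-catalog style).

    ``genes`` may be empty: catalog rows whose mapped gene is unknown are
    legitimate input and are counted separately downstream.  ``n_hits``
    carries association-row multiplicity after deduplication (1 for a raw
    catalog row).
    """

    rsid: str
    genes: tuple[str, ...]
    p_value: float
    odds_ratio: float | None = None
    source_id: str = ""
    n_hits: int = 1

    def __post_init__(self) -> None:
        object.__setattr__(self, "rsid", _check_rsid(self.rsid, "rsid"))
        object.__setattr__(self, "genes", _normalize_genes(self.genes))
        p = _check_finite(self.p_value, "p_value")
        if not (0.0 < p <= 1.0):
            raise ValueError(f"p_value must be in (0, 1], got {p!r}")
        object.__setattr__(self, "p_value", p)
        if self.odds_ratio is not None:
            orv = _check_finite(self.odds_ratio, "odds_ratio")
            if orv <= 0.0:
                raise ValueError(f"odds_ratio must be > 0, got {orv!r}")
            object.__setattr__(self, "odds_ratio", orv)
        if int(self.n_hits) < 1:
            raise ValueError(f"n_hits must be >= 1, got {self.n_hits!r}")
        object.__setattr__(self, "n_hits", int(self.n_hits))

    @property
    def gene_label(self) -> str:
        """The comma-joined gene cell as printed in per-gene summaries."""
        return ", ".join(self.genes)


@dataclass(frozen=True)
class LDProxyRecord:
    """A proxy SNP in linkage disequilibrium with an index SNP."""

    index_rsid: str
    proxy_rsid: str
    r2: float
    proxy_genes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "index_rsid", _check_rsid(self.index_rsid, "index_rsid"))
        object.__setattr__(self, "proxy_rsid", _check_rsid(self.proxy_rsid, "proxy_rsid"))
        if self.index_rsid == self.proxy_rsid:
            raise ValueError(f"index and proxy rsID must differ: {self.index_rsid}")
        r2 = _check_finite(self.r2, "r2")
        if not (0.0 <= r2 <= 1.0):
            raise ValueError(f"r2 must be in [0, 1], got {r2!r}")
        object.__setattr__(self, "r2", r2)
        object.__setattr__(self, "proxy_genes", _normalize_genes(self.proxy_genes))


@dataclass(frozen=True)
class InteractionEdge:
    """Undirected confidence-weighted gene–gene interaction.

    Stored canonically with ``gene_a < gene_b`` so that edge identity does
    not depend on input orientation.
    """

    gene_a: str
    gene_b: str
    confidence: float

    def __post_init__(self) -> None:
        a = normalize_gene(self.gene_a)
        b = normalize_gene(self.gene_b)
        if not a or not b:
            raise ValueError("edge endpoints must be non-empty gene symbols")
        if a == b:
            raise ValueError(f"self-interaction not allowed: {a}")
        if a > b:
            a, b = b, a
        object.__setattr__(self, "gene_a", a)
        object.__setattr__(self, "gene_b", b)
        c = _check_finite(self.confidence, "confidence")
        if not (0.0 <= c <= 1.0):
            raise ValueError(f"confidence must be in [0, 1], got {c!r}")
        object.__setattr__(self, "confidence", c)

    def other(self, gene: str) -> str:
        return self.gene_b if gene == self.gene_a else self.gene_a


@dataclass(frozen=True)
class DrugTargetRecord:
    """A drug→target-gene link with the druggability metadata used to filter it."""

    drug: str
    gene: str
    action_known: bool
    organism: str
    groups: frozenset[str]

    def __post_init__(self) -> None:
        drug = self.drug.strip()
        if not drug:
            raise ValueError("drug name must be non-empty")
        object.__setattr__(self, "drug", drug)
        g = normalize_gene(self.gene)
        if not g:
            raise ValueError("target gene must be non-empty")
        object.__setattr__(self, "gene", g)
        object.__setattr__(self, "action_known", bool(self.action_known))
        groups = frozenset(s.strip().lower() for s in self.groups)
        if not groups:
            raise ValueError("groups must be non-empty")
        unknown = groups - DRUG_GROUPS
        if unknown:
            raise ValueError(f"unknown status group(s): {sorted(unknown)}")
        object.__setattr__(self, "groups", groups)


@dataclass(frozen=True)
class ConnectivityRecord:
    """A drug with its comparator-relative connectivity score in [-100, 100]."""

    drug: str
    score: float

    def __post_init__(self) -> None:
        drug = self.drug.strip()
        if not drug:
            raise ValueError("drug name must be non-empty")
        object.__setattr__(self, "drug", drug)
        s = _check_finite(self.score, "score")
        if not (-100.0 <= s <= 100.0):
            raise ValueError(f"connectivity score must be in [-100, 100], got {s!r}")
        object.__setattr__(self, "score", s)


@dataclass(frozen=True)
class GeneSetRecord:
    """One GMT line: a named gene set with a free-text description."""

    set_id: str
    description: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        sid = self.set_id.strip()
        if not sid:
            raise ValueError("set_id must be non-empty")
        object.__setattr__(self, "set_id", sid)
        object.__setattr__(self, "genes", _normalize_genes(self.genes))


def gene_sets_as_mapping(records) -> dict[str, frozenset[str]]:
    """Collapse GeneSetRecords to the ``{set_id: genes}`` mapping stages consume."""
    out: dict[str, frozenset[str]] = {}
    for r in records:
        if r.set_id in out:
            raise ValueError(f"duplicate gene-set id: {r.set_id}")
        out[r.set_id] = frozenset(r.genes)
    return out


@dataclass(frozen=True)
class AnnotationTable:
    """All per-gene functional annotation evidence, plus the enrichment universe.

    ``background_genes`` must contain every annotated gene — it is the
    hypergeometric universe for enrichment.  ``kegg_sets`` is attached from a
    separate GMT file.
    """

    missense_genes: frozenset[str] = frozenset()
    eqtl_rows: tuple[tuple[str, str, bool], ...] = ()
    go_rows: tuple[tuple[str, str, str], ...] = ()
    background_genes: frozenset[str] = frozenset()
    kegg_sets: dict[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "missense_genes", frozenset(normalize_gene(g) for g in self.missense_genes)
        )
        eqtl = tuple(
            (normalize_gene(g), t.strip().lower(), bool(s)) for g, t, s in self.eqtl_rows
        )
        object.__setattr__(self, "eqtl_rows", eqtl)
        go = []
        for g, term, ns in self.go_rows:
            ns = ns.strip().upper()
            if ns not in GO_NAMESPACES:
                raise ValueError(f"GO namespace must be one of {GO_NAMESPACES}, got {ns!r}")
            go.append((normalize_gene(g), term.strip(), ns))
        object.__setattr__(self, "go_rows", tuple(go))
        object.__setattr__(
            self, "background_genes", frozenset(normalize_gene(g) for g in self.background_genes)
        )
        annotated = self.annotated_genes()
        missing = annotated - self.background_genes
        if missing:
            raise ValueError(
                "background_genes must contain every annotated gene; missing "
                f"{sorted(missing)[:5]}{'...' if len(missing) > 5 else ''}"
            )

    def annotated_genes(self) -> frozenset[str]:
        genes = set(self.missense_genes)
        genes.update(g for g, _, _ in self.eqtl_rows)
        genes.update(g for g, _, _ in self.go_rows)
        return frozenset(genes)

    def with_kegg_sets(self, sets: dict[str, frozenset[str]]) -> "AnnotationTable":
        return AnnotationTable(
            missense_genes=self.missense_genes,
            eqtl_rows=self.eqtl_rows,
            go_rows=self.go_rows,
            background_genes=self.background_genes,
            kegg_sets=dict(sets),
        )


@dataclass(frozen=True)
class GeneEvidence:
    """Per-gene six-boolean criterion vector."""

    gene: str
    missense: bool = False
    cis_eqtl: bool = False
    go_bp: bool = False
    go_cc: bool = False
    go_mf: bool = False
    kegg: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "gene", normalize_gene(self.gene))
        for c in CRITERIA:
            object.__setattr__(self, c, bool(getattr(self, c)))

    def criteria(self) -> tuple[bool, ...]:
        return tuple(getattr(self, c) for c in CRITERIA)

    @property
    def score(self) -> int:
        return sum(self.criteria())


@dataclass(frozen=True)
class GeneScore:
    """A gene's 0–6 criterion score and its risk-gene call."""

    gene: str
    score: int
    is_risk_gene: bool

    def __post_init__(self) -> None:
        object.__setattr__(self, "gene", normalize_gene(self.gene))
        if not (0 <= int(self.score) <= len(CRITERIA)):
            raise ValueError(f"score must be in [0, {len(CRITERIA)}], got {self.score!r}")
        object.__setattr__(self, "score", int(self.score))
        object.__setattr__(self, "is_risk_gene", bool(self.is_risk_gene))


@dataclass(frozen=True)
class EnrichmentResult:
    """One gene set's overlap with the query list and its EASE p-value.

    k: overlap of list and set; n: list size; K: background-annotated set
    size; N: background size.
    """

    set_id: str
    k: int
    n: int
    K: int
    N: int
    ease_p: float

    def __post_init__(self) -> None:
        k, n, K, N = int(self.k), int(self.n), int(self.K), int(self.N)
        if not (0 <= k <= min(n, K)):
            raise ValueError(f"need 0 <= k <= min(n, K); got k={k}, n={n}, K={K}")
        if n > N or K > N:
            raise ValueError(f"need n <= N and K <= N; got n={n}, K={K}, N={N}")
        object.__setattr__(self, "k", k)
        object.__setattr__(self, "n", n)
        object.__setattr__(self, "K", K)
        object.__setattr__(self, "N", N)
        p = _check_finite(self.ease_p, "ease_p")
        if not (0.0 < p <= 1.0):
            raise ValueError(f"ease_p must be in (0, 1], got {p!r}")
        object.__setattr__(self, "ease_p", p)


# ---------------------------------------------------------------------------
# stage configuration


@dataclass(frozen=True)
class VariantFilterConfig:
    """Thresholds for the variant-selection stage.

    p bound is inclusive (p <= p_max) and the odds-ratio bound exclusive
    (OR > or_min).  The LD cut defaults to the conventional inclusive
    r^2 >= 0.8; set ``r2_inclusive=False`` for a strict r^2 > r2_min cut.
    """

    p_max: float = 1e-5
    or_min: float = 1.0
    r2_min: float = 0.8
    r2_inclusive: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.p_max <= 1.0):
            raise ValueError(f"p_max must be in (0, 1], got {self.p_max!r}")
        if self.or_min < 0.0:
            raise ValueError(f"or_min must be >= 0, got {self.or_min!r}")
        if not (0.0 <= self.r2_min <= 1.0):
            raise ValueError(f"r2_min must be in [0, 1], got {self.r2_min!r}")


@dataclass(frozen=True)
class ExpansionConfig:
    """Interactor budget and confidence floor for network expansion."""

    max_interactors: int = 50
    min_confidence: float = 0.4

    def __post_init__(self) -> None:
        if int(self.max_interactors) < 0:
            raise ValueError("max_interactors must be >= 0")
        object.__setattr__(self, "max_interactors", int(self.max_interactors))
        if not (0.0 <= self.min_confidence <= 1.0):
            raise ValueError("min_confidence must be in [0, 1]")


@dataclass(frozen=True)
class RankingConfig:
    """Comparator drug and the strong-positive-correlation threshold (exclusive)."""

    comparator: str = "dasatinib"
    score_min: float = 80.0
    top_k: int | None = None

    def __post_init__(self) -> None:
        if not (-100.0 <= self.score_min <= 100.0):
            raise ValueError("score_min must be in [-100, 100]")
        if self.top_k is not None and int(self.top_k) < 0:
            raise ValueError("top_k must be >= 0 when set")
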