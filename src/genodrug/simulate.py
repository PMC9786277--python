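"""Synthetic input-table generator with planted, recoverable structure.

Every table the pipeline consumes can be generated here with a known ground
truth, so the whole analysis is testable without any database access.  The
defaults emulate the published study conditions: 74 risk-associated SNPs
over 57 genes with ~128 catalog rows, per-criterion fulfilment
probabilities equal to the published marginals (7/57 missense, 12/57
cis-eQTL, 30/57 BP, 36/57 CC, 47/57 MF, 5/57 KEGG), a scale-free
interaction network, 37 candidate drugs with a druggable subset, and a
comparator-correlated connectivity table in which about five candidates
exceed the +80 strong-positive threshold.

Determinism: every generator derives its RNG stream from ``SimConfig.seed``
alone, and tables are serialized with repr-stable floats, so the same seed
yields byte-identical files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from . import io as gio
from .annotate import DEFAULT_P_CUT, ease_score
from .records import (
    CRITERIA,
    AnnotationTable,
    AssociationRecord,
    ConnectivityRecord,
    DrugTargetRecord,
    GeneSetRecord,
    InteractionEdge,
    LDProxyRecord,
    gene_sets_as_mapping,
)

__all__ = [
    "SimConfig",
    "generate_catalog",
    "generate_annotations",
    "generate_network_drugs_scores",
    "simulate",
]

#: published per-criterion marginals used as default fulfilment probabilities
DEFAULT_CRITERION_PROBS = (7 / 57, 12 / 57, 30 / 57, 36 / 57, 47 / 57, 5 / 57)


@dataclass(frozen=True)
class SimConfig:
    """Study-scale generator configuration.

    ``hit_inflation`` is the mean number of extra catalog rows per variant
    (default (128-74)/74, reproducing ~128 rows from 74 SNPs).
    ``comparator_correlation`` is the per-candidate probability of being a
    strong positive (>+80) relative to the comparator; values <= 0 plant
    none.  ``attachment_exponent`` tunes preferential attachment (1 =
    classic linear/Barabási–Albert growth).
    """

    seed: int = 0
    n_genes: int = 57
    n_variants: int = 74
    hit_inflation: float = 54 / 74
    criterion_probs: tuple[float, ...] = DEFAULT_CRITERION_PROBS
    n_network_genes: int = 400
    attachment_exponent: float = 1.0
    n_drugs: int = 37
    frac_druggable: float = 15 / 92
    comparator_correlation: float = 5 / 37
    comparator: str = "dasatinib"

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_variants < 1 or self.n_drugs < 1:
            raise ValueError("counts must be positive")
        if self.n_network_genes < 0:
            raise ValueError("n_network_genes must be >= 0")
        if self.hit_inflation < 0:
            raise ValueError("hit_inflation must be >= 0")
        if len(self.criterion_probs) != len(CRITERIA):
            raise ValueError(f"criterion_probs needs {len(CRITERIA)} entries")
        if any(not (0.0 <= p <= 1.0) for p in self.criterion_probs):
            raise ValueError("criterion_probs must lie in [0, 1]")
        if not (0.0 <= self.frac_druggable <= 1.0):
            raise ValueError("frac_druggable must be in [0, 1]")
        if not (-1.0 <= self.comparator_correlation <= 1.0):
            raise ValueError("comparator_correlation must be in [-1, 1]")

    def gene_symbols(self) -> list[str]:
        return [f"GENE{i:03d}" for i in range(1, self.n_genes + 1)]


def _rng(cfg: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(cfg.seed) % (2**31), stream])


# ---------------------------------------------------------------------------
# catalog


def generate_catalog(
    cfg: SimConfig,
) -> tuple[list[AssociationRecord], list[LDProxyRecord], dict]:
    """Synthesize association and LD-proxy tables with planted survivors.

    The planted ``n_variants`` SNPs all pass the selection thresholds and
    map onto the ``n_genes`` planted genes (via LD proxies when there are
    more genes than SNPs); decoy rows fail exactly one predicate each
    (p-value above threshold, missing OR, OR at/below 1) and decoy proxies
    sit below the LD cut or hang off rejected variants.  The returned truth
    dict lists the surviving rsIDs, the expanded rsID set and the final
    gene list.
    """
    rng = _rng(cfg, 1)
    genes = cfg.gene_symbols()
    survivors = [f"rs{100000 + i}" for i in range(1, cfg.n_variants + 1)]
    gene_of = {rsid: genes[i % cfg.n_genes] for i, rsid in enumerate(survivors)}

    rows: list[AssociationRecord] = []
    for i, rsid in enumerate(survivors):
        rows.append(
            AssociationRecord(
                rsid=rsid,
                genes=(gene_of[rsid],),
                p_value=float(10.0 ** -rng.uniform(5.2, 12.0)),
                odds_ratio=float(rng.uniform(1.05, 3.0)),
                source_id=f"GCSTSIM{i:04d}",
            )
        )
    # duplicate catalog rows (extra hits) for randomly chosen survivors
    n_extra = int(round(cfg.hit_inflation * cfg.n_variants))
    for j, idx in enumerate(rng.integers(0, cfg.n_variants, size=n_extra)):
        base = rows[int(idx)]
        rows.append(
            AssociationRecord(
                rsid=base.rsid,
                genes=base.genes,
                p_value=float(10.0 ** -rng.uniform(5.2, 12.0)),
                odds_ratio=float(rng.uniform(1.05, 3.0)),
                source_id=f"GCSTDUP{j:04d}",
            )
        )
    n_survivor_rows = len(rows)

    # decoys: each fails exactly one predicate
    decoys: list[AssociationRecord] = []
    n_decoys = max(3, cfg.n_variants // 5)
    for i in range(n_decoys):
        rsid = f"rs{500000 + i}"
        mode = i % 3
        if mode == 0:  # p-value too large
            decoys.append(
                AssociationRecord(rsid, (f"DECOYG{i:03d}",), float(rng.uniform(1e-4, 1e-2)),
                                  float(rng.uniform(1.05, 3.0)), f"GCSTDEC{i:04d}")
            )
        elif mode == 1:  # odds ratio missing
            decoys.append(
                AssociationRecord(rsid, (f"DECOYG{i:03d}",), float(10.0 ** -rng.uniform(5.2, 12.0)),
                                  None, f"GCSTDEC{i:04d}")
            )
        else:  # odds ratio at/below the exclusive bound
            decoys.append(
                AssociationRecord(rsid, (f"DECOYG{i:03d}",), float(10.0 ** -rng.uniform(5.2, 12.0)),
                                  float(rng.uniform(0.2, 1.0)), f"GCSTDEC{i:04d}")
            )
    # deterministic boundary decoy: p at threshold passes, OR exactly 1 fails
    decoys.append(AssociationRecord("rs599999", ("DECOYGBOUND",), 1e-5, 1.0, "GCSTDECB"))

    all_rows = rows + decoys
    order = rng.permutation(len(all_rows))
    table = [all_rows[int(i)] for i in order]

    # proxies: genes not reachable from the survivors are planted on
    # admitted proxies; additional admitted proxies map to already-covered
    # genes; decoys fail the r2 cut or hang off rejected index SNPs
    covered = set(gene_of.values())
    missing = [g for g in genes if g not in covered]
    proxies: list[LDProxyRecord] = []
    next_proxy = 700001
    for g in missing:
        idx = survivors[int(rng.integers(0, len(survivors)))]
        proxies.append(
            LDProxyRecord(idx, f"rs{next_proxy}", float(rng.uniform(0.85, 0.99)), (g,))
        )
        next_proxy += 1
    for _ in range(max(2, cfg.n_variants // 10)):
        idx = survivors[int(rng.integers(0, len(survivors)))]
        proxies.append(
            LDProxyRecord(idx, f"rs{next_proxy}", float(rng.uniform(0.85, 0.99)),
                          (gene_of[idx],))
        )
        next_proxy += 1
    for i in range(max(2, cfg.n_variants // 10)):
        idx = survivors[int(rng.integers(0, len(survivors)))]
        proxies.append(  # below the LD cut: novel gene must be excluded
            LDProxyRecord(idx, f"rs{next_proxy}", float(rng.uniform(0.05, 0.79)),
                          (f"LOWLDG{i:03d}",))
        )
        next_proxy += 1
    if decoys:
        proxies.append(  # high LD but the index SNP itself was rejected
            LDProxyRecord(decoys[0].rsid, f"rs{next_proxy}", 0.95, ("REJECTEDG",))
        )

    admitted = {p.proxy_rsid for p in proxies if p.index_rsid in set(survivors) and p.r2 >= 0.8}
    truth = {
        "keep_rsids": sorted(survivors),
        "expanded_rsids": sorted(set(survivors) | admitted),
        "genes": sorted(genes),
        "n_survivor_rows": n_survivor_rows,
    }
    return table, proxies, truth


# ---------------------------------------------------------------------------
# annotations


def generate_annotations(
    cfg: SimConfig, genes: Sequence[str]
) -> tuple[AnnotationTable, list[GeneSetRecord], dict]:
    """Draw each gene's six criterion memberships independently and build
    annotation tables that make the pipeline recover them exactly.

    The KEGG criterion is realized as one pathway set holding exactly the
    planted member genes over a large background; because the EASE filter
    cannot reach significance for very small overlaps, the KEGG column is
    redrawn (bounded rejection, per-seed deterministic) until the planted
    set is either empty or recoverable at the default p cut, falling back
    to all-false.  Decoy pathway sets (overlap 1) and off-tissue /
    non-significant eQTL rows are included and must not change calls.

    Returns ``(annotation_table, gene_set_records, truth)`` where truth
    maps gene -> {criterion: bool}.
    """
    rng = _rng(cfg, 2)
    genes = list(genes)
    n = len(genes)
    background = list(genes) + [f"BGSYN{i:04d}" for i in range(1, 501)]
    probs = dict(zip(CRITERIA, cfg.criterion_probs))

    flags = {c: rng.random(n) < probs[c] for c in CRITERIA if c != "kegg"}

    # KEGG with rejection: planted members must survive the EASE filter
    kegg_flags = np.zeros(n, dtype=bool)
    for _attempt in range(50):
        cand = rng.random(n) < probs["kegg"]
        k = int(cand.sum())
        if k == 0:
            kegg_flags = cand
            break
        if ease_score(k, n, k, len(background)) <= DEFAULT_P_CUT:
            kegg_flags = cand
            break
    flags["kegg"] = kegg_flags

    missense = frozenset(g for g, f in zip(genes, flags["missense"]) if f)
    eqtl_rows: list[tuple[str, str, bool]] = []
    for i, g in enumerate(genes):
        if flags["cis_eqtl"][i]:
            eqtl_rows.append((g, "whole blood", True))
        elif rng.random() < 0.2:  # decoy rows that must not satisfy the criterion
            eqtl_rows.append((g, "liver", True) if rng.random() < 0.5 else (g, "whole blood", False))
    go_rows: list[tuple[str, str, str]] = []
    term_no = 1
    for ns, crit in (("BP", "go_bp"), ("CC", "go_cc"), ("MF", "go_mf")):
        for i, g in enumerate(genes):
            if flags[crit][i]:
                for _ in range(1 + int(rng.integers(0, 2))):
                    go_rows.append((g, f"GO:{term_no:07d}", ns))
                    term_no += 1

    gene_sets: list[GeneSetRecord] = []
    planted_kegg = [g for g, f in zip(genes, flags["kegg"]) if f]
    if planted_kegg:
        gene_sets.append(
            GeneSetRecord("PATHSYN001", "planted synthetic pathway", tuple(planted_kegg))
        )
    # decoy sets: single-gene overlap with the list -> EASE p = 1, filtered out
    non_kegg = [g for g, f in zip(genes, flags["kegg"]) if not f]
    for i in range(min(3, len(non_kegg))):
        fillers = tuple(background[len(genes) + 10 * i: len(genes) + 10 * i + 8])
        gene_sets.append(
            GeneSetRecord(f"PATHDEC{i:03d}", "decoy pathway", (non_kegg[i],) + fillers)
        )

    table = AnnotationTable(
        missense_genes=missense,
        eqtl_rows=tuple(eqtl_rows),
        go_rows=tuple(go_rows),
        background_genes=frozenset(background),
    ).with_kegg_sets(gene_sets_as_mapping(gene_sets))

    truth = {
        g: {c: bool(flags[c][i]) for c in CRITERIA} for i, g in enumerate(genes)
    }
    return table, gene_sets, truth


# ---------------------------------------------------------------------------
# network, drug targets, connectivity


def _preferential_attachment_edges(
    rng: np.random.Generator, seeds: list[str], new_nodes: list[str], alpha: float, m: int = 3
) -> set[tuple[str, str]]:
    """Grow a scale-free graph: each new node attaches to ``m`` distinct
    existing nodes with probability proportional to (degree + 1)^alpha."""
    nodes: list[str] = []
    degree: dict[str, int] = {}
    edges: set[tuple[str, str]] = set()

    def add_edge(a: str, b: str) -> None:
        if a == b:
            return
        key = (a, b) if a < b else (b, a)
        if key not in edges:
            edges.add(key)
            degree[a] += 1
            degree[b] += 1

    for s in seeds:
        degree[s] = 0
        nodes.append(s)
    for a, b in zip(seeds, seeds[1:]):  # connect the seed backbone
        add_edge(a, b)
    for node in new_nodes:
        degree[node] = 0
        if nodes:
            weights = np.array([(degree[x] + 1.0) ** alpha for x in nodes])
            p = weights / weights.sum()
            k = min(m, len(nodes))
            targets = rng.choice(len(nodes), size=k, replace=False, p=p)
            nodes.append(node)
            for t in targets:
                add_edge(node, nodes[int(t)])
        else:
            nodes.append(node)
    return edges


def generate_network_drugs_scores(
    cfg: SimConfig, risk_genes: Sequence[str]
) -> tuple[list[InteractionEdge], list[DrugTargetRecord], list[ConnectivityRecord], dict]:
    """Synthesize the interaction network, drug–target table and
    connectivity scores around a risk-gene seed set.

    Plants ``min(50, n_network_genes)`` interactors whose best edge to a
    seed has confidence in (0.85, 0.99), strictly above every other edge
    (<= 0.80), so the default expansion admits exactly the planted shell.
    Drug–target records carry a planted druggable subset of the expanded
    genes plus decoys failing each druggability predicate; connectivity
    scores plant strong positives (> +80) with probability
    ``comparator_correlation`` per candidate drug.
    """
    rng = _rng(cfg, 3)
    seeds = sorted({g.strip().upper() for g in risk_genes})
    net_nodes = [f"NETSYN{i:04d}" for i in range(1, cfg.n_network_genes + 1)]
    raw_edges = _preferential_attachment_edges(
        rng, seeds, net_nodes, cfg.attachment_exponent
    )
    conf: dict[tuple[str, str], float] = {
        e: float(rng.uniform(0.05, 0.80)) for e in sorted(raw_edges)
    }

    n_plant = min(50, len(net_nodes)) if seeds else 0
    planted = sorted(
        str(net_nodes[int(i)])
        for i in rng.choice(len(net_nodes), size=n_plant, replace=False)
    ) if n_plant else []
    for g in planted:
        s = seeds[int(rng.integers(0, len(seeds)))]
        key = (g, s) if g < s else (s, g)
        conf[key] = float(rng.uniform(0.85, 0.99))

    edges = [InteractionEdge(a, b, c) for (a, b), c in sorted(conf.items())]
    expanded = sorted(set(seeds) | set(planted))

    # drug targets
    druggable_n = max(1, int(round(cfg.frac_druggable * len(expanded)))) if expanded else 0
    druggable = sorted(
        str(expanded[int(i)])
        for i in rng.choice(len(expanded), size=druggable_n, replace=False)
    ) if druggable_n else []
    pool = [f"DRUGSIM{i:03d}" for i in range(1, cfg.n_drugs + 1)]
    group_choices = (
        frozenset({"approved"}),
        frozenset({"investigational"}),
        frozenset({"experimental"}),
        frozenset({"approved", "investigational"}),
    )
    records: list[DrugTargetRecord] = []
    bipartite: dict[str, set[str]] = {}
    for g in druggable:
        k = 1 + int(rng.integers(0, 3))
        for i in rng.choice(cfg.n_drugs, size=min(k, cfg.n_drugs), replace=False):
            drug = pool[int(i)]
            records.append(
                DrugTargetRecord(
                    drug, g, True, "Humans",
                    group_choices[int(rng.integers(0, len(group_choices)))],
                )
            )
            bipartite.setdefault(g, set()).add(drug)
    # decoys: one failing predicate each, plus valid records off the gene list
    for i, g in enumerate(druggable):
        mode = i % 3
        drug = pool[int(rng.integers(0, cfg.n_drugs))]
        if mode == 0:
            records.append(DrugTargetRecord(f"{drug}-NA", g, False, "Humans",
                                            frozenset({"approved"})))
        elif mode == 1:
            records.append(DrugTargetRecord(f"{drug}-EC", g, True, "Escherichia coli",
                                            frozenset({"approved"})))
        else:
            records.append(DrugTargetRecord(f"{drug}-OTH", g, True, "Humans",
                                            frozenset({"other"})))
    for i in range(3):
        records.append(
            DrugTargetRecord(pool[int(rng.integers(0, cfg.n_drugs))], f"OFFLIST{i:02d}",
                             True, "Humans", frozenset({"approved"}))
        )
    order = rng.permutation(len(records))
    records = [records[int(i)] for i in order]

    # connectivity scores
    used = sorted({d for ds in bipartite.values() for d in ds})
    p_above = min(1.0, max(0.0, cfg.comparator_correlation))
    scores: list[ConnectivityRecord] = [ConnectivityRecord(cfg.comparator, 99.2)]
    strong: dict[str, float] = {}
    for d in used:
        if rng.random() < p_above:
            s = float(rng.uniform(80.5, 99.0))
            strong[d] = s
        else:
            s = float(rng.uniform(-99.0, 79.0))
        scores.append(ConnectivityRecord(d, s))

    truth = {
        "interactors": planted,
        "expanded_genes": expanded,
        "druggable": {g: sorted(ds) for g, ds in sorted(bipartite.items())},
        "n_druggable_genes": len(bipartite),
        "n_drugs": len(used),
        "strong_candidates": {d: strong[d] for d in sorted(strong)},
    }
    return edges, records, scores, truth


# ---------------------------------------------------------------------------
# full bundle


def simulate(cfg: SimConfig, outdir) -> dict:
    """Materialize a complete synthetic input bundle plus its truth sidecar.

    Writes every dialect the pipeline reads, a ``truth.json`` consumed only
    by tests, and a ready-to-run ``config.yaml``.  Returns the truth dict
    (with a ``paths`` entry added).
    """
    from .pipeline import write_run_config  # local import to avoid a cycle

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    associations, proxies, cat_truth = generate_catalog(cfg)
    genes = cat_truth["genes"]
    ann, gene_sets, evidence_truth = generate_annotations(cfg, genes)
    risk_genes = sorted(
        g for g, ev in evidence_truth.items() if sum(ev.values()) >= 2
    )
    edges, drug_targets, conn, net_truth = generate_network_drugs_scores(cfg, risk_genes)

    paths = {
        "associations": outdir / "associations.tsv",
        "ld_proxies": outdir / "ld_proxies.tsv",
        "annotations": outdir / "annotations.tsv",
        "gene_sets": outdir / "gene_sets.gmt",
        "edges": outdir / "edges.tsv",
        "drug_targets": outdir / "drug_targets.tsv",
        "connectivity": outdir / "connectivity.tsv",
    }
    gio.write_table(associations, paths["associations"], "associations")
    gio.write_table(proxies, paths["ld_proxies"], "ld_proxies")
    gio.write_table(ann, paths["annotations"], "annotations")
    gio.write_table(gene_sets, paths["gene_sets"], "gmt")
    gio.write_table(edges, paths["edges"], "edges")
    gio.write_table(drug_targets, paths["drug_targets"], "drug_targets")
    gio.write_table(conn, paths["connectivity"], "connectivity")

    truth = {
        **cat_truth,
        "evidence": evidence_truth,
        "risk_genes": risk_genes,
        **net_truth,
    }
    with open(outdir / "truth.json", "w", encoding="utf-8") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
    # paths are written relative to the config so the bundle is relocatable
    # (and byte-identical across output directories for the same seed)
    write_run_config(outdir / "config.yaml", {k: v.name for k, v in paths.items()},
                     comparator=cfg.comparator)
    truth["paths"] = {k: str(v) for k, v in paths.items()}
    return truth
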