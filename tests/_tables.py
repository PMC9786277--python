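"""Random record generators shared by the oracle and round-trip tests."""

from __future__ import annotations

import numpy as np

from genodrug.records import (
    AssociationRecord,
    ConnectivityRecord,
    DrugTargetRecord,
    GeneSetRecord,
    InteractionEdge,
    LDProxyRecord,
)

GENE_POOL = [f"G{i:03d}" for i in range(1, 41)]
GROUP_POOL = ["approved", "investigational", "experimental", "other"]


def random_associations(rng: np.random.Generator, n: int) -> list[AssociationRecord]:
    out = []
    for i in range(n):
        n_genes = int(rng.integers(0, 4))
        genes = tuple(
            GENE_POOL[int(j)] for j in rng.choice(len(GENE_POOL), size=n_genes, replace=False)
        )
        has_or = rng.random() < 0.8
        out.append(
            AssociationRecord(
                rsid=f"rs{int(rng.integers(1, 30))}",
                genes=genes,
                p_value=float(10.0 ** -rng.uniform(0.1, 10.0)),
                odds_ratio=float(rng.uniform(0.3, 3.0)) if has_or else None,
                source_id=f"S{i}",
            )
        )
    return out


def random_proxies(rng: np.random.Generator, n: int) -> list[LDProxyRecord]:
    out = []
    for _ in range(n):
        a, b = rng.choice(60, size=2, replace=False)
        n_genes = int(rng.integers(0, 3))
        genes = tuple(
            GENE_POOL[int(j)] for j in rng.choice(len(GENE_POOL), size=n_genes, replace=False)
        )
        out.append(
            LDProxyRecord(
                index_rsid=f"rs{int(a) + 1}",
                proxy_rsid=f"rs{int(b) + 1}",
                r2=float(rng.uniform(0.0, 1.0)),
                proxy_genes=genes,
            )
        )
    return out


def random_edges(rng: np.random.Generator, n: int, pool=None) -> list[InteractionEdge]:
    pool = pool or GENE_POOL
    seen = set()
    out = []
    for _ in range(n):
        a, b = rng.choice(len(pool), size=2, replace=False)
        key = (min(int(a), int(b)), max(int(a), int(b)))
        if key in seen:
            continue
        seen.add(key)
        out.append(
            InteractionEdge(pool[key[0]], pool[key[1]], float(rng.uniform(0.0, 1.0)))
        )
    return out


def random_drug_targets(rng: np.random.Generator, n: int) -> list[DrugTargetRecord]:
    organisms = ["Humans", "humans", "Escherichia coli", "Mus musculus"]
    out = []
    for i in range(n):
        n_groups = int(rng.integers(1, 4))
        groups = frozenset(
            GROUP_POOL[int(j)] for j in rng.choice(len(GROUP_POOL), size=n_groups, replace=False)
        )
        out.append(
            DrugTargetRecord(
                drug=f"drug{int(rng.integers(1, 15))}",
                gene=GENE_POOL[int(rng.integers(0, len(GENE_POOL)))],
                action_known=bool(rng.random() < 0.7),
                organism=organisms[int(rng.integers(0, len(organisms)))],
                groups=groups,
            )
        )
    return out


def random_connectivity(rng: np.random.Generator, n: int) -> list[ConnectivityRecord]:
    names = rng.choice(200, size=n, replace=False)
    return [
        ConnectivityRecord(drug=f"cmpd{int(names[i])}", score=float(rng.uniform(-100, 100)))
        for i in range(n)
    ]


def random_gene_sets(rng: np.random.Generator, n: int) -> list[GeneSetRecord]:
    out = []
    for i in range(n):
        size = int(rng.integers(0, 8))
        genes = tuple(
            GENE_POOL[int(j)] for j in rng.choice(len(GENE_POOL), size=size, replace=False)
        )
        out.append(GeneSetRecord(f"SET{i:03d}", f"random set {i}", genes))
    return out
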