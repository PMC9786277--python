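"""Readers and writers for the pipeline's tabular dialects.

Seven dialects, all plain UTF-8 text: six tab-separated tables with a fixed
header (``associations``, ``ld_proxies``, ``annotations``, ``edges``,
``drug_targets``, ``connectivity``) and the standard headerless GMT gene-set
format.  Reals are serialized with ``repr`` so a write→read round trip is
bit-exact.  Readers validate every row against the record invariants and
raise with the 1-based line number on failure; they never silently drop a
row.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, Sequence

from .records import (
    AnnotationTable,
    AssociationRecord,
    ConnectivityRecord,
    DrugTargetRecord,
    GeneSetRecord,
    InteractionEdge,
    LDProxyRecord,
)

__all__ = ["read_table", "write_table", "TableFormatError", "TableRowError", "FORMATS"]


class TableFormatError(ValueError):
    """Header or file-level problem: wrong, missing or unknown column."""


class TableRowError(ValueError):
    """A row violating its record type's invariants; carries the line number."""

    def __init__(self, line_number: int, message: str):
        super().__init__(f"line {line_number}: {message}")
        self.line_number = line_number


# GWAS Catalog MAPPED_GENE cells join multiple symbols with "," or " - "
def split_gene_cell(cell: str) -> list[str]:
    parts: list[str] = []
    for chunk in cell.split(","):
        parts.extend(chunk.split(" - "))
    return [p for p in (s.strip() for s in parts) if p]


def _join_genes(genes: Sequence[str]) -> str:
    return ", ".join(genes)


def _fmt_float(x: float | None) -> str:
    return "" if x is None else repr(float(x))


def _parse_float(cell: str, what: str) -> float:
    try:
        return float(cell)
    except ValueError:
        raise ValueError(f"{what} is not a number: {cell!r}") from None


def _parse_bool(cell: str, what: str) -> bool:
    low = cell.strip().lower()
    if low in {"true", "1", "yes"}:
        return True
    if low in {"false", "0", "no"}:
        return False
    raise ValueError(f"{what} is not a boolean: {cell!r}")


class _Dialect:
    """One tab-separated table dialect: header contract + row codecs."""

    name: str
    columns: tuple[str, ...]
    optional: frozenset[str] = frozenset()
    record_type: type

    def parse_row(self, row: dict) -> object:  # pragma: no cover - interface
        raise NotImplementedError

    def format_row(self, record) -> list[str]:  # pragma: no cover - interface
        raise NotImplementedError

    def read(self, path: Path):
        with open(path, newline="", encoding="utf-8") as fh:
            reader = csv.reader(fh, delimiter="\t")
            try:
                header = next(reader)
            except StopIteration:
                raise TableFormatError(f"{path}: empty file, expected a header row")
            self._check_header(header, path)
            records = []
            for lineno, raw in enumerate(reader, start=2):
                if not raw or (len(raw) == 1 and not raw[0].strip()):
                    continue  # trailing blank line
                if len(raw) != len(header):
                    raise TableRowError(
                        lineno, f"expected {len(header)} fields, found {len(raw)}"
                    )
                row = dict(zip(header, raw))
                for col in self.optional - set(header):
                    row[col] = ""
                try:
                    records.append(self.parse_row(row))
                except ValueError as exc:
                    raise TableRowError(lineno, str(exc)) from exc
        return records

    def write(self, records, path: Path) -> Path:
        header = list(self.columns)
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
            writer.writerow(header)
            for record in records:
                if not isinstance(record, self.record_type):
                    raise TypeError(
                        f"{self.name} dialect expects {self.record_type.__name__}, "
                        f"got {type(record).__name__}"
                    )
                writer.writerow(self.format_row(record))
        return path

    def _check_header(self, header: list[str], path: Path) -> None:
        required = [c for c in self.columns if c not in self.optional]
        missing = [c for c in required if c not in header]
        if missing:
            raise TableFormatError(f"{path}: missing column {missing[0]!r}")
        unknown = [c for c in header if c not in self.columns]
        if unknown:
            raise TableFormatError(f"{path}: unknown column {unknown[0]!r}")
        if len(set(header)) != len(header):
            raise TableFormatError(f"{path}: duplicated column in header")


class _Associations(_Dialect):
    name = "associations"
    columns = ("rsid", "genes", "p_value", "odds_ratio", "source_id", "n_hits")
    optional = frozenset({"n_hits"})
    record_type = AssociationRecord

    def parse_row(self, row):
        orc = row["odds_ratio"].strip()
        return AssociationRecord(
            rsid=row["rsid"],
            genes=tuple(split_gene_cell(row["genes"])),
            p_value=_parse_float(row["p_value"], "p_value"),
            odds_ratio=None if orc == "" else _parse_float(orc, "odds_ratio"),
            source_id=row["source_id"],
            n_hits=1 if row["n_hits"].strip() == "" else int(row["n_hits"]),
        )

    def format_row(self, r):
        return [
            r.rsid,
            _join_genes(r.genes),
            repr(r.p_value),
            _fmt_float(r.odds_ratio),
            r.source_id,
            str(r.n_hits),
        ]


class _LDProxies(_Dialect):
    name = "ld_proxies"
    columns = ("index_rsid", "proxy_rsid", "r2", "proxy_genes")
    record_type = LDProxyRecord

    def parse_row(self, row):
        return LDProxyRecord(
            index_rsid=row["index_rsid"],
            proxy_rsid=row["proxy_rsid"],
            r2=_parse_float(row["r2"], "r2"),
            proxy_genes=tuple(split_gene_cell(row["proxy_genes"])),
        )

    def format_row(self, r):
        return [r.index_rsid, r.proxy_rsid, repr(r.r2), _join_genes(r.proxy_genes)]


class _Edges(_Dialect):
    name = "edges"
    columns = ("gene_a", "gene_b", "confidence")
    record_type = InteractionEdge

    def parse_row(self, row):
        return InteractionEdge(
            gene_a=row["gene_a"],
            gene_b=row["gene_b"],
            confidence=_parse_float(row["confidence"], "confidence"),
        )

    def format_row(self, r):
        return [r.gene_a, r.gene_b, repr(r.confidence)]


class _DrugTargets(_Dialect):
    name = "drug_targets"
    columns = ("drug", "gene", "action_known", "organism", "groups")
    record_type = DrugTargetRecord

    def parse_row(self, row):
        groups = [g for g in row["groups"].split("|") if g.strip()]
        return DrugTargetRecord(
            drug=row["drug"],
            gene=row["gene"],
            action_known=_parse_bool(row["action_known"], "action_known"),
            organism=row["organism"].strip(),
            groups=frozenset(groups),
        )

    def format_row(self, r):
        return [
            r.drug,
            r.gene,
            "true" if r.action_known else "false",
            r.organism,
            "|".join(sorted(r.groups)),
        ]


class _Connectivity(_Dialect):
    name = "connectivity"
    columns = ("drug", "score")
    record_type = ConnectivityRecord

    def parse_row(self, row):
        return ConnectivityRecord(drug=row["drug"], score=_parse_float(row["score"], "score"))

    def format_row(self, r):
        return [r.drug, repr(r.score)]


class _Annotations(_Dialect):
    """Long-format annotation evidence.

    One row per evidence item: ``kind`` in {missense, eqtl, go, background};
    ``detail`` is the tissue (eqtl) or term id (go); ``flag`` is the
    significance flag (eqtl) or GO namespace (go).  read_table returns a
    single assembled :class:`AnnotationTable` rather than a row list.
    """

    name = "annotations"
    columns = ("gene", "kind", "detail", "flag")
    record_type = AnnotationTable

    def parse_row(self, row):
        kind = row["kind"].strip().lower()
        if kind not in {"missense", "eqtl", "go", "background"}:
            raise ValueError(f"unknown annotation kind: {row['kind']!r}")
        return (row["gene"], kind, row["detail"], row["flag"])

    def read(self, path: Path):
        rows = super().read(path)
        missense: set[str] = set()
        eqtl: list[tuple[str, str, bool]] = []
        go: list[tuple[str, str, str]] = []
        background: set[str] = set()
        for gene, kind, detail, flag in rows:
            if kind == "missense":
                missense.add(gene)
            elif kind == "eqtl":
                eqtl.append((gene, detail, _parse_bool(flag, "eqtl significance flag")))
            elif kind == "go":
                go.append((gene, detail, flag))
            else:
                background.add(gene)
        return AnnotationTable(
            missense_genes=frozenset(missense),
            eqtl_rows=tuple(eqtl),
            go_rows=tuple(go),
            background_genes=frozenset(background),
        )

    def write(self, table, path: Path) -> Path:
        if isinstance(table, (list, tuple)):
            if len(table) != 1 or not isinstance(table[0], AnnotationTable):
                raise TypeError("annotations dialect expects a single AnnotationTable")
            table = table[0]
        if not isinstance(table, AnnotationTable):
            raise TypeError("annotations dialect expects an AnnotationTable")
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
            writer.writerow(self.columns)
            for g in sorted(table.missense_genes):
                writer.writerow([g, "missense", "", ""])
            for g, tissue, sig in table.eqtl_rows:
                writer.writerow([g, "eqtl", tissue, "true" if sig else "false"])
            for g, term, ns in table.go_rows:
                writer.writerow([g, "go", term, ns])
            for g in sorted(table.background_genes):
                writer.writerow([g, "background", "", ""])
        return path


class _GMT(_Dialect):
    """Standard GMT: headerless ``set_id<TAB>description<TAB>gene...`` lines."""

    name = "gmt"
    columns = ()
    record_type = GeneSetRecord

    def read(self, path: Path):
        records = []
        with open(path, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line.strip():
                    continue
                fields = line.split("\t")
                if len(fields) < 2:
                    raise TableRowError(
                        lineno, "GMT line needs at least set_id and description"
                    )
                try:
                    records.append(
                        GeneSetRecord(
                            set_id=fields[0],
                            description=fields[1],
                            genes=tuple(g for g in fields[2:] if g.strip()),
                        )
                    )
                except ValueError as exc:
                    raise TableRowError(lineno, str(exc)) from exc
        return records

    def write(self, records, path: Path) -> Path:
        with open(path, "w", newline="", encoding="utf-8") as fh:
            for r in records:
                if not isinstance(r, GeneSetRecord):
                    raise TypeError(
                        f"gmt dialect expects GeneSetRecord, got {type(r).__name__}"
                    )
                fh.write("\t".join([r.set_id, r.description, *r.genes]) + "\n")
        return path


FORMATS: dict[str, _Dialect] = {
    d.name: d
    for d in (
        _Associations(),
        _LDProxies(),
        _Annotations(),
        _GMT(),
        _Edges(),
        _DrugTargets(),
        _Connectivity(),
    )
}

_BY_TYPE = {
    AssociationRecord: "associations",
    LDProxyRecord: "ld_proxies",
    AnnotationTable: "annotations",
    GeneSetRecord: "gmt",
    InteractionEdge: "edges",
    DrugTargetRecord: "drug_targets",
    ConnectivityRecord: "connectivity",
}


def read_table(path, format_name: str):
    """Read ``path`` in the named dialect, validating every row.

    Returns a list of records for the row-oriented dialects, or a single
    :class:`AnnotationTable` for ``annotations``.
    """
    if format_name not in FORMATS:
        raise TableFormatError(
            f"unknown format {format_name!r}; expected one of {sorted(FORMATS)}"
        )
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return FORMATS[format_name].read(path)


def write_table(records, path, format_name: str | None = None):
    """Write a homogeneous record list (or an AnnotationTable) to ``path``.

    The dialect is inferred from the record type; pass ``format_name``
    explicitly to write an empty table (header only).
    """
    if format_name is None:
        if isinstance(records, AnnotationTable):
            format_name = "annotations"
        else:
            items = list(records)
            if not items:
                raise TypeError(
                    "cannot infer the dialect of an empty record list; "
                    "pass format_name explicitly"
                )
            first = type(items[0])
            if first not in _BY_TYPE:
                raise TypeError(f"no dialect for record type {first.__name__}")
            if any(type(r) is not first for r in items):
                raise TypeError("mixed record types in one table")
            format_name = _BY_TYPE[first]
            records = items
    if format_name not in FORMATS:
        raise TableFormatError(
            f"unknown format {format_name!r}; expected one of {sorted(FORMATS)}"
        )
    return FORMATS[format_name].write(records, Path(path))
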