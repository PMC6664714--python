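"""Spreadsheet-driven term generation.

A template table is TSV or CSV with two header rows: row 1 holds human-readable
column labels (ignored), row 2 holds template strings, and rows 3+ hold data.
Supported template strings:

  ``ID``             the term identifier (exactly one such column)
  ``LABEL``          rdfs:label annotation
  ``TYPE``           entity type (default ``owl:Class`` when empty/absent)
  ``A <property>``   annotation with the given property CURIE/IRI
  ``SC %``           named superclass (cell is a CURIE/IRI)
  ``SC <R> some %``  existential superclass, cell substituted as the filler
  ``EC %``           named equivalent class
  ``EC <R> some %``  existential equivalent class

Cell values for SC/EC columns are CURIEs or IRIs, never labels. Empty cells
contribute nothing. Anything outside this grammar is rejected loudly.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from typing import Dict, List, Optional

from . import vocab
from .errors import PrefixError, TemplateError
from .model import (
    AnnotationAssertion,
    Declaration,
    EquivalentClasses,
    Identifier,
    Literal,
    Named,
    OntologyDocument,
    Some,
    SubClassOf,
    expand_curie,
)

_TYPE_MAP = {
    "": "class",
    "class": "class",
    "owl:Class": "class",
    "object property": "object_property",
    "owl:ObjectProperty": "object_property",
    "annotation property": "annotation_property",
    "owl:AnnotationProperty": "annotation_property",
    "individual": "individual",
    "owl:NamedIndividual": "individual",
}

_SOME_RE = re.compile(r"^(SC|EC)\s+(\S+)\s+some\s+%$")


@dataclass(frozen=True)
class _Column:
    kind: str  # id | label | type | annotation | sc | ec | sc_some | ec_some
    property: Optional[str] = None  # annotation property or object property (unexpanded)


@dataclass
class TemplateTable:
    column_headers: List[str]
    template_strings: List[str]
    columns: List[_Column]
    data_rows: List[List[str]]
    id_column: int


def _parse_template_string(text: str, column: int) -> _Column:
    text = text.strip()
    if text == "ID":
        return _Column("id")
    if text == "LABEL":
        return _Column("label")
    if text == "TYPE":
        return _Column("type")
    if text.startswith("A "):
        prop = text[2:].strip()
        if not prop or " " in prop:
            raise TemplateError(f"bad annotation template {text!r}", row=2, column=column)
        return _Column("annotation", property=prop)
    if text == "SC %":
        return _Column("sc")
    if text == "EC %":
        return _Column("ec")
    m = _SOME_RE.match(text)
    if m:
        return _Column("sc_some" if m.group(1) == "SC" else "ec_some", property=m.group(2))
    raise TemplateError(f"unknown template string {text!r}", row=2, column=column)


def parse_template(path, dialect: Optional[str] = None) -> TemplateTable:
    if dialect is None:
        dialect = "tsv" if str(path).endswith(".tsv") else "csv"
    if dialect not in ("tsv", "csv"):
        raise TemplateError(f"unknown dialect {dialect!r}")
    with open(path, "r", encoding="utf-8", newline="") as handle:
        reader = csv.reader(handle, delimiter="\t" if dialect == "tsv" else ",")
        rows = [row for row in reader]
    if len(rows) < 2:
        raise TemplateError("template needs a header row and a template-string row")
    headers, templates = rows[0], rows[1]
    if len(templates) != len(headers):
        raise TemplateError("template-string row arity differs from header row", row=2)
    columns = [_parse_template_string(t, i + 1) for i, t in enumerate(templates)]
    id_columns = [i for i, c in enumerate(columns) if c.kind == "id"]
    if len(id_columns) != 1:
        raise TemplateError(f"exactly one ID column required, found {len(id_columns)}")
    data = []
    for rowno, row in enumerate(rows[2:], start=3):
        if not any(cell.strip() for cell in row):
            continue
        if len(row) != len(headers):
            raise TemplateError(
                f"row has {len(row)} cells, expected {len(headers)}", row=rowno
            )
        data.append(row)
    return TemplateTable(
        column_headers=headers,
        template_strings=templates,
        columns=columns,
        data_rows=data,
        id_column=id_columns[0],
    )


def expand_template(table: TemplateTable, prefixes: Dict[str, str]) -> OntologyDocument:
    """One declaration per data row plus one axiom/annotation per nonempty
    templated cell. Deterministic and row-order independent at the axiom-set
    level."""
    doc = OntologyDocument(prefixes=dict(prefixes))

    def to_iri(cell: str, rowno: int) -> Identifier:
        try:
            return expand_curie(cell.strip(), prefixes)
        except PrefixError as exc:
            raise TemplateError(str(exc), row=rowno) from exc

    for offset, row in enumerate(table.data_rows):
        rowno = offset + 3
        term = to_iri(row[table.id_column], rowno)
        entity_type = "class"
        for col, cell in zip(table.columns, row):
            if col.kind == "type" and cell.strip():
                if cell.strip() not in _TYPE_MAP:
                    raise TemplateError(f"unknown TYPE {cell!r}", row=rowno)
                entity_type = _TYPE_MAP[cell.strip()]
        doc.axioms.add(Declaration(term, entity_type))
        for col, cell in zip(table.columns, row):
            cell = cell.strip()
            if not cell or col.kind in ("id", "type"):
                continue
            if col.kind == "label":
                doc.axioms.add(
                    AnnotationAssertion(term, Identifier(vocab.RDFS_LABEL), Literal(cell))
                )
            elif col.kind == "annotation":
                doc.axioms.add(
                    AnnotationAssertion(term, to_iri(col.property, rowno), Literal(cell))
                )
            elif col.kind == "sc":
                doc.axioms.add(SubClassOf(Named(term), Named(to_iri(cell, rowno))))
            elif col.kind == "ec":
                doc.axioms.add(
                    EquivalentClasses(frozenset({Named(term), Named(to_iri(cell, rowno))}))
                )
            elif col.kind == "sc_some":
                expr = Some(to_iri(col.property, rowno), Named(to_iri(cell, rowno)))
                doc.axioms.add(SubClassOf(Named(term), expr))
            elif col.kind == "ec_some":
                expr = Some(to_iri(col.property, rowno), Named(to_iri(cell, rowno)))
                doc.axioms.add(EquivalentClasses(frozenset({Named(term), expr})))
    return doc
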