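"""Configurable quality-control reporting and automatic repair.

``report`` runs a battery of checks — most are SPARQL SELECTs over the
document's RDF view; the inferred-equivalence check consults the reasoner's
taxonomy — and returns violations at three severity levels (ERROR > WARN >
INFO). The run fails when any violation reaches the configured ``fail_on``
level. Check queries follow one convention: they must bind ``?subject`` and
may bind ``?property`` and ``?value``; a check may instead carry a fixed
report property.

``repair`` fixes the two problems whose correct fix is mechanical: duplicate
axioms (same logical content, different annotations) are collapsed into one
axiom carrying the union of the annotations, and references to deprecated
classes that carry a replacement annotation are rewritten to the replacement
(transitively, with cycle detection).
"""

from __future__ import annotations

import csv
import os
from dataclasses import dataclass, field, replace
from typing import Callable, Dict, List, Optional, Sequence, Set, Tuple

import yaml

from . import vocab
from .errors import ProfileError, RepairError
from .model import (
    And,
    AnnotationAssertion,
    Axiom,
    ClassExpression,
    Declaration,
    DisjointClasses,
    EquivalentClasses,
    Identifier,
    Literal,
    Named,
    OntologyDocument,
    Some,
    SubClassOf,
    strip_annotations,
)
from .sparql import ResultTable, run_select, to_graph_view

LEVELS = ("ERROR", "WARN", "INFO")
_LEVEL_RANK = {"ERROR": 0, "WARN": 1, "INFO": 2}

_PREFIX_BLOCK = """\
PREFIX rdf: <http://www.w3.org/1999/02/22-rdf-syntax-ns#>
PREFIX rdfs: <http://www.w3.org/2000/01/rdf-schema#>
PREFIX owl: <http://www.w3.org/2002/07/owl#>
PREFIX xsd: <http://www.w3.org/2001/XMLSchema#>
PREFIX obo: <http://purl.obolibrary.org/obo/>
PREFIX oboInOwl: <http://www.geneontology.org/formats/oboInOwl#>
PREFIX dcterms: <http://purl.org/dc/terms/>
"""

_DOCS = "https://github.com/owlkit/owlkit/blob/main/docs/checks.md#"


@dataclass(frozen=True)
class Check:
    name: str
    level: str
    query: Optional[str] = None  # SPARQL SELECT ?subject [?property] [?value]
    builtin: Optional[Callable[[OntologyDocument], List["Violation"]]] = None
    property: Optional[Identifier] = None
    doc_url: str = ""


@dataclass
class ReportProfile:
    checks: List[Check]
    fail_on: str = "ERROR"  # ERROR | WARN | INFO | none

    def check_names(self) -> List[str]:
        return [c.name for c in self.checks]


@dataclass(frozen=True)
class Violation:
    rule_name: str
    level: str
    subject: Identifier
    property: Optional[Identifier] = None
    value: str = ""

    def sort_key(self):
        return (
            _LEVEL_RANK[self.level],
            self.rule_name,
            self.subject.iri,
            self.property.iri if self.property else "",
            self.value,
        )


# ---------------------------------------------------------------------------
# the default battery


def _equivalent_class_pairs(doc: OntologyDocument) -> List[Violation]:
    """Inferred one-to-one class equivalencies, via the reasoner's taxonomy
    (not just asserted equivalence axioms)."""
    from .reasoner import classify

    out = []
    taxonomy = classify(doc)
    for a, b in taxonomy.equivalent_pairs():
        out.append(Violation("equivalent_class_pair", "WARN", a, None, b.iri))
    return out


_QUERIES: Dict[str, Tuple[str, Optional[str]]] = {
    # name -> (query body, fixed property IRI or None)
    "missing_label": (
        """SELECT ?subject WHERE {
             ?subject a owl:Class .
             FILTER(isIRI(?subject))
             FILTER NOT EXISTS { ?subject rdfs:label ?l }
           }""",
        vocab.RDFS_LABEL,
    ),
    "duplicate_label": (
        """SELECT ?subject ?value WHERE {
             ?subject rdfs:label ?value .
             ?other rdfs:label ?value .
             FILTER(?subject != ?other)
             FILTER(STR(?subject) < STR(?other))
           }""",
        vocab.RDFS_LABEL,
    ),
    "multiple_labels": (
        """SELECT ?subject ?value WHERE {
             ?subject rdfs:label ?value .
             ?subject rdfs:label ?v2 .
             FILTER(?value != ?v2)
             FILTER(STR(?value) < STR(?v2))
           }""",
        vocab.RDFS_LABEL,
    ),
    "duplicate_definition": (
        """SELECT ?subject ?value WHERE {
             ?subject obo:IAO_0000115 ?value .
             ?other obo:IAO_0000115 ?value .
             FILTER(?subject != ?other)
             FILTER(STR(?subject) < STR(?other))
           }""",
        vocab.DEFINITION,
    ),
    "multiple_definitions": (
        """SELECT ?subject ?value WHERE {
             ?subject obo:IAO_0000115 ?value .
             ?subject obo:IAO_0000115 ?v2 .
             FILTER(?value != ?v2)
             FILTER(STR(?value) < STR(?v2))
           }""",
        vocab.DEFINITION,
    ),
    "self_reference": (
        """SELECT ?subject WHERE { ?subject rdfs:subClassOf ?subject . }""",
        vocab.RDFS_SUBCLASSOF,
    ),
    "trailing_whitespace": (
        """SELECT ?subject ?property ?value WHERE {
             ?subject ?property ?value .
             FILTER(isIRI(?subject))
             FILTER(isLiteral(?value))
             FILTER(regex(STR(?value), "^\\s+|\\s+$"))
           }""",
        None,
    ),
    "invalid_xref_syntax": (
        """SELECT ?subject ?value WHERE {
             ?subject oboInOwl:hasDbXref ?value .
             FILTER(!regex(STR(?value), "^[^\\s:]+:[^\\s:]+$"))
           }""",
        vocab.XREF,
    ),
    "missing_ontology_license": (
        """SELECT ?subject WHERE {
             ?subject a owl:Ontology .
             FILTER NOT EXISTS { ?subject dcterms:license ?l }
           }""",
        vocab.LICENSE,
    ),
    "missing_ontology_title": (
        """SELECT ?subject WHERE {
             ?subject a owl:Ontology .
             FILTER NOT EXISTS { ?subject dcterms:title ?t }
           }""",
        vocab.TITLE,
    ),
    "definition_format": (
        """SELECT ?subject ?value WHERE {
             ?subject obo:IAO_0000115 ?value .
             FILTER(!regex(STR(?value), "^[A-Z].*\\.$"))
           }""",
        vocab.DEFINITION,
    ),
    "missing_definition": (
        """SELECT ?subject WHERE {
             ?subject a owl:Class .
             FILTER(isIRI(?subject))
             FILTER NOT EXISTS { ?subject obo:IAO_0000115 ?d }
           }""",
        vocab.DEFINITION,
    ),
}

_DEFAULT_LEVELS: List[Tuple[str, str]] = [
    ("missing_label", "ERROR"),
    ("duplicate_label", "ERROR"),
    ("duplicate_definition", "ERROR"),
    ("multiple_definitions", "ERROR"),
    ("equivalent_class_pair", "WARN"),
    ("self_reference", "WARN"),
    ("trailing_whitespace", "WARN"),
    ("invalid_xref_syntax", "WARN"),
    ("missing_ontology_license", "WARN"),
    ("missing_ontology_title", "WARN"),
    ("definition_format", "INFO"),
    ("missing_definition", "INFO"),
]


def default_profile(fail_on: str = "ERROR") -> ReportProfile:
    """The built-in check battery with its default severity levels."""
    checks = []
    for name, level in _DEFAULT_LEVELS:
        if name == "equivalent_class_pair":
            checks.append(
                Check(name, level, builtin=_equivalent_class_pairs, doc_url=_DOCS + name.replace("_", "-"))
            )
        else:
            body, prop = _QUERIES[name]
            checks.append(
                Check(
                    name,
                    level,
                    query=_PREFIX_BLOCK + body,
                    property=Identifier(prop) if prop else None,
                    doc_url=_DOCS + name.replace("_", "-"),
                )
            )
    return ReportProfile(checks=checks, fail_on=fail_on)


def load_profile(path, fail_on: str = "ERROR") -> ReportProfile:
    """Profile file: one check per line, ``LEVEL<TAB>name[<TAB>query-path]``.

    Lines override the default battery's levels; ``EXCLUDE<TAB>name`` drops a
    check; a line with a query path adds (or replaces with) a custom SPARQL
    check, the path resolving against the profile file's directory."""
    base = os.path.dirname(os.path.abspath(str(path)))
    profile = default_profile(fail_on=fail_on)
    by_name = {c.name: c for c in profile.checks}
    order = [c.name for c in profile.checks]
    for lineno, raw in enumerate(open(path, encoding="utf-8"), start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise ProfileError(f"{path}:{lineno}: expected LEVEL<TAB>name")
        level, name = parts[0].strip().upper(), parts[1].strip()
        if level == "EXCLUDE":
            by_name.pop(name, None)
            continue
        if level not in LEVELS:
            raise ProfileError(f"{path}:{lineno}: bad level {parts[0]!r}")
        if len(parts) >= 3:
            query_path = os.path.normpath(os.path.join(base, parts[2].strip()))
            try:
                query = open(query_path, encoding="utf-8").read()
            except OSError as exc:
                raise ProfileError(f"{path}:{lineno}: cannot read query for {name}: {exc}") from exc
            by_name[name] = Check(name, level, query=query, doc_url=_DOCS + "custom-checks")
            if name not in order:
                order.append(name)
        elif name in by_name:
            by_name[name] = replace(by_name[name], level=level)
        else:
            raise ProfileError(f"{path}:{lineno}: unknown check {name!r} (custom checks need a query path)")
    return ReportProfile(checks=[by_name[n] for n in order if n in by_name], fail_on=fail_on)


# ---------------------------------------------------------------------------
# running


def run_report(doc: OntologyDocument, profile: Optional[ReportProfile] = None) -> Tuple[List[Violation], bool]:
    from .errors import SparqlParseError

    if profile is None:
        profile = default_profile()
    view = to_graph_view(doc)
    violations: List[Violation] = []
    for check in profile.checks:
        if check.builtin is not None:
            found = [replace(v, level=check.level) for v in check.builtin(doc)]
        else:
            try:
                table = run_select(view, check.query, path=check.name)
            except SparqlParseError as exc:
                raise ProfileError(f"check {check.name!r}: {exc}") from exc
            found = []
            cols = {name: idx for idx, name in enumerate(table.header)}
            for row in table.rows:
                subject = row[cols["subject"]] if "subject" in cols else ""
                prop = row[cols["property"]] if "property" in cols else None
                value = row[cols["value"]] if "value" in cols else ""
                found.append(
                    Violation(
                        rule_name=check.name,
                        level=check.level,
                        subject=Identifier(subject),
                        property=Identifier(prop) if prop else check.property,
                        value=value,
                    )
                )
        violations.extend(found)
    violations.sort(key=Violation.sort_key)
    if profile.fail_on in LEVELS:
        threshold = _LEVEL_RANK[profile.fail_on]
        failed = any(_LEVEL_RANK[v.level] <= threshold for v in violations)
    else:
        failed = False
    return violations, failed


_COLUMNS = ("level", "rule", "subject", "property", "value")


def _violation_row(v: Violation) -> Tuple[str, str, str, str, str]:
    return (v.level, v.rule_name, v.subject.iri, v.property.iri if v.property else "", v.value)


def write_report(violations: Sequence[Violation], format: str, path) -> None:
    """TSV/CSV spreadsheet or YAML list; deterministic order."""
    rows = [_violation_row(v) for v in sorted(violations, key=Violation.sort_key)]
    if format == "yaml":
        data = [dict(zip(_COLUMNS, row)) for row in rows]
        with open(path, "w", encoding="utf-8") as handle:
            yaml.safe_dump(data, handle, sort_keys=True, allow_unicode=True)
        return
    if format not in ("tsv", "csv"):
        raise ProfileError(f"unknown report format {format!r}")
    with open(path, "w", encoding="utf-8", newline="") as handle:
        if format == "tsv":
            writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        else:
            writer = csv.writer(handle, lineterminator="\r\n")
        writer.writerow(_COLUMNS)
        writer.writerows(rows)


def read_report_yaml(path) -> List[Violation]:
    data = yaml.safe_load(open(path, encoding="utf-8")) or []
    out = []
    for item in data:
        out.append(
            Violation(
                rule_name=item["rule"],
                level=item["level"],
                subject=Identifier(item["subject"]),
                property=Identifier(item["property"]) if item.get("property") else None,
                value=item.get("value", ""),
            )
        )
    return out


# ---------------------------------------------------------------------------
# repair


def _replacement_map(doc: OntologyDocument) -> Dict[Identifier, Identifier]:
    deprecated: Set[Identifier] = set()
    replaced: Dict[Identifier, Identifier] = {}
    for ax in doc.axioms:
        if not isinstance(ax, AnnotationAssertion):
            continue
        if ax.property.iri == vocab.OWL_DEPRECATED and isinstance(ax.value, Literal) and ax.value.lexical == "true":
            deprecated.add(ax.subject)
        elif ax.property.iri == vocab.REPLACED_BY and isinstance(ax.value, Identifier):
            replaced[ax.subject] = ax.value
    direct = {d: replaced[d] for d in deprecated if d in replaced}

    resolved: Dict[Identifier, Identifier] = {}
    for start in direct:
        seen = [start]
        node = start
        while node in direct:
            node = direct[node]
            if node in seen:
                cycle = " -> ".join(str(x) for x in seen + [node])
                raise RepairError(f"replacement cycle: {cycle}")
            seen.append(node)
        resolved[start] = node
    return resolved


def _rewrite_ce(ce: ClassExpression, mapping) -> ClassExpression:
    if isinstance(ce, Named):
        return Named(mapping.get(ce.cls, ce.cls))
    if isinstance(ce, Some):
        return Some(ce.property, _rewrite_ce(ce.filler, mapping))
    ops = frozenset(_rewrite_ce(op, mapping) for op in ce.operands)
    if len(ops) == 1:
        return next(iter(ops))
    return And(ops)


def repair(doc: OntologyDocument) -> OntologyDocument:
    """(1) collapse duplicate axioms, merging their annotations; (2) rewrite
    logical-axiom references to deprecated classes onto their suggested
    replacements (transitively). Annotations on the deprecated term itself
    are retained."""
    out = doc.copy()

    # 1. merge annotations on duplicate axioms
    groups: Dict[Axiom, List[Axiom]] = {}
    for ax in out.axioms:
        groups.setdefault(strip_annotations(ax), []).append(ax)
    merged: Set[Axiom] = set()
    for bare, members in groups.items():
        if len(members) == 1:
            merged.add(members[0])
        else:
            anns = frozenset(pair for ax in members for pair in ax.annotations)
            merged.add(replace(bare, annotations=anns))
    out.axioms = merged

    # 2. rewrite references to deprecated classes
    mapping = _replacement_map(out)
    if mapping:
        rewritten: Set[Axiom] = set()
        for ax in out.axioms:
            if isinstance(ax, SubClassOf):
                ax2 = replace(ax, sub=_rewrite_ce(ax.sub, mapping), sup=_rewrite_ce(ax.sup, mapping))
                if ax2.sub == ax2.sup:
                    continue  # rewrite created a tautology; drop it
                rewritten.add(ax2)
            elif isinstance(ax, EquivalentClasses):
                members = frozenset(_rewrite_ce(m, mapping) for m in ax.members)
                if len(members) >= 2:
                    rewritten.add(replace(ax, members=members))
            elif isinstance(ax, DisjointClasses):
                members = frozenset(mapping.get(m, m) for m in ax.members)
                if len(members) >= 2:
                    rewritten.add(replace(ax, members=members))
            else:
                rewritten.add(ax)
        out.axioms = rewritten
    return out
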