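"""OBO flat-file 1.4 reader and writer (subset).

The OBO-expressible subset is: class and property declarations ([Term] /
[Typedef], annotation properties via ``is_metadata_tag``), ``name``, ``def``
(with its xref list as axiom annotations), ``subset``, ``xref``, ``is_a``
between named classes, ``relationship`` for ``A ⊑ R some B``,
``equivalent_to`` / ``intersection_of`` definitions, ``is_obsolete`` and
``replaced_by``. An axiom is only expressible when its subject term is
*declared* in the document (a stanza implies a declaration on read, so
undeclared subjects would not round-trip). Identifier translation follows the
standard OBO rule: ``X:123`` ↔ ``http://purl.obolibrary.org/obo/X_123``.
"""

from __future__ import annotations

import re
from typing import Dict, Iterable, List, Optional, Set, Tuple

from . import vocab
from .errors import ConversionError, ParseError, UnsupportedConstructError
from .model import (
    And,
    AnnotationAssertion,
    Axiom,
    Declaration,
    EquivalentClasses,
    Identifier,
    Literal,
    Named,
    OntologyDocument,
    Some,
    SubClassOf,
    axiom_sort_key,
    intersection,
)

_OBO_ID_RE = re.compile(r"^([A-Za-z_][A-Za-z0-9_]*):([A-Za-z0-9_.-]+)$")


def obo_id_to_iri(obo_id: str, default_ns: str = vocab.OBO) -> Identifier:
    if obo_id.startswith("http://") or obo_id.startswith("https://") or obo_id.startswith("urn:"):
        return Identifier(obo_id)
    m = _OBO_ID_RE.match(obo_id)
    if m:
        return Identifier(vocab.OBO + f"{m.group(1)}_{m.group(2)}")
    return Identifier(default_ns + obo_id)


def iri_to_obo_id(iri: str) -> str:
    if iri.startswith(vocab.OBO):
        rest = iri[len(vocab.OBO):]
        if "#" in rest:
            return rest.split("#", 1)[1]
        if "_" in rest and "/" not in rest:
            prefix, local = rest.rsplit("_", 1)
            return f"{prefix}:{local}"
    return iri


# ---------------------------------------------------------------------------
# expressibility


_TERM_ANNOTATIONS = {
    vocab.RDFS_LABEL: "name",
    vocab.DEFINITION: "def",
    vocab.IN_SUBSET: "subset",
    vocab.XREF: "xref",
    vocab.OWL_DEPRECATED: "is_obsolete",
    vocab.REPLACED_BY: "replaced_by",
}


def _declared(doc: OntologyDocument) -> Dict[Identifier, str]:
    return {ax.entity: ax.entity_type for ax in doc.axioms if isinstance(ax, Declaration)}


def _expressible(ax: Axiom, declared: Dict[Identifier, str]) -> bool:
    if isinstance(ax, Declaration):
        return ax.entity_type in ("class", "object_property", "annotation_property")
    if isinstance(ax, AnnotationAssertion):
        if ax.subject not in declared or ax.property.iri not in _TERM_ANNOTATIONS:
            return False
        if ax.annotations and not (
            ax.property.iri == vocab.DEFINITION
            and all(
                p.iri == vocab.XREF and isinstance(v, Literal) and not v.lang and not v.datatype
                for p, v in ax.annotations
            )
        ):
            return False
        if ax.property.iri == vocab.REPLACED_BY:
            return isinstance(ax.value, Identifier)
        if ax.property.iri == vocab.OWL_DEPRECATED:
            return isinstance(ax.value, Literal) and ax.value == Literal("true", datatype=vocab.XSD_BOOLEAN)
        # only plain literals survive the OBO tag syntax unchanged
        return isinstance(ax.value, Literal) and not ax.value.lang and not ax.value.datatype
    if ax.annotations:
        return False
    if isinstance(ax, SubClassOf):
        if not isinstance(ax.sub, Named) or declared.get(ax.sub.cls) != "class":
            return False
        if isinstance(ax.sup, Named):
            return True
        return (
            isinstance(ax.sup, Some)
            and isinstance(ax.sup.filler, Named)
        )
    if isinstance(ax, EquivalentClasses):
        if len(ax.members) != 2:
            return False
        named = [m for m in ax.sorted_members() if isinstance(m, Named) and declared.get(m.cls) == "class"]
        if not named:
            return False
        other = next(m for m in ax.sorted_members() if m is not named[0])
        if isinstance(other, Named):
            return True
        if isinstance(other, And):
            return all(
                isinstance(op, Named) or (isinstance(op, Some) and isinstance(op.filler, Named))
                for op in other.operands
            )
        return False
    return False  # disjointness, subPropertyOf, individuals


def obo_expressible_subset(doc: OntologyDocument) -> Set[Axiom]:
    declared = _declared(doc)
    return {ax for ax in doc.axioms if _expressible(ax, declared)}


# ---------------------------------------------------------------------------
# writer


def _quote(text: str) -> str:
    return '"' + text.replace("\\", "\\\\").replace('"', '\\"').replace("\n", "\\n") + '"'


def _ontology_id(doc: OntologyDocument) -> Optional[str]:
    if doc.ontology_iri is None:
        return None
    iri = doc.ontology_iri.iri
    m = re.match(r"^http://purl\.obolibrary\.org/obo/([A-Za-z0-9_-]+)\.(owl|obo)$", iri)
    return m.group(1) if m else iri


def write_obo(doc: OntologyDocument, strict: bool = False) -> str:
    """Serialize the OBO-expressible subset deterministically.

    With ``strict`` any non-expressible axiom raises
    :class:`~owlkit.errors.ConversionError` listing the offenders; by default
    they are silently restricted away (the ROBOT-style lossy conversion)."""
    expressible = obo_expressible_subset(doc)
    dropped = doc.axioms - expressible
    if strict and dropped:
        from .model import render_axiom

        raise ConversionError(
            "axioms not expressible in OBO format:\n"
            + "\n".join(sorted(render_axiom(ax) for ax in dropped)),
            axioms=dropped,
        )

    lines = ["format-version: 1.4"]
    if doc.version_iri is not None:
        lines.append(f"data-version: {doc.version_iri.iri}")
    ont_id = _ontology_id(doc)
    if ont_id is not None:
        lines.append(f"ontology: {ont_id}")
    for imp in doc.imports:
        lines.append(f"import: {imp.iri}")
    for prop, value in sorted(
        doc.ontology_annotations, key=lambda pv: (pv[0].iri, str(pv[1]))
    ):
        if isinstance(value, Identifier):
            lines.append(f"property_value: {iri_to_obo_id(prop.iri)} {iri_to_obo_id(value.iri)}")
        else:
            lines.append(f"property_value: {iri_to_obo_id(prop.iri)} {_quote(value.lexical)}")

    declared = _declared(doc)
    stanzas: Dict[Identifier, List[str]] = {}
    kinds: Dict[Identifier, str] = {}
    for entity, etype in declared.items():
        if etype == "class":
            kinds[entity] = "Term"
        elif etype in ("object_property", "annotation_property"):
            kinds[entity] = "Typedef"
        else:
            continue
        stanzas[entity] = []

    def tag(entity: Identifier, line: str):
        stanzas[entity].append(line)

    for ax in sorted(expressible, key=axiom_sort_key):
        if isinstance(ax, Declaration):
            if ax.entity_type == "annotation_property":
                tag(ax.entity, "is_metadata_tag: true")
        elif isinstance(ax, AnnotationAssertion):
            kind = _TERM_ANNOTATIONS[ax.property.iri]
            if kind == "def":
                xrefs = sorted(v.lexical for _p, v in ax.annotations)
                tag(ax.subject, f"def: {_quote(ax.value.lexical)} [{', '.join(xrefs)}]")
            elif kind == "is_obsolete":
                if ax.value.lexical == "true":
                    tag(ax.subject, "is_obsolete: true")
            elif kind == "replaced_by":
                v = ax.value.iri if isinstance(ax.value, Identifier) else ax.value.lexical
                tag(ax.subject, f"replaced_by: {iri_to_obo_id(v)}")
            elif kind == "name":
                tag(ax.subject, f"name: {ax.value.lexical}")
            else:
                tag(ax.subject, f"{kind}: {ax.value.lexical}")
        elif isinstance(ax, SubClassOf):
            if isinstance(ax.sup, Named):
                tag(ax.sub.cls, f"is_a: {iri_to_obo_id(ax.sup.cls.iri)}")
            else:
                rel = iri_to_obo_id(ax.sup.property.iri)
                tag(ax.sub.cls, f"relationship: {rel} {iri_to_obo_id(ax.sup.filler.cls.iri)}")
        elif isinstance(ax, EquivalentClasses):
            members = ax.sorted_members()
            named = next(
                m for m in members if isinstance(m, Named) and declared.get(m.cls) == "class"
            )
            other = next(m for m in members if m is not named)
            if isinstance(other, Named):
                tag(named.cls, f"equivalent_to: {iri_to_obo_id(other.cls.iri)}")
            else:
                from .model import render_expression

                for op in sorted(other.operands, key=lambda o: (isinstance(o, Some), render_expression(o))):
                    if isinstance(op, Named):
                        tag(named.cls, f"intersection_of: {iri_to_obo_id(op.cls.iri)}")
                    else:
                        rel = iri_to_obo_id(op.property.iri)
                        tag(named.cls, f"intersection_of: {rel} {iri_to_obo_id(op.filler.cls.iri)}")

    _TAG_ORDER = [
        "name:", "def:", "subset:", "xref:", "is_a:", "intersection_of:",
        "equivalent_to:", "relationship:", "is_obsolete:", "replaced_by:",
        "is_metadata_tag:",
    ]

    def line_key(line: str) -> tuple:
        for i, prefix in enumerate(_TAG_ORDER):
            if line.startswith(prefix):
                return (i, line)
        return (len(_TAG_ORDER), line)

    out = ["\n".join(lines)]
    for entity in sorted(stanzas, key=lambda e: iri_to_obo_id(e.iri)):
        body = [f"[{kinds[entity]}]", f"id: {iri_to_obo_id(entity.iri)}"]
        seen = set()
        for line in sorted(stanzas[entity], key=line_key):
            if line not in seen:
                seen.add(line)
                body.append(line)
        out.append("\n".join(body))
    return "\n\n".join(out) + "\n"


# ---------------------------------------------------------------------------
# reader


_DEF_RE = re.compile(r'^"((?:[^"\\]|\\.)*)"\s*(?:\[([^\]]*)\])?\s*$')


def _unescape(text: str) -> str:
    return text.replace('\\"', '"').replace("\\n", "\n").replace("\\\\", "\\")


def _strip_comment(value: str) -> str:
    in_quote = False
    for i, c in enumerate(value):
        if c == '"' and (i == 0 or value[i - 1] != "\\"):
            in_quote = not in_quote
        elif c == "!" and not in_quote:
            return value[:i].rstrip()
    return value


def parse_obo(text: str, path=None) -> OntologyDocument:
    doc = OntologyDocument(prefixes=dict(vocab.DEFAULT_PREFIXES))
    current: Optional[Identifier] = None
    stanza_kind: Optional[str] = None
    intersections: List[Tuple[int, str]] = []
    pending_metadata_tag = False

    def finish_stanza(lineno: int):
        nonlocal intersections, pending_metadata_tag
        if current is not None and intersections:
            if len(intersections) < 2:
                raise ParseError("intersection_of needs at least two lines", path, intersections[0][0])
            ops = []
            for ln, value in intersections:
                parts = value.split()
                if len(parts) == 1:
                    ops.append(Named(obo_id_to_iri(parts[0])))
                elif len(parts) == 2:
                    ops.append(Some(obo_id_to_iri(parts[0]), Named(obo_id_to_iri(parts[1]))))
                else:
                    raise ParseError(f"bad intersection_of value {value!r}", path, ln)
            doc.axioms.add(
                EquivalentClasses(frozenset({Named(current), intersection(ops)}))
            )
        if current is not None and pending_metadata_tag:
            doc.axioms.discard(Declaration(current, "object_property"))
            doc.axioms.add(Declaration(current, "annotation_property"))
        intersections = []
        pending_metadata_tag = False

    in_header = True
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = _strip_comment(raw.strip())
        if not line:
            continue
        if line.startswith("["):
            finish_stanza(lineno)
            if line == "[Term]":
                stanza_kind = "class"
            elif line == "[Typedef]":
                stanza_kind = "object_property"
            else:
                raise UnsupportedConstructError(f"stanza {line}", path, lineno)
            in_header = False
            current = None
            continue
        if ":" not in line:
            raise ParseError(f"malformed line {raw!r}", path, lineno)
        tag_name, value = line.split(":", 1)
        value = value.strip()

        if in_header:
            if tag_name == "format-version":
                continue
            if tag_name == "ontology":
                if re.match(r"^[A-Za-z][A-Za-z0-9+.-]*:", value):
                    doc.ontology_iri = Identifier(value)
                else:
                    doc.ontology_iri = Identifier(vocab.OBO + value + ".owl")
            elif tag_name == "data-version":
                doc.version_iri = Identifier(value)
            elif tag_name == "import":
                doc.imports.append(Identifier(value))
            elif tag_name == "property_value":
                parts = value.split(None, 1)
                if len(parts) != 2:
                    raise ParseError(f"bad property_value {value!r}", path, lineno)
                prop = obo_id_to_iri(parts[0])
                rest = parts[1].strip()
                if rest.startswith('"'):
                    m = _DEF_RE.match(rest)
                    if not m:
                        raise ParseError(f"bad property_value literal {rest!r}", path, lineno)
                    doc.ontology_annotations.add((prop, Literal(_unescape(m.group(1)))))
                else:
                    doc.ontology_annotations.add((prop, obo_id_to_iri(rest)))
            else:
                raise UnsupportedConstructError(f"header tag {tag_name!r}", path, lineno)
            continue

        if tag_name == "id":
            current = obo_id_to_iri(value)
            doc.axioms.add(Declaration(current, stanza_kind))
            m = _OBO_ID_RE.match(value)
            if m:
                doc.prefixes.setdefault(m.group(1), vocab.OBO + m.group(1) + "_")
            continue
        if current is None:
            raise ParseError("tag before id", path, lineno)

        if tag_name == "name":
            doc.axioms.add(AnnotationAssertion(current, Identifier(vocab.RDFS_LABEL), Literal(value)))
        elif tag_name == "def":
            m = _DEF_RE.match(value)
            if not m:
                raise ParseError(f"bad def line {value!r}", path, lineno)
            anns = frozenset(
                (Identifier(vocab.XREF), Literal(x.strip()))
                for x in (m.group(2) or "").split(",")
                if x.strip()
            )
            doc.axioms.add(
                AnnotationAssertion(current, Identifier(vocab.DEFINITION), Literal(_unescape(m.group(1))), anns)
            )
        elif tag_name == "subset":
            doc.axioms.add(AnnotationAssertion(current, Identifier(vocab.IN_SUBSET), Literal(value)))
        elif tag_name == "xref":
            doc.axioms.add(AnnotationAssertion(current, Identifier(vocab.XREF), Literal(value)))
        elif tag_name == "is_a":
            if stanza_kind != "class":
                raise UnsupportedConstructError("is_a in [Typedef]", path, lineno)
            doc.axioms.add(SubClassOf(Named(current), Named(obo_id_to_iri(value))))
        elif tag_name == "relationship":
            parts = value.split()
            if len(parts) != 2:
                raise ParseError(f"bad relationship value {value!r}", path, lineno)
            doc.axioms.add(
                SubClassOf(Named(current), Some(obo_id_to_iri(parts[0]), Named(obo_id_to_iri(parts[1]))))
            )
        elif tag_name == "intersection_of":
            intersections.append((lineno, value))
        elif tag_name == "equivalent_to":
            doc.axioms.add(
                EquivalentClasses(frozenset({Named(current), Named(obo_id_to_iri(value))}))
            )
        elif tag_name == "is_obsolete":
            if value == "true":
                doc.axioms.add(
                    AnnotationAssertion(
                        current,
                        Identifier(vocab.OWL_DEPRECATED),
                        Literal("true", datatype=vocab.XSD_BOOLEAN),
                    )
                )
        elif tag_name == "replaced_by":
            doc.axioms.add(
                AnnotationAssertion(current, Identifier(vocab.REPLACED_BY), obo_id_to_iri(value))
            )
        elif tag_name == "is_metadata_tag":
            if value == "true":
                pending_metadata_tag = True
        else:
            raise UnsupportedConstructError(f"tag {tag_name!r}", path, lineno)

    finish_stanza(len(text.splitlines()) + 1)
    return doc
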