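"""Whole-document algebra: merge, remove, filter, annotate, diff, and the
entity selectors they share."""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Sequence, Set, Tuple, Union

from .errors import ConfigurationError, PatternError, UsageError
from .model import (
    AnnotationAssertion,
    AnnotationPair,
    Axiom,
    Declaration,
    DisjointClasses,
    EquivalentClasses,
    Identifier,
    Literal,
    OntologyDocument,
    SubClassOf,
    SubPropertyOf,
    Named,
    axiom_set_merge,
    axiom_signature,
    axiom_sort_key,
    is_logical,
    render_axiom,
    signature_of,
)


# ---------------------------------------------------------------------------
# Selectors


@dataclass(frozen=True)
class SelfSelector:
    pass


@dataclass(frozen=True)
class Ancestors:
    pass


@dataclass(frozen=True)
class Descendants:
    pass


@dataclass(frozen=True)
class AnnotationMatch:
    property: Identifier
    value: str
    is_regex: bool = False


@dataclass(frozen=True)
class EntityTypeSelector:
    entity_type: str


Selector = Union[SelfSelector, Ancestors, Descendants, AnnotationMatch, EntityTypeSelector]


def _subclass_edges(doc: OntologyDocument) -> List[Tuple[Identifier, Identifier]]:
    return [
        (ax.sub.cls, ax.sup.cls)
        for ax in doc.axioms
        if isinstance(ax, SubClassOf) and isinstance(ax.sub, Named) and isinstance(ax.sup, Named)
    ]


def _reach(edges, seeds, forward: bool) -> Set[Identifier]:
    adj = {}
    for sub, sup in edges:
        a, b = (sub, sup) if forward else (sup, sub)
        adj.setdefault(a, set()).add(b)
    out: Set[Identifier] = set()
    stack = list(seeds)
    while stack:
        n = stack.pop()
        for m in adj.get(n, ()):
            if m not in out:
                out.add(m)
                stack.append(m)
    return out - set(seeds)


def select_entities(
    doc: OntologyDocument,
    seed: Iterable[Identifier],
    selectors: Sequence[Selector],
) -> Set[Identifier]:
    """Apply selectors left-to-right, each mapping the current entity set to a
    new one. ``AnnotationMatch`` ignores the incoming set and selects every
    entity carrying a matching annotation value."""
    current: Set[Identifier] = set(seed)
    edges = _subclass_edges(doc)
    for sel in selectors:
        if isinstance(sel, SelfSelector):
            pass
        elif isinstance(sel, Ancestors):
            current = _reach(edges, current, forward=True)
        elif isinstance(sel, Descendants):
            current = _reach(edges, current, forward=False)
        elif isinstance(sel, AnnotationMatch):
            if sel.is_regex:
                try:
                    pattern = re.compile(sel.value)
                except re.error as exc:
                    raise PatternError(f"bad regex {sel.value!r}: {exc}") from exc
                match = lambda s: pattern.fullmatch(s) is not None  # noqa: E731
            else:
                match = lambda s: s == sel.value  # noqa: E731
            current = {
                ax.subject
                for ax in doc.axioms
                if isinstance(ax, AnnotationAssertion)
                and ax.property == sel.property
                and match(ax.value.iri if isinstance(ax.value, Identifier) else ax.value.lexical)
            }
        elif isinstance(sel, EntityTypeSelector):
            sig = signature_of(doc)
            by_type = {
                "class": sig.classes,
                "object_property": sig.object_properties,
                "annotation_property": sig.annotation_properties,
                "individual": sig.individuals,
            }
            if sel.entity_type not in by_type:
                raise UsageError(f"unknown entity type {sel.entity_type!r}")
            current = current & by_type[sel.entity_type]
        else:
            raise UsageError(f"unknown selector {sel!r}")
    return current


# ---------------------------------------------------------------------------
# Axiom type filters


AXIOM_TYPE_KEYS = ("logical", "annotation", "declaration", "subclass", "equivalent", "disjoint", "all")


def _type_matches(ax: Axiom, types: Set[str]) -> bool:
    if "all" in types:
        return True
    if "logical" in types and is_logical(ax):
        return True
    if "annotation" in types and isinstance(ax, AnnotationAssertion):
        return True
    if "declaration" in types and isinstance(ax, Declaration):
        return True
    if "subclass" in types and isinstance(ax, SubClassOf):
        return True
    if "equivalent" in types and isinstance(ax, EquivalentClasses):
        return True
    if "disjoint" in types and isinstance(ax, DisjointClasses):
        return True
    return False


def _selected(doc: OntologyDocument, entities: Set[Identifier], types: Set[str]) -> Set[Axiom]:
    """The shared selection predicate: axioms of a selected type whose
    signature intersects the entity set. `remove` deletes exactly these and
    `filter` copies exactly these, so the two commands partition the input's
    axioms of the selected types (declarations aside, see below)."""
    bad = set(types) - set(AXIOM_TYPE_KEYS)
    if bad:
        raise UsageError(f"unknown axiom types: {sorted(bad)}")
    if not types:
        raise UsageError("empty axiom type filter")
    return {
        ax
        for ax in doc.axioms
        if _type_matches(ax, types) and (axiom_signature(ax) & entities)
    }


def remove_axioms(doc: OntologyDocument, entities: Iterable[Identifier], types: Iterable[str]) -> OntologyDocument:
    entities, types = set(entities), set(types)
    selected = _selected(doc, entities, types)
    out = doc.copy()
    out.axioms -= selected
    # declarations survive while the entity is still referenced elsewhere
    referenced: Set[Identifier] = set()
    for ax in out.axioms:
        if not isinstance(ax, Declaration):
            referenced |= axiom_signature(ax)
    for ax in selected:
        if isinstance(ax, Declaration) and ax.entity in referenced:
            out.axioms.add(ax)
    return out


def filter_axioms(doc: OntologyDocument, entities: Iterable[Identifier], types: Iterable[str]) -> OntologyDocument:
    entities, types = set(entities), set(types)
    selected = _selected(doc, entities, types)
    out = OntologyDocument(
        ontology_iri=doc.ontology_iri,
        version_iri=doc.version_iri,
        prefixes=dict(doc.prefixes),
        ontology_annotations=set(doc.ontology_annotations),
    )
    out.axioms = set(selected)
    kept_entities = signature_of(out.axioms).all_entities() | {
        e for ax in out.axioms for e in axiom_signature(ax)
    }
    for ax in doc.axioms:
        if isinstance(ax, Declaration) and ax.entity in kept_entities:
            out.axioms.add(ax)
    return out


# ---------------------------------------------------------------------------
# merge / annotate / diff


def merge(
    docs: Sequence[OntologyDocument],
    collapse_import_closure: bool = True,
    catalog=None,
) -> OntologyDocument:
    """Axiom-set union. Ontology IRI and annotations come from the first
    input; prefix maps are merged first-wins. With
    ``collapse_import_closure`` the resolved import closures are folded in and
    the output carries no import statements."""
    if not docs:
        raise UsageError("merge needs at least one input")
    from .io import resolve_imports  # local import to avoid a cycle

    first = docs[0]
    out = first.copy()
    for doc in docs[1:]:
        out.axioms = axiom_set_merge(out.axioms, doc.axioms)
        for prefix, ns in doc.prefixes.items():
            out.prefixes.setdefault(prefix, ns)
        for imp in doc.imports:
            if imp not in out.imports:
                out.imports.append(imp)
    if collapse_import_closure:
        closure_docs: List[OntologyDocument] = []
        for doc in docs:
            closure_docs.extend(resolve_imports(doc, catalog))
        for doc in closure_docs:
            out.axioms = axiom_set_merge(out.axioms, doc.axioms)
            for prefix, ns in doc.prefixes.items():
                out.prefixes.setdefault(prefix, ns)
        out.imports = []
    return out


_IRI_RE = re.compile(r"^[A-Za-z][A-Za-z0-9+.-]*:\S+$")


def annotate(
    doc: OntologyDocument,
    ontology_annotations: Iterable[AnnotationPair] = (),
    version_iri: Optional[Identifier] = None,
    ontology_iri: Optional[Identifier] = None,
) -> OntologyDocument:
    """Set/overwrite the version IRI and add ontology-level annotations;
    axioms are untouched."""
    out = doc.copy()
    for iri in (version_iri, ontology_iri):
        if iri is not None and not _IRI_RE.match(iri.iri):
            raise ConfigurationError(f"malformed IRI: {iri.iri!r}")
    if version_iri is not None:
        out.version_iri = version_iri
    if ontology_iri is not None:
        out.ontology_iri = ontology_iri
    out.ontology_annotations |= set(ontology_annotations)
    return out


@dataclass
class DiffResult:
    only_in_left: Set[Axiom] = field(default_factory=set)
    only_in_right: Set[Axiom] = field(default_factory=set)

    def identical(self) -> bool:
        return not self.only_in_left and not self.only_in_right

    def render(self) -> str:
        lines = []
        for ax in sorted(self.only_in_left, key=axiom_sort_key):
            lines.append(f"- {render_axiom(ax)}")
        for ax in sorted(self.only_in_right, key=axiom_sort_key):
            lines.append(f"+ {render_axiom(ax)}")
        return "\n".join(lines) + ("\n" if lines else "")


def diff(left: OntologyDocument, right: OntologyDocument) -> DiffResult:
    """Symmetric axiom-set difference under logical + annotation equality.
    Compares axiom sets, never serialized text, so serializer noise cannot
    produce spurious differences."""
    return DiffResult(
        only_in_left=left.axioms - right.axioms,
        only_in_right=right.axioms - left.axioms,
    )
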