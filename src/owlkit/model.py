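"""Core OWL data model.

The toolkit works over a deliberately small fragment of OWL 2: named classes,
existential restrictions (``R some B``) and intersections on the class side;
subclass, equivalence, disjointness and subproperty axioms on the logical
side; plus entity declarations and annotation assertions. Everything richer
is rejected at parse time, never silently dropped.

All axiom objects are immutable and hashable. Two axioms are equal iff both
their logical content *and* their axiom annotations are equal, so a document
may legitimately hold two "duplicate" axioms that share logical content and
differ in provenance annotations — the situation `repair` collapses.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import FrozenSet, Iterable, Iterator, List, Optional, Set, Tuple, Union

from . import vocab
from .errors import PrefixError, RoleConflictError


# ---------------------------------------------------------------------------
# Identifiers and literals


@dataclass(frozen=True, order=True)
class Identifier:
    """An entity named by an absolute IRI. Equality is IRI string equality."""

    iri: str

    def __str__(self) -> str:
        return self.iri


@dataclass(frozen=True, order=True)
class Literal:
    """An RDF literal: (lexical form, datatype IRI, language tag) triple."""

    lexical: str
    datatype: Optional[str] = None
    lang: Optional[str] = None

    def __str__(self) -> str:
        return self.lexical


AnnotationValue = Union[Literal, Identifier]
AnnotationPair = Tuple[Identifier, AnnotationValue]

_LOCAL_RE = re.compile(r"^[A-Za-z0-9_][A-Za-z0-9_.-]*$")


def expand_curie(curie: str, prefixes: dict) -> Identifier:
    """Expand ``prefix:local`` under a prefix map. Absolute IRIs pass through."""
    if curie.startswith("http://") or curie.startswith("https://") or curie.startswith("urn:"):
        return Identifier(curie)
    if curie.startswith("<") and curie.endswith(">"):
        return Identifier(curie[1:-1])
    if ":" not in curie:
        raise PrefixError(f"not a CURIE or absolute IRI: {curie!r}")
    prefix, local = curie.split(":", 1)
    if prefix not in prefixes:
        raise PrefixError(f"undeclared prefix {prefix!r} in {curie!r}")
    return Identifier(prefixes[prefix] + local)


def contract_iri(iri: str, prefixes: dict) -> Optional[str]:
    """Contract an IRI to a CURIE: longest matching namespace wins, ties
    broken lexicographically by prefix name. Returns None when no prefix
    matches or the local part would not be CURIE-safe."""
    best = None
    for prefix, ns in sorted(prefixes.items()):
        if ns and iri.startswith(ns) and len(iri) > len(ns):
            if best is None or len(ns) > len(best[1]):
                best = (prefix, ns)
    if best is None:
        return None
    prefix, ns = best
    local = iri[len(ns):]
    if not _LOCAL_RE.match(local):
        return None
    return f"{prefix}:{local}"


# ---------------------------------------------------------------------------
# Class expressions


class ClassExpression:
    """Marker base class; see :class:`Named`, :class:`Some`, :class:`And`."""

    __slots__ = ()


@dataclass(frozen=True)
class Named(ClassExpression):
    cls: Identifier


@dataclass(frozen=True)
class Some(ClassExpression):
    property: Identifier
    filler: ClassExpression


@dataclass(frozen=True)
class And(ClassExpression):
    """An intersection; operands are an unordered set, never nested ``And``s.

    Build through :func:`intersection`, which flattens and deduplicates.
    """

    operands: FrozenSet[ClassExpression]

    def __post_init__(self):
        if len(self.operands) < 2:
            raise ValueError("intersection needs at least 2 distinct operands")
        if any(isinstance(op, And) for op in self.operands):
            raise ValueError("nested intersections must be flattened")

    def sorted_operands(self) -> List[ClassExpression]:
        return sorted(self.operands, key=render_expression)


def intersection(operands: Iterable[ClassExpression]) -> ClassExpression:
    """Intersection constructor: flattens nested ``And``, deduplicates, and
    collapses a singleton to its only operand."""
    flat: Set[ClassExpression] = set()
    for op in operands:
        if isinstance(op, And):
            flat.update(op.operands)
        else:
            flat.add(op)
    if not flat:
        raise ValueError("empty intersection")
    if len(flat) == 1:
        return next(iter(flat))
    return And(frozenset(flat))


def render_expression(ce: ClassExpression) -> str:
    """Canonical textual rendering; used for sorting and deterministic
    auxiliary-name generation."""
    if isinstance(ce, Named):
        return ce.cls.iri
    if isinstance(ce, Some):
        return f"({ce.property.iri} some {render_expression(ce.filler)})"
    if isinstance(ce, And):
        return "(and " + " ".join(render_expression(op) for op in ce.sorted_operands()) + ")"
    raise TypeError(f"not a class expression: {ce!r}")


def expression_classes(ce: ClassExpression) -> Set[Identifier]:
    if isinstance(ce, Named):
        return {ce.cls}
    if isinstance(ce, Some):
        return expression_classes(ce.filler)
    out: Set[Identifier] = set()
    for op in ce.operands:
        out |= expression_classes(op)
    return out


def expression_properties(ce: ClassExpression) -> Set[Identifier]:
    if isinstance(ce, Named):
        return set()
    if isinstance(ce, Some):
        return {ce.property} | expression_properties(ce.filler)
    out: Set[Identifier] = set()
    for op in ce.operands:
        out |= expression_properties(op)
    return out


def subexpressions(ce: ClassExpression) -> Iterator[ClassExpression]:
    """Yield ce and every (strict) subexpression, depth first."""
    yield ce
    if isinstance(ce, Some):
        yield from subexpressions(ce.filler)
    elif isinstance(ce, And):
        for op in ce.sorted_operands():
            yield from subexpressions(op)


# ---------------------------------------------------------------------------
# Axioms

ENTITY_TYPES = ("class", "object_property", "annotation_property", "individual")

Annotations = FrozenSet[AnnotationPair]
NO_ANNOTATIONS: Annotations = frozenset()


@dataclass(frozen=True)
class SubClassOf:
    sub: ClassExpression
    sup: ClassExpression
    annotations: Annotations = NO_ANNOTATIONS


@dataclass(frozen=True)
class EquivalentClasses:
    members: FrozenSet[ClassExpression]
    annotations: Annotations = NO_ANNOTATIONS

    def __post_init__(self):
        if len(self.members) < 2:
            raise ValueError("equivalent_classes needs >= 2 members")

    def sorted_members(self) -> List[ClassExpression]:
        return sorted(self.members, key=render_expression)


@dataclass(frozen=True)
class DisjointClasses:
    members: FrozenSet[Identifier]
    annotations: Annotations = NO_ANNOTATIONS

    def __post_init__(self):
        if len(self.members) < 2:
            raise ValueError("disjoint_classes needs >= 2 members")

    def sorted_members(self) -> List[Identifier]:
        return sorted(self.members)


@dataclass(frozen=True)
class SubPropertyOf:
    sub: Identifier
    sup: Identifier
    annotations: Annotations = NO_ANNOTATIONS


@dataclass(frozen=True)
class AnnotationAssertion:
    subject: Identifier
    property: Identifier
    value: AnnotationValue
    annotations: Annotations = NO_ANNOTATIONS


@dataclass(frozen=True)
class Declaration:
    entity: Identifier
    entity_type: str
    annotations: Annotations = NO_ANNOTATIONS

    def __post_init__(self):
        if self.entity_type not in ENTITY_TYPES:
            raise ValueError(f"bad entity type {self.entity_type!r}")


Axiom = Union[
    SubClassOf,
    EquivalentClasses,
    DisjointClasses,
    SubPropertyOf,
    AnnotationAssertion,
    Declaration,
]

LOGICAL_AXIOM_TYPES = (SubClassOf, EquivalentClasses, DisjointClasses, SubPropertyOf)

_VARIANT_RANK = {
    Declaration: 0,
    SubClassOf: 1,
    EquivalentClasses: 2,
    DisjointClasses: 3,
    SubPropertyOf: 4,
    AnnotationAssertion: 5,
}


def strip_annotations(ax: Axiom) -> Axiom:
    """The logical content of an axiom: same axiom with no annotations."""
    if ax.annotations:
        return replace(ax, annotations=NO_ANNOTATIONS)
    return ax


def with_annotations(ax: Axiom, annotations: Iterable[AnnotationPair]) -> Axiom:
    return replace(ax, annotations=frozenset(annotations))


def render_value(value: AnnotationValue) -> str:
    if isinstance(value, Identifier):
        return value.iri
    suffix = ""
    if value.lang:
        suffix = f"@{value.lang}"
    elif value.datatype:
        suffix = f"^^{value.datatype}"
    return f'"{value.lexical}"{suffix}'


def render_axiom(ax: Axiom) -> str:
    """Deterministic rendering; drives sorted serialization and diffs."""
    if isinstance(ax, Declaration):
        body = f"Declaration({ax.entity_type} {ax.entity})"
    elif isinstance(ax, SubClassOf):
        body = f"SubClassOf({render_expression(ax.sub)} {render_expression(ax.sup)})"
    elif isinstance(ax, EquivalentClasses):
        body = "EquivalentClasses(" + " ".join(render_expression(m) for m in ax.sorted_members()) + ")"
    elif isinstance(ax, DisjointClasses):
        body = "DisjointClasses(" + " ".join(str(m) for m in ax.sorted_members()) + ")"
    elif isinstance(ax, SubPropertyOf):
        body = f"SubPropertyOf({ax.sub} {ax.sup})"
    elif isinstance(ax, AnnotationAssertion):
        body = f"AnnotationAssertion({ax.property} {ax.subject} {render_value(ax.value)})"
    else:
        raise TypeError(f"not an axiom: {ax!r}")
    if ax.annotations:
        anns = sorted(f"{p}={render_value(v)}" for p, v in ax.annotations)
        body += " [" + ", ".join(anns) + "]"
    return body


def axiom_sort_key(ax: Axiom) -> tuple:
    return (_VARIANT_RANK[type(ax)], render_axiom(ax))


def is_logical(ax: Axiom) -> bool:
    return isinstance(ax, LOGICAL_AXIOM_TYPES)


def axiom_classes(ax: Axiom) -> Set[Identifier]:
    """Named classes in class positions of the axiom."""
    if isinstance(ax, SubClassOf):
        return expression_classes(ax.sub) | expression_classes(ax.sup)
    if isinstance(ax, EquivalentClasses):
        out: Set[Identifier] = set()
        for m in ax.members:
            out |= expression_classes(m)
        return out
    if isinstance(ax, DisjointClasses):
        return set(ax.members)
    if isinstance(ax, Declaration) and ax.entity_type == "class":
        return {ax.entity}
    return set()


def axiom_signature(ax: Axiom) -> Set[Identifier]:
    """Every identifier occurring anywhere in the axiom (annotation values
    included when they are IRIs)."""
    out = axiom_classes(ax)
    if isinstance(ax, SubClassOf):
        out |= expression_properties(ax.sub) | expression_properties(ax.sup)
    elif isinstance(ax, EquivalentClasses):
        for m in ax.members:
            out |= expression_properties(m)
    elif isinstance(ax, SubPropertyOf):
        out |= {ax.sub, ax.sup}
    elif isinstance(ax, AnnotationAssertion):
        out |= {ax.subject, ax.property}
        if isinstance(ax.value, Identifier):
            out.add(ax.value)
    elif isinstance(ax, Declaration):
        out.add(ax.entity)
    for prop, value in ax.annotations:
        out.add(prop)
        if isinstance(value, Identifier):
            out.add(value)
    return out


# ---------------------------------------------------------------------------
# Documents and signatures


@dataclass
class OntologyDocument:
    """The in-memory ontology passed through every command.

    ``axioms`` is a true set, so it is duplicate-free under logical-content +
    annotation equality by construction.
    """

    ontology_iri: Optional[Identifier] = None
    version_iri: Optional[Identifier] = None
    prefixes: dict = field(default_factory=dict)
    imports: List[Identifier] = field(default_factory=list)
    axioms: Set[Axiom] = field(default_factory=set)
    ontology_annotations: Set[AnnotationPair] = field(default_factory=set)

    def copy(self) -> "OntologyDocument":
        return OntologyDocument(
            ontology_iri=self.ontology_iri,
            version_iri=self.version_iri,
            prefixes=dict(self.prefixes),
            imports=list(self.imports),
            axioms=set(self.axioms),
            ontology_annotations=set(self.ontology_annotations),
        )

    def sorted_axioms(self) -> List[Axiom]:
        return sorted(self.axioms, key=axiom_sort_key)

    def logically_equal(self, other: "OntologyDocument") -> bool:
        return self.axioms == other.axioms


@dataclass(frozen=True)
class Signature:
    classes: FrozenSet[Identifier] = frozenset()
    object_properties: FrozenSet[Identifier] = frozenset()
    annotation_properties: FrozenSet[Identifier] = frozenset()
    individuals: FrozenSet[Identifier] = frozenset()

    def all_entities(self) -> FrozenSet[Identifier]:
        return self.classes | self.object_properties | self.annotation_properties | self.individuals

    def union(self, other: "Signature") -> "Signature":
        return Signature(
            self.classes | other.classes,
            self.object_properties | other.object_properties,
            self.annotation_properties | other.annotation_properties,
            self.individuals | other.individuals,
        )


_ROLE_FIELD = {
    "class": "classes",
    "object_property": "object_properties",
    "annotation_property": "annotation_properties",
    "individual": "individuals",
}

_BUILTIN = {vocab.OWL_THING, vocab.OWL_NOTHING}


def signature_of(doc_or_axioms) -> Signature:
    """Partition every identifier used in the axioms by role.

    Undeclared entities are typed by their usage position (class position →
    class, ``some`` property / subproperty → object property, annotation
    property position → annotation property). An identifier used in two
    incompatible roles raises :class:`RoleConflictError`.
    """
    axioms = doc_or_axioms.axioms if isinstance(doc_or_axioms, OntologyDocument) else doc_or_axioms
    roles: dict = {}

    def assign(entity: Identifier, role: str):
        if entity.iri in _BUILTIN:
            return
        seen = roles.setdefault(entity, set())
        seen.add(role)
        if len(seen) > 1:
            raise RoleConflictError(entity, seen)

    for ax in axioms:
        if isinstance(ax, Declaration):
            assign(ax.entity, ax.entity_type)
        elif isinstance(ax, (SubClassOf, EquivalentClasses, DisjointClasses)):
            for c in axiom_classes(ax):
                assign(c, "class")
            if isinstance(ax, SubClassOf):
                props = expression_properties(ax.sub) | expression_properties(ax.sup)
            elif isinstance(ax, EquivalentClasses):
                props = set()
                for m in ax.members:
                    props |= expression_properties(m)
            else:
                props = set()
            for p in props:
                assign(p, "object_property")
        elif isinstance(ax, SubPropertyOf):
            assign(ax.sub, "object_property")
            assign(ax.sup, "object_property")
        elif isinstance(ax, AnnotationAssertion):
            assign(ax.property, "annotation_property")
        for prop, _value in ax.annotations:
            assign(prop, "annotation_property")

    sets = {name: set() for name in _ROLE_FIELD.values()}
    for entity, entity_roles in roles.items():
        (role,) = entity_roles
        sets[_ROLE_FIELD[role]].add(entity)
    return Signature(**{k: frozenset(v) for k, v in sets.items()})


def axiom_set_merge(a: Set[Axiom], b: Set[Axiom]) -> Set[Axiom]:
    """Set union under logical-content + annotation equality. Axioms equal in
    logical content but differing in annotations both survive."""
    return set(a) | set(b)
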