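"""OWL document ↔ RDF graph mapping.

Follows the standard OWL-to-RDF graph patterns for the supported fragment:
existential restrictions and intersections become blank nodes, n-ary
disjointness becomes ``owl:AllDisjointClasses``, axiom annotations use the
``owl:Axiom`` reification pattern. Blank-node labels are minted in sorted
axiom order, so the emitted graph — and hence any serialization of it — is a
pure function of the document.

Reading is strict: every triple must be accounted for, and any recognized but
unsupported OWL construct (``owl:unionOf``, cardinalities, ...) raises
:class:`~owlkit.errors.UnsupportedConstructError` rather than being dropped.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Set, Tuple

from . import vocab
from .errors import ParseError, UnsupportedConstructError
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
    SubPropertyOf,
    intersection,
    with_annotations,
)
from .rdf import BNode, Graph, Object, Triple, render_term

_TYPE = Identifier(vocab.RDF_TYPE)
_SUBCLASS = Identifier(vocab.RDFS_SUBCLASSOF)
_SUBPROP = Identifier(vocab.RDFS_SUBPROPERTYOF)
_EQUIV = Identifier(vocab.OWL_EQUIVALENT_CLASS)
_DISJOINT = Identifier(vocab.OWL_DISJOINT_WITH)
_FIRST = Identifier(vocab.RDF_FIRST)
_REST = Identifier(vocab.RDF_REST)
_NIL = Identifier(vocab.RDF_NIL)

_DECL_TYPE_IRI = {
    "class": vocab.OWL_CLASS,
    "object_property": vocab.OWL_OBJECT_PROPERTY,
    "annotation_property": vocab.OWL_ANNOTATION_PROPERTY,
    "individual": vocab.OWL_NAMED_INDIVIDUAL,
}
_IRI_DECL_TYPE = {v: k for k, v in _DECL_TYPE_IRI.items()}


# ---------------------------------------------------------------------------
# document -> graph


class _Writer:
    def __init__(self, doc: OntologyDocument):
        self.doc = doc
        self.graph = Graph()
        self._n = 0

    def _bnode(self) -> BNode:
        self._n += 1
        return BNode(f"b{self._n}")

    def _ce(self, ce: ClassExpression) -> Object:
        if isinstance(ce, Named):
            return ce.cls
        node = self._bnode()
        if isinstance(ce, Some):
            self.graph.add((node, _TYPE, Identifier(vocab.OWL_RESTRICTION)))
            self.graph.add((node, Identifier(vocab.OWL_ON_PROPERTY), ce.property))
            self.graph.add((node, Identifier(vocab.OWL_SOME_VALUES_FROM), self._ce(ce.filler)))
        else:
            self.graph.add((node, _TYPE, Identifier(vocab.OWL_CLASS)))
            self.graph.add(
                (node, Identifier(vocab.OWL_INTERSECTION_OF), self._list([self._ce(op) for op in ce.sorted_operands()]))
            )
        return node

    def _list(self, items: List[Object]) -> Object:
        head: Object = _NIL
        for item in reversed(items):
            cons = self._bnode()
            self.graph.add((cons, _FIRST, item))
            self.graph.add((cons, _REST, head))
            head = cons
        return head

    def _reify(self, triple: Triple, annotations):
        node = self._bnode()
        self.graph.add((node, _TYPE, Identifier(vocab.OWL_AXIOM)))
        self.graph.add((node, Identifier(vocab.OWL_ANNOTATED_SOURCE), triple[0]))
        self.graph.add((node, Identifier(vocab.OWL_ANNOTATED_PROPERTY), triple[1]))
        self.graph.add((node, Identifier(vocab.OWL_ANNOTATED_TARGET), triple[2]))
        for prop, value in sorted(annotations, key=lambda pv: (pv[0].iri, render_term(pv[1]))):
            self.graph.add((node, prop, value))

    def _main_triple(self, ax: Axiom) -> Optional[Triple]:
        if isinstance(ax, SubClassOf):
            return (self._ce(ax.sub), _SUBCLASS, self._ce(ax.sup))
        if isinstance(ax, SubPropertyOf):
            return (ax.sub, _SUBPROP, ax.sup)
        if isinstance(ax, AnnotationAssertion):
            return (ax.subject, ax.property, ax.value)
        if isinstance(ax, Declaration):
            return (ax.entity, _TYPE, Identifier(_DECL_TYPE_IRI[ax.entity_type]))
        return None

    def write(self) -> Graph:
        doc = self.doc
        header: Optional[Object] = doc.ontology_iri
        if header is None and (doc.version_iri or doc.imports or doc.ontology_annotations):
            header = BNode("ontology")
        if header is not None:
            self.graph.add((header, _TYPE, Identifier(vocab.OWL_ONTOLOGY)))
            if doc.version_iri:
                self.graph.add((header, Identifier(vocab.OWL_VERSION_IRI), doc.version_iri))
            for imp in doc.imports:
                self.graph.add((header, Identifier(vocab.OWL_IMPORTS), imp))
            for prop, value in doc.ontology_annotations:
                self.graph.add((header, prop, value))

        for ax in self.doc.sorted_axioms():
            main = self._main_triple(ax)
            if main is not None:
                self.graph.add(main)
                if ax.annotations:
                    self._reify(main, ax.annotations)
                continue
            if isinstance(ax, EquivalentClasses):
                members = [self._ce(m) for m in ax.sorted_members()]
                pairs = list(zip(members, members[1:]))
                for a, b in pairs:
                    self.graph.add((a, _EQUIV, b))
                if ax.annotations:
                    self._reify((pairs[0][0], _EQUIV, pairs[0][1]), ax.annotations)
            elif isinstance(ax, DisjointClasses):
                members = ax.sorted_members()
                if len(members) == 2 and not ax.annotations:
                    self.graph.add((members[0], _DISJOINT, members[1]))
                else:
                    node = self._bnode()
                    self.graph.add((node, _TYPE, Identifier(vocab.OWL_ALL_DISJOINT_CLASSES)))
                    self.graph.add((node, Identifier(vocab.OWL_MEMBERS), self._list(list(members))))
                    for prop, value in sorted(ax.annotations, key=lambda pv: (pv[0].iri, render_term(pv[1]))):
                        self.graph.add((node, prop, value))
            else:
                raise TypeError(f"cannot map axiom {ax!r}")
        return self.graph


def doc_to_graph(doc: OntologyDocument) -> Graph:
    return _Writer(doc).write()


# ---------------------------------------------------------------------------
# graph -> document


_STRUCTURAL_TYPES = {
    vocab.OWL_RESTRICTION,
    vocab.OWL_AXIOM,
    vocab.OWL_ALL_DISJOINT_CLASSES,
    vocab.OWL_ONTOLOGY,
}


class _Reader:
    def __init__(self, graph: Graph, prefixes: Dict[str, str], path=None):
        self.graph = graph
        self.prefixes = dict(prefixes)
        self.path = path
        self.used: Set[Triple] = set()

    def _use(self, *triples: Triple):
        self.used.update(triples)

    def _check_unsupported(self):
        for t in self.graph:
            if t[1].iri in vocab.OWL_UNSUPPORTED:
                raise UnsupportedConstructError(vocab.OWL_UNSUPPORTED[t[1].iri], self.path)

    # -- expressions -------------------------------------------------------

    def _read_list(self, head: Object) -> List[Object]:
        items: List[Object] = []
        while head != _NIL:
            if not isinstance(head, BNode):
                raise ParseError("malformed RDF list", self.path)
            first = self.graph.object(head, _FIRST)
            rest = self.graph.object(head, _REST)
            if first is None or rest is None:
                raise ParseError("malformed RDF list", self.path)
            self._use((head, _FIRST, first), (head, _REST, rest))
            items.append(first)
            head = rest
        return items

    def _ce(self, node: Object) -> ClassExpression:
        if isinstance(node, Identifier):
            return Named(node)
        if isinstance(node, Literal) or not isinstance(node, BNode):
            raise ParseError(f"not a class expression: {render_term(node)}", self.path)
        on_prop = self.graph.object(node, Identifier(vocab.OWL_ON_PROPERTY))
        some = self.graph.object(node, Identifier(vocab.OWL_SOME_VALUES_FROM))
        inter = self.graph.object(node, Identifier(vocab.OWL_INTERSECTION_OF))
        type_triples = list(self.graph.triples(node, _TYPE))
        self._use(*type_triples)
        if on_prop is not None and some is not None:
            self._use(
                (node, Identifier(vocab.OWL_ON_PROPERTY), on_prop),
                (node, Identifier(vocab.OWL_SOME_VALUES_FROM), some),
            )
            if not isinstance(on_prop, Identifier):
                raise ParseError("owl:onProperty must name a property", self.path)
            return Some(on_prop, self._ce(some))
        if inter is not None:
            self._use((node, Identifier(vocab.OWL_INTERSECTION_OF), inter))
            return intersection([self._ce(item) for item in self._read_list(inter)])
        raise UnsupportedConstructError(
            f"anonymous class expression {render_term(node)} (only someValuesFrom/intersectionOf supported)",
            self.path,
        )

    # -- axioms ------------------------------------------------------------

    def _triple_axiom(self, s, p, o) -> Axiom:
        """Map one asserted (or reified) axiom triple to an axiom object."""
        if p == _SUBCLASS:
            return SubClassOf(self._ce(s), self._ce(o))
        if p == _EQUIV:
            return EquivalentClasses(frozenset({self._ce(s), self._ce(o)}))
        if p == _DISJOINT:
            if not isinstance(s, Identifier) or not isinstance(o, Identifier):
                raise UnsupportedConstructError("disjointness between anonymous classes", self.path)
            return DisjointClasses(frozenset({s, o}))
        if p == _SUBPROP:
            if not isinstance(s, Identifier) or not isinstance(o, Identifier):
                raise ParseError("subPropertyOf requires named properties", self.path)
            return SubPropertyOf(s, o)
        if p == _TYPE and isinstance(o, Identifier) and o.iri in _IRI_DECL_TYPE:
            if not isinstance(s, Identifier):
                raise ParseError("declarations require an IRI subject", self.path)
            return Declaration(s, _IRI_DECL_TYPE[o.iri])
        if isinstance(s, Identifier) and p != _TYPE:
            if isinstance(o, BNode):
                raise UnsupportedConstructError(
                    f"blank-node annotation value on {s}", self.path
                )
            return AnnotationAssertion(s, p, o)
        raise UnsupportedConstructError(
            f"triple {render_term(s)} {render_term(p)} {render_term(o)}", self.path
        )

    def read(self) -> OntologyDocument:
        self._check_unsupported()
        g = self.graph
        doc = OntologyDocument(prefixes=dict(self.prefixes))

        # ontology header
        onts = sorted(g.subjects(_TYPE, Identifier(vocab.OWL_ONTOLOGY)), key=str)
        if onts:
            header = onts[0]
            if isinstance(header, Identifier):
                doc.ontology_iri = header
            for s, p, o in list(g.triples(header)):
                self._use((s, p, o))
                if p == _TYPE:
                    continue
                if p.iri == vocab.OWL_VERSION_IRI and isinstance(o, Identifier):
                    doc.version_iri = o
                elif p.iri == vocab.OWL_IMPORTS and isinstance(o, Identifier):
                    doc.imports.append(o)
                else:
                    if isinstance(o, BNode):
                        raise UnsupportedConstructError("blank-node ontology annotation", self.path)
                    doc.ontology_annotations.add((p, o))
            doc.imports.sort()

        # axiom reification blocks, grouped by base triple
        reified: Dict[Triple, List[frozenset]] = {}
        for node in sorted(g.subjects(_TYPE, Identifier(vocab.OWL_AXIOM)), key=str):
            src = g.object(node, Identifier(vocab.OWL_ANNOTATED_SOURCE))
            prop = g.object(node, Identifier(vocab.OWL_ANNOTATED_PROPERTY))
            tgt = g.object(node, Identifier(vocab.OWL_ANNOTATED_TARGET))
            if src is None or prop is None or tgt is None or not isinstance(prop, Identifier):
                raise ParseError("incomplete owl:Axiom block", self.path)
            anns = []
            for s, p, o in list(g.triples(node)):
                self._use((s, p, o))
                if p == _TYPE or p.iri in (
                    vocab.OWL_ANNOTATED_SOURCE,
                    vocab.OWL_ANNOTATED_PROPERTY,
                    vocab.OWL_ANNOTATED_TARGET,
                ):
                    continue
                if isinstance(o, BNode):
                    raise UnsupportedConstructError("blank-node axiom annotation", self.path)
                anns.append((p, o))
            reified.setdefault((src, prop, tgt), []).append(frozenset(anns))

        # n-ary disjointness
        for node in sorted(g.subjects(_TYPE, Identifier(vocab.OWL_ALL_DISJOINT_CLASSES)), key=str):
            anns = []
            members: List[Identifier] = []
            for s, p, o in list(g.triples(node)):
                self._use((s, p, o))
                if p == _TYPE:
                    continue
                if p.iri == vocab.OWL_MEMBERS:
                    for item in self._read_list(o):
                        if not isinstance(item, Identifier):
                            raise UnsupportedConstructError("anonymous disjoint member", self.path)
                        members.append(item)
                elif isinstance(o, BNode):
                    raise UnsupportedConstructError("blank-node axiom annotation", self.path)
                else:
                    anns.append((p, o))
            doc.axioms.add(DisjointClasses(frozenset(members), frozenset(anns)))

        # main pass over asserted triples; triples inside expression blank
        # nodes are consumed lazily by _ce, so they are skipped here and the
        # final leftover check catches genuine orphans
        skip_types = {Identifier(t) for t in _STRUCTURAL_TYPES}

        def emit(s, p, o):
            ax = self._triple_axiom(s, p, o)
            self._use((s, p, o))
            blocks = reified.get((s, p, o))
            if blocks:
                for anns in blocks:
                    doc.axioms.add(with_annotations(ax, anns))
            else:
                doc.axioms.add(ax)

        for s, p, o in g.sorted_triples():
            if (s, p, o) in self.used:
                continue
            if p == _TYPE and o in skip_types:
                self._use((s, p, o))
                continue
            if p == _TYPE and isinstance(o, Identifier) and o.iri == vocab.OWL_THING:
                self._use((s, p, o))
                continue
            if isinstance(s, BNode):
                if p in (_SUBCLASS, _EQUIV):
                    emit(s, p, o)
                continue
            emit(s, p, o)

        # any triple not consumed by now is an unsupported leftover
        for t in g.sorted_triples():
            if t not in self.used:
                raise UnsupportedConstructError(
                    f"triple {render_term(t[0])} {render_term(t[1])} {render_term(t[2])}",
                    self.path,
                )
        return doc


def graph_to_doc(graph: Graph, prefixes: Dict[str, str], path=None) -> OntologyDocument:
    return _Reader(graph, prefixes, path).read()
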