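"""Saturation-based classification for the supported EL fragment.

The classifier normalizes all logical axioms into the four standard EL normal
forms (A ⊑ B, A1 ⊓ A2 ⊑ B, A ⊑ ∃R.B, ∃R.B ⊑ A), introducing deterministic
auxiliary names for complex subexpressions, then applies the usual completion
rules to a fixpoint. Disjointness compiles to ``B ⊓ C ⊑ ⊥``. The procedure is
sound and complete for subsumption between named classes in the fragment
(conjunction + existential restriction); property hierarchies deliberately do
not participate in existential subsumption.

Because there is no ABox, an ontology is always *consistent*; it is
*incoherent* when some named class is unsatisfiable (subsumed by ``owl:Nothing``).
"""

from __future__ import annotations

import hashlib
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Optional, Set, Tuple

from . import vocab
from .errors import EquivalentPairError, IncoherentOntologyError, OwlkitError
from .model import (
    And,
    Axiom,
    ClassExpression,
    Declaration,
    DisjointClasses,
    EquivalentClasses,
    Identifier,
    Named,
    OntologyDocument,
    Some,
    SubClassOf,
    axiom_classes,
    render_expression,
    signature_of,
)

TOP = vocab.OWL_THING
BOT = vocab.OWL_NOTHING

_AUX_NS = "urn:x-owlkit-aux:"


def _aux_name(ce: ClassExpression) -> str:
    digest = hashlib.sha1(render_expression(ce).encode("utf-8")).hexdigest()[:16]
    return _AUX_NS + digest


def is_aux(iri: str) -> bool:
    return iri.startswith(_AUX_NS)


class Saturation:
    """One saturation run over a set of axioms.

    ``extra_expressions`` are additional class expressions to name (with full
    definitional equivalence), so entailment queries about complex expressions
    can be answered on the same structure.
    """

    def __init__(self, axioms: Iterable[Axiom], extra_expressions: Iterable[ClassExpression] = ()):
        # normal forms
        self.subs: Dict[str, List[str]] = defaultdict(list)            # A -> [B]      (A ⊑ B)
        self.conjs: Dict[str, List[Tuple[str, str]]] = defaultdict(list)  # A1 -> [(A2, B)] (A1 ⊓ A2 ⊑ B)
        self.ex_rhs: Dict[str, List[Tuple[str, str]]] = defaultdict(list)  # A -> [(R, B)] (A ⊑ ∃R.B)
        self.ex_lhs: Dict[Tuple[str, str], List[str]] = defaultdict(list)  # (R, A) -> [B] (∃R.A ⊑ B)
        self._defined: Set[str] = set()
        self.concepts: Set[str] = {TOP, BOT}

        for ax in axioms:
            if isinstance(ax, SubClassOf):
                self._add_gci(ax.sub, ax.sup)
            elif isinstance(ax, EquivalentClasses):
                members = ax.sorted_members()
                for i, a in enumerate(members):
                    for b in members[i + 1:]:
                        self._add_gci(a, b)
                        self._add_gci(b, a)
            elif isinstance(ax, DisjointClasses):
                members = ax.sorted_members()
                for i, a in enumerate(members):
                    for b in members[i + 1:]:
                        self._nf_conj(a.iri, b.iri, BOT)
        for ce in extra_expressions:
            self._name(ce)

        self._saturate()

    # -- normalization ----------------------------------------------------

    def _name(self, ce: ClassExpression) -> str:
        """Return a concept name for ce, introducing a definitional auxiliary
        name (both inclusion directions) for complex expressions."""
        if isinstance(ce, Named):
            self.concepts.add(ce.cls.iri)
            return ce.cls.iri
        aux = _aux_name(ce)
        if aux in self._defined:
            return aux
        self._defined.add(aux)
        self.concepts.add(aux)
        if isinstance(ce, Some):
            filler = self._name(ce.filler)
            r = ce.property.iri
            self.ex_rhs[aux].append((r, filler))          # aux ⊑ ∃R.filler
            self.ex_lhs[(r, filler)].append(aux)          # ∃R.filler ⊑ aux
        elif isinstance(ce, And):
            names = [self._name(op) for op in ce.sorted_operands()]
            for n in names:                                # aux ⊑ n_i
                self.subs[aux].append(n)
            acc = names[0]
            for n in names[1:-1]:
                nxt = _aux_name(intersection_pair_tag(acc, n))
                self.concepts.add(nxt)
                self._nf_conj(acc, n, nxt)
                acc = nxt
            self._nf_conj(acc, names[-1], aux)             # n_1 ⊓ … ⊓ n_k ⊑ aux
        else:
            raise TypeError(f"not a class expression: {ce!r}")
        return aux

    def _nf_conj(self, a1: str, a2: str, b: str):
        self.concepts.update((a1, a2, b))
        self.conjs[a1].append((a2, b))
        if a2 != a1:
            self.conjs[a2].append((a1, b))

    def _add_gci(self, lhs: ClassExpression, rhs: ClassExpression):
        self.subs[self._name(lhs)].append(self._name(rhs))

    # -- completion --------------------------------------------------------

    def _saturate(self):
        S: Dict[str, Set[str]] = {c: {c, TOP} for c in self.concepts}
        edges: Dict[str, Set[Tuple[str, str]]] = defaultdict(set)      # R -> {(X, Y)}
        edges_by_target: Dict[str, Set[Tuple[str, str]]] = defaultdict(set)  # Y -> {(R, X)}
        queue: List[Tuple[str, str]] = [(x, a) for x in self.concepts for a in S[x]]

        def add(x: str, a: str):
            if a not in S[x]:
                S[x].add(a)
                queue.append((x, a))

        def add_edge(r: str, x: str, y: str):
            if (x, y) in edges[r]:
                return
            edges[r].add((x, y))
            edges_by_target[y].add((r, x))
            # CR4 against everything already in S(y)
            for a in list(S[y]):
                for b in self.ex_lhs.get((r, a), ()):
                    add(x, b)
            if BOT in S[y]:
                add(x, BOT)

        while queue:
            x, a = queue.pop()
            # CR1
            for b in self.subs.get(a, ()):
                add(x, b)
            # CR2
            for a2, b in self.conjs.get(a, ()):
                if a2 in S[x]:
                    add(x, b)
            # CR3
            for r, b in self.ex_rhs.get(a, ()):
                self.concepts.add(b)
                if b not in S:
                    S[b] = {b, TOP}
                    queue.extend((b, c) for c in S[b])
                add_edge(r, x, b)
            # CR4 triggered by new member of S(x): x may be an edge target
            for r, w in edges_by_target.get(x, ()):
                for b in self.ex_lhs.get((r, a), ()):
                    add(w, b)
                if a == BOT:
                    add(w, BOT)

        self.S = S
        self.edges = edges

    # -- queries -----------------------------------------------------------

    def subsumed(self, sub: str, sup: str) -> bool:
        s = self.S.get(sub)
        if s is None:
            return sup == TOP or sup == sub
        return sup in s or BOT in s

    def unsatisfiable(self) -> Set[str]:
        return {c for c, s in self.S.items() if BOT in s and c != BOT}

    def existential_fillers(self, x: str, r: str) -> Set[str]:
        """Named concepts B with  x ⊑ ∃R.B  entailed (via the canonical model:
        some successor y of x along R has B in S(y))."""
        out: Set[str] = set()
        for (src, y) in self.edges.get(r, ()):
            if src == x:
                out.update(self.S[y])
        return out


# ---------------------------------------------------------------------------
# Public API


@dataclass(frozen=True)
class ReasonOptions:
    assert_direct_superclasses: bool = True
    fail_on_equivalent_pairs: bool = False


@dataclass
class Taxonomy:
    """Classification result: equivalence groups of named classes with direct
    (transitively reduced) subclass links between group representatives."""

    nodes: Dict[Identifier, FrozenSet[Identifier]] = field(default_factory=dict)
    direct_edges: Set[Tuple[Identifier, Identifier]] = field(default_factory=set)
    unsatisfiable: FrozenSet[Identifier] = frozenset()
    consistent: bool = True

    def node_of(self, cls: Identifier) -> Optional[Identifier]:
        for rep, members in self.nodes.items():
            if cls in members:
                return rep
        return None

    def equivalent_pairs(self) -> List[Tuple[Identifier, Identifier]]:
        pairs = []
        for members in self.nodes.values():
            ms = sorted(members)
            for i, a in enumerate(ms):
                for b in ms[i + 1:]:
                    pairs.append((a, b))
        return pairs


def _named_classes(doc: OntologyDocument) -> Set[Identifier]:
    named = set(signature_of(doc).classes)
    for ax in doc.axioms:
        named |= axiom_classes(ax)
    named.discard(Identifier(TOP))
    named.discard(Identifier(BOT))
    return named


def classify(doc: OntologyDocument) -> Taxonomy:
    """Compute the complete named-class subsumption hierarchy.

    Unsatisfiability is reported in the result, never raised.
    """
    named = sorted(_named_classes(doc))
    sat = Saturation(doc.axioms)

    unsat = {c for c in named if sat.subsumed(c.iri, BOT)}
    satisfiable = [c for c in named if c not in unsat]

    supers: Dict[Identifier, Set[Identifier]] = {}
    for c in satisfiable:
        supers[c] = {
            d for d in satisfiable
            if d != c and d.iri in sat.S.get(c.iri, ())
        }

    # equivalence groups
    rep_of: Dict[Identifier, Identifier] = {}
    nodes: Dict[Identifier, Set[Identifier]] = {}
    for c in satisfiable:
        if c in rep_of:
            continue
        group = {c} | {d for d in supers[c] if c in supers[d]}
        rep = min(group)
        nodes[rep] = group
        for m in group:
            rep_of[m] = rep

    # strict supers between representatives, then transitive reduction
    strict: Dict[Identifier, Set[Identifier]] = {rep: set() for rep in nodes}
    for rep, group in nodes.items():
        strict[rep] = {rep_of[d] for d in supers[rep] if rep_of[d] != rep}
    direct: Set[Tuple[Identifier, Identifier]] = set()
    for rep, ups in strict.items():
        for u in ups:
            if not any(u in strict[v] for v in ups if v != u):
                direct.add((rep, u))

    taxonomy_nodes: Dict[Identifier, FrozenSet[Identifier]] = {
        rep: frozenset(group) for rep, group in nodes.items()
    }
    if unsat:
        # all unsatisfiable classes are mutually equivalent (to owl:Nothing)
        rep = min(unsat)
        taxonomy_nodes[rep] = frozenset(unsat)

    return Taxonomy(
        nodes=taxonomy_nodes,
        direct_edges=direct,
        unsatisfiable=frozenset(unsat),
        consistent=True,
    )


def reason(doc: OntologyDocument, opts: ReasonOptions = ReasonOptions()) -> OntologyDocument:
    """Validate then classify: halt on incoherence, otherwise return the
    document plus one asserted ``SubClassOf(named, named)`` axiom per direct
    inferred edge not already asserted. ``owl:Thing`` superclasses are never
    asserted."""
    taxonomy = classify(doc)
    if taxonomy.unsatisfiable:
        raise IncoherentOntologyError(taxonomy.unsatisfiable)
    if opts.fail_on_equivalent_pairs:
        pairs = taxonomy.equivalent_pairs()
        if pairs:
            raise EquivalentPairError(pairs)
    out = doc.copy()
    if not opts.assert_direct_superclasses:
        return out
    for sub_rep, sup_rep in taxonomy.direct_edges:
        if sup_rep.iri == TOP:
            continue
        for a in taxonomy.nodes[sub_rep]:
            for b in taxonomy.nodes[sup_rep]:
                ax = SubClassOf(Named(a), Named(b))
                if ax not in out.axioms:
                    out.axioms.add(ax)
    return out


def is_entailed(doc_or_axioms, axiom: Axiom) -> bool:
    """True iff a subclass axiom within the fragment follows from the document.

    Implemented by saturating the axioms with both sides of the query named by
    fresh definitional auxiliaries (a conservative extension)."""
    if not isinstance(axiom, SubClassOf):
        raise OwlkitError(f"entailment queries support sub_class_of only, got {type(axiom).__name__}")
    axioms = doc_or_axioms.axioms if isinstance(doc_or_axioms, OntologyDocument) else doc_or_axioms
    sat = Saturation(axioms, extra_expressions=[axiom.sub, axiom.sup])
    sub = axiom.sub.cls.iri if isinstance(axiom.sub, Named) else _aux_name(axiom.sub)
    sup = axiom.sup.cls.iri if isinstance(axiom.sup, Named) else _aux_name(axiom.sup)
    return sat.subsumed(sub, sup)


def intersection_pair_tag(a: str, b: str):
    """A deterministic pseudo-expression used only to mint stable auxiliary
    names for the intermediate conjunctions of >2-ary intersections."""
    lo, hi = sorted((a, b))
    return Named(Identifier(f"{_AUX_NS}pair({lo},{hi})"))
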