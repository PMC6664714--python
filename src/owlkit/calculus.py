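"""Axiom-level transformations surrounding `reason` in a release pipeline:
relax, reduce, and materialize.

* relax: make equivalence definitions navigable without a reasoner by
  asserting each top-level conjunct of every definition as a subclass axiom.
* reduce: delete subclass axioms between named classes that stay entailed
  after their own removal (redundancy elimination).
* materialize: assert entailed most-specific existential superclasses
  ``A ⊑ R some B`` for selected properties.
"""

from __future__ import annotations

from typing import Iterable, Optional, Set

from .errors import IncoherentOntologyError
from .model import (
    And,
    EquivalentClasses,
    Identifier,
    Named,
    OntologyDocument,
    Some,
    SubClassOf,
    signature_of,
)
from .reasoner import BOT, Saturation, classify, is_aux, is_entailed


def relax(doc: OntologyDocument) -> OntologyDocument:
    """For every equivalence axiom with a named member A, assert
    ``A ⊑ C_i`` for each top-level conjunct C_i of every other member
    (the whole member when it is not an intersection). Input axioms are
    untouched; nested intersections inside fillers are not recursed into."""
    out = doc.copy()
    for ax in doc.axioms:
        if not isinstance(ax, EquivalentClasses):
            continue
        for named in ax.members:
            if not isinstance(named, Named):
                continue
            for other in ax.members:
                if other is named:
                    continue
                conjuncts = other.sorted_operands() if isinstance(other, And) else [other]
                for c in conjuncts:
                    out.axioms.add(SubClassOf(named, c))
    return out


def reduce(doc: OntologyDocument) -> OntologyDocument:
    """Remove redundant named-named subclass axioms.

    An asserted ``A ⊑ B`` (A, B named) is redundant when the *remaining*
    asserted named-subclass edges still connect A to B (a transitive chain,
    or another copy of the same edge differing only in annotations).
    Redundancy is deliberately judged against the asserted hierarchy, not
    full entailment: an ``A ⊑ B`` whose only support is A's equivalence
    definition is exactly what ``relax`` asserts for navigability and must
    survive. Candidates are processed greedily in lexicographic (sub IRI,
    sup IRI) order with re-checking, so interacting redundancies resolve
    deterministically. Annotation and equivalence axioms are never removed."""
    out = doc.copy()
    candidates = sorted(
        (
            ax
            for ax in doc.axioms
            if isinstance(ax, SubClassOf)
            and isinstance(ax.sub, Named)
            and isinstance(ax.sup, Named)
        ),
        key=lambda ax: (ax.sub.cls.iri, ax.sup.cls.iri, len(ax.annotations)),
    )

    def reachable(start: Identifier, goal: Identifier, axioms) -> bool:
        adjacency: dict = {}
        for other in axioms:
            if (
                isinstance(other, SubClassOf)
                and isinstance(other.sub, Named)
                and isinstance(other.sup, Named)
            ):
                adjacency.setdefault(other.sub.cls, set()).add(other.sup.cls)
        seen = {start}
        stack = [start]
        while stack:
            node = stack.pop()
            for nxt in adjacency.get(node, ()):
                if nxt == goal:
                    return True
                if nxt not in seen:
                    seen.add(nxt)
                    stack.append(nxt)
        return False

    for ax in candidates:
        rest = set(out.axioms)
        rest.discard(ax)
        if ax.sub == ax.sup or reachable(ax.sub.cls, ax.sup.cls, rest):
            out.axioms = rest  # self-references are tautologies; drop outright
    return out


def materialize(doc: OntologyDocument, properties: Optional[Iterable[Identifier]] = None) -> OntologyDocument:
    """Assert ``A ⊑ R some B`` for every named class A, selected property R,
    and every *most-specific* named filler B such that the axiom is entailed
    and not already asserted.

    ``properties=None`` selects every object property in the signature.
    Incoherent input raises, matching the `reason` contract."""
    taxonomy = classify(doc)
    if taxonomy.unsatisfiable:
        raise IncoherentOntologyError(taxonomy.unsatisfiable)

    sig = signature_of(doc)
    if properties is None:
        props = sorted(sig.object_properties)
    else:
        props = sorted(set(properties))
    named = sorted(c for c in sig.classes if not is_aux(c.iri))

    sat = Saturation(doc.axioms)
    out = doc.copy()
    for a in named:
        for r in props:
            fillers: Set[Identifier] = {
                Identifier(f)
                for f in sat.existential_fillers(a.iri, r.iri)
                if not is_aux(f) and f != BOT and Identifier(f) in sig.classes
            }
            if not fillers:
                continue
            # keep most-specific fillers; among equivalents keep the least IRI
            keep = []
            for b in sorted(fillers):
                strictly_below = any(
                    sat.subsumed(b2.iri, b.iri) and not sat.subsumed(b.iri, b2.iri)
                    for b2 in fillers
                    if b2 != b
                )
                if strictly_below:
                    continue
                equivalent_smaller = any(
                    b2 < b and sat.subsumed(b2.iri, b.iri) and sat.subsumed(b.iri, b2.iri)
                    for b2 in fillers
                    if b2 != b
                )
                if not equivalent_smaller:
                    keep.append(b)
            for b in keep:
                ax = SubClassOf(Named(a), Some(r, Named(b)))
                if ax not in out.axioms:
                    out.axioms.add(ax)
    return out
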