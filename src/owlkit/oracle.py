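"""Naive, independent entailment oracle.

This module exists so the saturation reasoner can be checked against a second
implementation that shares none of its machinery. It computes an exhaustive
subsumption closure directly over the *expression* level (the subexpression
closure of the ontology), applying obviously-correct structural rules to a
fixpoint:

  reflexivity; transitivity; asserted inclusions; intersection decomposition
  and composition; monotonicity of existential restriction in the filler;
  bottom propagation through existentials; disjointness as a clash rule.

It is cubic in the number of subexpressions and intended for ontologies of a
dozen classes, where it is feasible to enumerate everything. A plain
graph-reachability oracle over asserted named subclass edges is included for
checking extraction and selector logic; it uses networkx rather than the
toolkit's own traversals.
"""

from __future__ import annotations

from typing import Dict, Iterable, List, Set, Tuple

import networkx as nx

from . import vocab
from .model import (
    And,
    Axiom,
    ClassExpression,
    DisjointClasses,
    EquivalentClasses,
    Identifier,
    Named,
    OntologyDocument,
    Some,
    SubClassOf,
    render_expression,
    subexpressions,
)

TOP = Named(Identifier(vocab.OWL_THING))
BOT = Named(Identifier(vocab.OWL_NOTHING))


class ClosureOracle:
    """Exhaustive subsumption closure over the subexpression universe."""

    def __init__(self, doc_or_axioms, extra: Iterable[ClassExpression] = ()):
        axioms = doc_or_axioms.axioms if isinstance(doc_or_axioms, OntologyDocument) else doc_or_axioms
        exprs: Set[ClassExpression] = {TOP, BOT}
        asserted: List[Tuple[ClassExpression, ClassExpression]] = []
        disjoint: List[Tuple[Named, Named]] = []

        for ax in axioms:
            if isinstance(ax, SubClassOf):
                asserted.append((ax.sub, ax.sup))
                exprs.update(subexpressions(ax.sub))
                exprs.update(subexpressions(ax.sup))
            elif isinstance(ax, EquivalentClasses):
                ms = ax.sorted_members()
                for i, a in enumerate(ms):
                    exprs.update(subexpressions(a))
                    for b in ms[i + 1:]:
                        asserted.append((a, b))
                        asserted.append((b, a))
            elif isinstance(ax, DisjointClasses):
                ms = [Named(m) for m in ax.sorted_members()]
                exprs.update(ms)
                for i, a in enumerate(ms):
                    for b in ms[i + 1:]:
                        disjoint.append((a, b))
        for ce in extra:
            exprs.update(subexpressions(ce))

        universe = sorted(exprs, key=render_expression)
        self.universe = universe
        sub: Set[Tuple[ClassExpression, ClassExpression]] = set()
        for e in universe:
            sub.add((e, e))
            sub.add((e, TOP))
            sub.add((BOT, e))
        sub.update((a, b) for a, b in asserted)
        for e in universe:
            if isinstance(e, And):
                for op in e.operands:
                    sub.add((e, op))

        somes: Dict[Identifier, List[Some]] = {}
        for e in universe:
            if isinstance(e, Some):
                somes.setdefault(e.property, []).append(e)
        ands = [e for e in universe if isinstance(e, And)]

        changed = True
        while changed:
            changed = False
            # transitivity
            for (a, b) in list(sub):
                for c in universe:
                    if (b, c) in sub and (a, c) not in sub:
                        sub.add((a, c))
                        changed = True
            # intersection composition
            for e in ands:
                for x in universe:
                    if (x, e) not in sub and all((x, op) in sub for op in e.operands):
                        sub.add((x, e))
                        changed = True
            # existential monotonicity and bottom propagation
            for group in somes.values():
                for e1 in group:
                    for e2 in group:
                        if e1 is not e2 and (e1.filler, e2.filler) in sub and (e1, e2) not in sub:
                            sub.add((e1, e2))
                            changed = True
                    if (e1.filler, BOT) in sub and (e1, BOT) not in sub:
                        sub.add((e1, BOT))
                        changed = True
            # disjointness clash
            for (a, b) in disjoint:
                for x in universe:
                    if (x, a) in sub and (x, b) in sub and (x, BOT) not in sub:
                        sub.add((x, BOT))
                        changed = True

        self._sub = sub

    def entails(self, sub: ClassExpression, sup: ClassExpression) -> bool:
        if (sub, BOT) in self._sub:
            return True
        return (sub, sup) in self._sub

    def unsatisfiable(self) -> Set[Identifier]:
        return {
            e.cls
            for e in self.universe
            if isinstance(e, Named) and e != BOT and (e, BOT) in self._sub
        }

    def named_subsumptions(self) -> Set[Tuple[Identifier, Identifier]]:
        """All entailed (sub, sup) pairs between distinct named classes,
        owl:Thing/Nothing excluded."""
        named = [e for e in self.universe if isinstance(e, Named) and e not in (TOP, BOT)]
        out = set()
        for a in named:
            for b in named:
                if a != b and self.entails(a, b):
                    out.add((a.cls, b.cls))
        return out


def asserted_subclass_graph(doc_or_axioms) -> nx.DiGraph:
    """Directed graph of asserted named-named subclass edges (sub → sup)."""
    axioms = doc_or_axioms.axioms if isinstance(doc_or_axioms, OntologyDocument) else doc_or_axioms
    g = nx.DiGraph()
    for ax in axioms:
        if isinstance(ax, SubClassOf) and isinstance(ax.sub, Named) and isinstance(ax.sup, Named):
            g.add_edge(ax.sub.cls, ax.sup.cls)
    return g


def reachable_ancestors(doc_or_axioms, seeds: Iterable[Identifier], stop_at: Iterable[Identifier] = ()) -> Set[Identifier]:
    """Seeds plus every ancestor along asserted is_a edges, halting at (but
    including) any stop term. Independent reachability oracle for MIREOT."""
    g = asserted_subclass_graph(doc_or_axioms)
    stop = set(stop_at)
    out: Set[Identifier] = set()
    stack = list(seeds)
    while stack:
        node = stack.pop()
        if node in out:
            continue
        out.add(node)
        if node in stop:
            continue
        if g.has_node(node):
            stack.extend(g.successors(node))
    return out
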