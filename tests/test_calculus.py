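"""relax / reduce / materialize transformations."""

import pytest

from owlkit.calculus import materialize, reduce, relax
from owlkit.errors import IncoherentOntologyError
from owlkit.fixtures import FixtureSpec, generate
from owlkit.model import (
    AnnotationAssertion,
    DisjointClasses,
    EquivalentClasses,
    Identifier,
    Literal,
    Named,
    Some,
    SubClassOf,
    intersection,
)
from owlkit.oracle import ClosureOracle
from owlkit.reasoner import is_entailed
from util import N, doc_of, iri, sub


class TestRelax:
    def test_definition_conjuncts_become_subclass_axioms(self):
        d = doc_of(
            EquivalentClasses(frozenset({N("A"), intersection([N("B"), Some(iri("R"), N("C"))])})),
        )
        out = relax(d)
        assert sub("A", "B") in out.axioms
        assert SubClassOf(N("A"), Some(iri("R"), N("C"))) in out.axioms
        assert d.axioms <= out.axioms

    def test_no_equivalences_means_no_change(self):
        d = doc_of(sub("A", "B"))
        assert relax(d).axioms == d.axioms

    def test_named_equivalence_relaxes_both_ways(self):
        d = doc_of(EquivalentClasses(frozenset({N("A"), N("B")})))
        out = relax(d)
        assert sub("A", "B") in out.axioms and sub("B", "A") in out.axioms

    def test_relax_is_conservative(self):
        """Every axiom relax adds is already entailed by the input."""
        for seed in (3, 8, 13):
            doc, _ = generate(FixtureSpec(n_classes=10, p_existential=0.7, seed=seed))
            out = relax(doc)
            for ax in out.axioms - doc.axioms:
                assert is_entailed(doc, ax)
                oracle = ClosureOracle(doc, extra=[ax.sub, ax.sup])
                assert oracle.entails(ax.sub, ax.sup)


class TestReduce:
    def test_transitive_redundancy_removed(self):
        out = reduce(doc_of(sub("A", "B"), sub("B", "C"), sub("A", "C")))
        assert sub("A", "C") not in out.axioms
        assert {sub("A", "B"), sub("B", "C")} <= out.axioms

    def test_nothing_redundant_means_unchanged(self):
        d = doc_of(sub("A", "B"))
        assert reduce(d).axioms == d.axioms

    def test_relax_then_reduce_deduplicates(self):
        d = doc_of(
            EquivalentClasses(frozenset({N("A"), intersection([N("B"), Some(iri("R"), N("C"))])})),
            sub("A", "B"),
        )
        out = reduce(relax(d))
        survivors = [ax for ax in out.axioms if ax == sub("A", "B")]
        assert len(survivors) == 1

    def test_annotations_and_equivalences_never_removed(self):
        ann = AnnotationAssertion(iri("A"), iri("p"), Literal("v"))
        eq = EquivalentClasses(frozenset({N("A"), N("B")}))
        out = reduce(doc_of(ann, eq, sub("A", "B")))
        assert ann in out.axioms and eq in out.axioms
        # A ⊑ B is supported only by the equivalence (as after relax); kept
        assert sub("A", "B") in out.axioms

    def test_self_reference_removed(self):
        out = reduce(doc_of(sub("A", "A"), sub("A", "B")))
        assert out.axioms == {sub("A", "B")}

    def test_annotated_duplicates_collapse_to_one_edge(self):
        a = SubClassOf(N("A"), N("B"), frozenset({(iri("p"), Literal("v"))}))
        b = SubClassOf(N("A"), N("B"), frozenset({(iri("p"), Literal("w"))}))
        out = reduce(doc_of(a, b))
        edges = [ax for ax in out.axioms if isinstance(ax, SubClassOf)]
        assert len(edges) == 1

    def test_reduce_preserves_entailments_and_is_idempotent(self):
        for seed in (2, 7):
            doc, _ = generate(FixtureSpec(n_classes=10, p_existential=0.6, seed=seed))
            out = reduce(relax(doc))
            before = ClosureOracle(doc).named_subsumptions()
            after = ClosureOracle(out).named_subsumptions()
            assert before == after
            assert reduce(out).axioms == out.axioms
            # no removable axiom remains: every surviving named-named edge
            # lacks an alternative asserted path
            edges = {
                (ax.sub.cls, ax.sup.cls)
                for ax in out.axioms
                if isinstance(ax, SubClassOf) and isinstance(ax.sub, Named) and isinstance(ax.sup, Named)
            }
            import networkx as nx

            g = nx.DiGraph(list(edges))
            for a, b in edges:
                g.remove_edge(a, b)
                assert not (g.has_node(a) and g.has_node(b) and nx.has_path(g, a, b)), (a, b)
                g.add_edge(a, b)


class TestMaterialize:
    def test_inherited_existential_asserted(self):
        d = doc_of(sub("A", "B"), SubClassOf(N("B"), Some(iri("R"), N("C"))))
        out = materialize(d)
        assert SubClassOf(N("A"), Some(iri("R"), N("C"))) in out.axioms

    def test_most_specific_filler_only(self):
        d = doc_of(SubClassOf(N("A"), Some(iri("R"), N("C"))), sub("C", "D"))
        out = materialize(d)
        # the D filler is suppressed as non-most-specific; C already asserted
        assert out.axioms == d.axioms

    def test_empty_document_unchanged(self):
        d = doc_of()
        assert materialize(d).axioms == set()

    def test_materialized_axioms_are_entailed(self):
        doc, _ = generate(FixtureSpec(n_classes=10, p_existential=0.7, seed=31))
        out = materialize(doc)
        for ax in out.axioms - doc.axioms:
            assert is_entailed(doc, ax)

    def test_incoherent_input_rejected(self):
        d = doc_of(sub("A", "B"), sub("A", "C"), DisjointClasses(frozenset({iri("B"), iri("C")})))
        with pytest.raises(IncoherentOntologyError):
            materialize(d)

    def test_property_selection(self):
        d = doc_of(
            sub("A", "B"),
            SubClassOf(N("B"), Some(iri("R"), N("C"))),
            SubClassOf(N("B"), Some(iri("S"), N("C"))),
        )
        out = materialize(d, properties={iri("S")})
        assert SubClassOf(N("A"), Some(iri("S"), N("C"))) in out.axioms
        assert SubClassOf(N("A"), Some(iri("R"), N("C"))) not in out.axioms
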