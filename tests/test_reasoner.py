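"""EL saturation classifier: examples, soundness, and oracle equivalence."""

import random

import pytest

from owlkit.errors import EquivalentPairError, IncoherentOntologyError, OwlkitError
from owlkit.fixtures import FixtureSpec, generate
from owlkit.model import (
    DisjointClasses,
    EquivalentClasses,
    Named,
    Some,
    SubClassOf,
    intersection,
)
from owlkit.oracle import ClosureOracle
from owlkit.reasoner import ReasonOptions, classify, is_entailed, reason
from util import N, doc_of, iri, sub


class TestClassify:
    def test_direct_edges_are_transitively_reduced(self):
        t = classify(doc_of(sub("A", "B"), sub("B", "C")))
        edges = {(a.iri, b.iri) for a, b in t.direct_edges}
        assert edges == {(iri("A").iri, iri("B").iri), (iri("B").iri, iri("C").iri)}

    def test_definition_subsumption_is_inferred(self):
        # A ≡ B ⊓ ∃R.C together with D ⊑ B, D ⊑ ∃R.C entails D ⊑ A
        d = doc_of(
            EquivalentClasses(frozenset({N("A"), intersection([N("B"), Some(iri("R"), N("C"))])})),
            sub("D", "B"),
            SubClassOf(N("D"), Some(iri("R"), N("C"))),
        )
        assert is_entailed(d, sub("D", "A"))
        oracle = ClosureOracle(d)
        assert oracle.entails(N("D"), N("A"))

    def test_disjointness_clash_is_unsatisfiable(self):
        t = classify(doc_of(sub("A", "B"), sub("A", "C"), DisjointClasses(frozenset({iri("B"), iri("C")}))))
        assert t.unsatisfiable == frozenset({iri("A")})
        assert t.consistent

    def test_every_class_in_exactly_one_node(self):
        doc, _ = generate(FixtureSpec(n_classes=10, p_existential=0.6, seed=9))
        t = classify(doc)
        counts = {}
        for members in t.nodes.values():
            for m in members:
                counts[m] = counts.get(m, 0) + 1
        assert set(counts.values()) == {1}


class TestReason:
    def test_idempotent_on_classified_input(self):
        d = doc_of(sub("A", "B"), sub("B", "C"))
        once = reason(d)
        assert reason(once).axioms == once.axioms

    def test_anonymous_equivalence_drives_assertion(self):
        d = doc_of(
            EquivalentClasses(frozenset({N("A"), Some(iri("R"), N("B"))})),
            SubClassOf(N("C"), Some(iri("R"), N("B"))),
        )
        out = reason(d)
        assert sub("C", "A") in out.axioms

    def test_incoherence_halts(self):
        d = doc_of(sub("A", "B"), sub("A", "C"), DisjointClasses(frozenset({iri("B"), iri("C")})))
        with pytest.raises(IncoherentOntologyError) as excinfo:
            reason(d)
        assert iri("A") in excinfo.value.unsatisfiable

    def test_equivalent_pair_check(self):
        d = doc_of(sub("A", "B"), sub("B", "A"))
        reason(d)  # allowed by default
        with pytest.raises(EquivalentPairError):
            reason(d, ReasonOptions(fail_on_equivalent_pairs=True))

    def test_soundness_of_asserted_inferences(self):
        for seed in (1, 2, 3):
            doc, _ = generate(FixtureSpec(n_classes=10, p_existential=0.6, seed=seed))
            out = reason(doc)
            for ax in out.axioms - doc.axioms:
                assert is_entailed(doc, ax), ax

    def test_monotonicity(self):
        base, _ = generate(FixtureSpec(n_classes=8, p_existential=0.5, seed=21))
        extended = base.copy()
        extended.axioms.add(sub("Z1", "Z2"))
        before = {(a.iri, b.iri) for a, b in ClosureOracle(base).named_subsumptions()}
        sat_after = classify(extended)
        for a, b in before:
            from owlkit.model import Identifier

            assert is_entailed(extended, SubClassOf(Named(Identifier(a)), Named(Identifier(b))))


class TestIsEntailed:
    def test_reflexivity_and_transitivity(self):
        assert is_entailed(doc_of(sub("A", "B")), sub("A", "A"))
        assert is_entailed(doc_of(sub("A", "B"), sub("B", "C")), sub("A", "C"))
        assert not is_entailed(doc_of(sub("A", "B")), sub("B", "A"))

    def test_existential_filler_monotonicity(self):
        d = doc_of(SubClassOf(N("A"), Some(iri("R"), N("B"))), sub("B", "C"))
        query = SubClassOf(N("A"), Some(iri("R"), N("C")))
        assert is_entailed(d, query)
        assert ClosureOracle(d, extra=[query.sup]).entails(query.sub, query.sup)

    def test_only_subclass_queries_supported(self):
        with pytest.raises(OwlkitError):
            is_entailed(doc_of(), DisjointClasses(frozenset({iri("A"), iri("B")})))


def test_classifier_matches_oracle_on_random_ontologies():
    """Saturation classification agrees with the independent exhaustive
    closure oracle on small random ontologies (subsumption + unsat sets)."""
    rng = random.Random(77)
    for trial in range(40):
        spec = FixtureSpec(
            n_classes=rng.randint(3, 12),
            n_properties=rng.randint(1, 2),
            p_existential=0.6,
            seed=1000 + trial,
            violation_census={"unsatisfiable": 1} if trial % 5 == 0 else {},
        )
        doc, ledger = generate(spec)
        t = classify(doc)
        assert {(a.iri, b.iri) for a, b in t.direct_edges} == ledger.inferred_direct_edges
        assert {c.iri for c in t.unsatisfiable} == ledger.unsatisfiable
        got_pairs = {(min(a.iri, b.iri), max(a.iri, b.iri)) for a, b in t.equivalent_pairs()}
        assert got_pairs == ledger.equivalent_pairs
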