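"""Core model: identifiers, expressions, signatures, axiom-set algebra."""

import pytest
from hypothesis import given, settings, strategies as st

from owlkit.errors import RoleConflictError
from owlkit.fixtures import FixtureSpec, generate
from owlkit.model import (
    AnnotationAssertion,
    Declaration,
    Identifier,
    Literal,
    Named,
    Some,
    SubClassOf,
    And,
    axiom_set_merge,
    contract_iri,
    expand_curie,
    intersection,
    signature_of,
)
from util import N, doc_of, iri, sub

PREFIXES = {
    "go": "http://purl.obolibrary.org/obo/GO_",
    "gorel": "http://purl.obolibrary.org/obo/GO_REL_",
    "a": "http://example.org/a#",
    "b": "http://example.org/a#x",
}


class TestIdentifiers:
    @given(
        prefix=st.sampled_from(sorted(PREFIXES)),
        local=st.from_regex(r"[A-Za-z0-9_][A-Za-z0-9_.-]{0,8}", fullmatch=True),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_curie_expand_contract_roundtrip(self, prefix, local):
        """Expanding a CURIE and re-contracting yields the same CURIE (up to
        longest-prefix preference)."""
        curie = f"{prefix}:{local}"
        expanded = expand_curie(curie, PREFIXES)
        back = contract_iri(expanded.iri, PREFIXES)
        assert back is not None
        assert expand_curie(back, PREFIXES) == expanded

    def test_longest_prefix_wins(self):
        assert contract_iri("http://example.org/a#xyz", PREFIXES) == "b:yz"

    def test_equality_is_iri_equality(self):
        assert Identifier("http://x/a") == Identifier("http://x/a")
        assert Identifier("http://x/a") != Identifier("http://x/b")


class TestExpressions:
    def test_intersection_flattens_and_deduplicates(self):
        nested = intersection([N("A"), intersection([N("B"), N("C")]), N("B")])
        assert isinstance(nested, And)
        assert nested.operands == frozenset({N("A"), N("B"), N("C")})

    def test_intersection_order_insensitive(self):
        assert intersection([N("A"), N("B")]) == intersection([N("B"), N("A")])

    def test_singleton_intersection_collapses(self):
        assert intersection([N("A"), N("A")]) == N("A")


class TestSignature:
    def test_empty_document(self):
        sig = signature_of(doc_of())
        assert sig.classes == sig.object_properties == frozenset()
        assert sig.annotation_properties == sig.individuals == frozenset()

    def test_usage_positions_type_entities(self):
        d = doc_of(
            Declaration(iri("A"), "class"),
            SubClassOf(N("A"), Some(iri("R"), N("B"))),
        )
        sig = signature_of(d)
        assert sig.classes == frozenset({iri("A"), iri("B")})
        assert sig.object_properties == frozenset({iri("R")})

    def test_role_conflict_is_an_error(self):
        d = doc_of(
            Declaration(iri("R"), "annotation_property"),
            SubClassOf(N("A"), Some(iri("R"), N("B"))),
        )
        with pytest.raises(RoleConflictError, match="R"):
            signature_of(d)

    def test_generator_bookkeeping_matches(self):
        doc, ledger = generate(FixtureSpec(n_classes=20, n_properties=3, seed=4))
        sig = signature_of(doc)
        assert {c.iri for c in sig.classes} == set(ledger.classes)
        assert {p.iri for p in sig.object_properties} == set(ledger.properties)
        assert sig.individuals == frozenset()


class TestAxiomSetMerge:
    ANN1 = frozenset({(iri("p"), Literal("v"))})
    ANN2 = frozenset({(iri("p"), Literal("w"))})

    def test_identity_and_idempotence(self):
        x = {sub("A", "B"), sub("B", "C")}
        assert axiom_set_merge(x, set()) == x
        assert axiom_set_merge({sub("A", "B")}, {sub("A", "B")}) == {sub("A", "B")}

    def test_annotation_variants_both_survive(self):
        a = SubClassOf(N("A"), N("B"), self.ANN1)
        b = SubClassOf(N("A"), N("B"), self.ANN2)
        merged = axiom_set_merge({a}, {b})
        assert len(merged) == 2

    @given(st.data())
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_union_laws_and_signature_distributes(self, data):
        docs = []
        for seed in data.draw(st.lists(st.integers(0, 50), min_size=3, max_size=3, unique=True)):
            doc, _ = generate(FixtureSpec(n_classes=6, seed=seed))
            docs.append(doc)
        x, y, z = (d.axioms for d in docs)
        assert axiom_set_merge(x, y) == axiom_set_merge(y, x)
        assert axiom_set_merge(axiom_set_merge(x, y), z) == axiom_set_merge(x, axiom_set_merge(y, z))
        assert axiom_set_merge(x, x) == x
        merged_sig = signature_of(axiom_set_merge(x, y))
        assert merged_sig == signature_of(x).union(signature_of(y))
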