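"""Module extraction: MIREOT reachability and syntactic-locality guarantees."""

import random

import pytest

from owlkit.errors import ConfigurationError, UnknownTermError
from owlkit.extract import ExtractRequest, annotate_sources, extract, extract_mireot, extract_slme
from owlkit.fixtures import FixtureSpec, generate
from owlkit.model import (
    AnnotationAssertion,
    Declaration,
    Identifier,
    Literal,
    Named,
    SubClassOf,
    is_logical,
    signature_of,
)
from owlkit.oracle import ClosureOracle, reachable_ancestors
from owlkit import vocab
from util import N, doc_of, iri, sub

CHAIN = doc_of(
    sub("A", "B"),
    sub("B", "C"),
    Declaration(iri("A"), "class"),
    Declaration(iri("B"), "class"),
    Declaration(iri("C"), "class"),
    AnnotationAssertion(iri("A"), Identifier(vocab.RDFS_LABEL), Literal("a")),
)


def classes_of(module):
    return {ax.entity for ax in module.axioms if isinstance(ax, Declaration) and ax.entity_type == "class"}


class TestMireot:
    def test_ancestors_up_to_root(self):
        module = extract_mireot(CHAIN, ExtractRequest("mireot", bottom_terms=frozenset({iri("A")})))
        assert classes_of(module) == {iri("A"), iri("B"), iri("C")}
        assert sub("A", "B") in module.axioms and sub("B", "C") in module.axioms
        # labels travel with the module
        assert AnnotationAssertion(iri("A"), Identifier(vocab.RDFS_LABEL), Literal("a")) in module.axioms

    def test_stop_at_top_terms(self):
        module = extract_mireot(
            CHAIN, ExtractRequest("mireot", bottom_terms=frozenset({iri("A")}), top_terms=frozenset({iri("B")}))
        )
        assert classes_of(module) == {iri("A"), iri("B")}

    def test_bottom_with_no_ancestors(self):
        module = extract_mireot(CHAIN, ExtractRequest("mireot", bottom_terms=frozenset({iri("C")})))
        assert classes_of(module) == {iri("C")}

    def test_unknown_bottom_term_is_an_error(self):
        with pytest.raises(UnknownTermError):
            extract_mireot(CHAIN, ExtractRequest("mireot", bottom_terms=frozenset({iri("nope")})))

    def test_matches_reachability_oracle_on_fixtures(self):
        for seed in (4, 9, 14):
            doc, ledger = generate(FixtureSpec(n_classes=15, p_existential=0.4, seed=seed))
            seed_cls = Identifier(ledger.mireot_seed)
            module = extract_mireot(doc, ExtractRequest("mireot", bottom_terms=frozenset({seed_cls})))
            assert {c.iri for c in classes_of(module)} == ledger.mireot_expected_classes
            expected = reachable_ancestors(doc, [seed_cls])
            assert classes_of(module) == expected


class TestSlme:
    def test_bot_keeps_ancestor_relations_only(self):
        d = doc_of(sub("A", "B"), sub("B", "C"))
        module = extract_slme(d, ExtractRequest("bot", seed=frozenset({iri("B")})))
        logical = {ax for ax in module.axioms if is_logical(ax)}
        assert sub("B", "C") in logical
        assert sub("A", "B") not in logical

    def test_top_keeps_descendant_relations_only(self):
        d = doc_of(sub("A", "B"), sub("B", "C"))
        module = extract_slme(d, ExtractRequest("top", seed=frozenset({iri("B")})))
        logical = {ax for ax in module.axioms if is_logical(ax)}
        assert sub("A", "B") in logical
        assert sub("B", "C") not in logical

    def test_full_signature_seed_keeps_all_logical_axioms(self):
        doc, _ = generate(FixtureSpec(n_classes=10, p_existential=0.5, seed=6))
        sig = signature_of(doc)
        module = extract_slme(doc, ExtractRequest("bot", seed=frozenset(sig.all_entities())))
        assert {ax for ax in doc.axioms if is_logical(ax)} <= module.axioms

    def test_star_is_smallest(self):
        rng = random.Random(5)
        for seed in range(6):
            doc, ledger = generate(FixtureSpec(n_classes=12, p_existential=0.6, seed=40 + seed))
            classes = [Identifier(c) for c in ledger.classes]
            seed_set = frozenset(rng.sample(classes, 3))
            modules = {
                m: extract_slme(doc, ExtractRequest(m, seed=seed_set)) for m in ("bot", "top", "star")
            }
            star = {ax for ax in modules["star"].axioms if is_logical(ax)}
            bot = {ax for ax in modules["bot"].axioms if is_logical(ax)}
            top = {ax for ax in modules["top"].axioms if is_logical(ax)}
            assert star <= bot and star <= top
            for m in modules.values():
                assert m.axioms <= doc.axioms  # syntactic sub-module property

    def test_bot_preserves_seed_subsumptions(self):
        rng = random.Random(11)
        for seed in range(5):
            doc, ledger = generate(FixtureSpec(n_classes=10, p_existential=0.6, seed=60 + seed))
            classes = [Identifier(c) for c in ledger.classes]
            seed_set = frozenset(rng.sample(classes, 4))
            module = extract_slme(doc, ExtractRequest("bot", seed=seed_set))
            doc_oracle = ClosureOracle(doc)
            mod_oracle = ClosureOracle(module)
            for x in seed_set:
                for y in seed_set:
                    if x != y and doc_oracle.entails(Named(x), Named(y)):
                        assert mod_oracle.entails(Named(x), Named(y)), (x, y)

    def test_unknown_seed_is_an_error(self):
        with pytest.raises(UnknownTermError):
            extract_slme(CHAIN, ExtractRequest("bot", seed=frozenset({iri("nope")})))


class TestAnnotateSources:
    def test_one_annotation_per_term_idempotent(self):
        req = ExtractRequest(
            "mireot",
            bottom_terms=frozenset({iri("A")}),
            annotate_with_source=True,
            source_iri=Identifier("http://example.org/src.owl"),
        )
        module = extract(CHAIN, req)
        sources = [
            ax
            for ax in module.axioms
            if isinstance(ax, AnnotationAssertion) and ax.property.iri == vocab.RDFS_IS_DEFINED_BY
        ]
        assert len(sources) == len(classes_of(module))
        again = annotate_sources(module, req)
        assert again.axioms == module.axioms

    def test_missing_source_iri_is_configuration_error(self):
        with pytest.raises(ConfigurationError):
            annotate_sources(CHAIN, ExtractRequest("mireot", annotate_with_source=True))

    def test_empty_module_unchanged(self):
        empty = doc_of()
        req = ExtractRequest("bot", annotate_with_source=True, source_iri=iri("src"))
        assert annotate_sources(empty, req).axioms == set()
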