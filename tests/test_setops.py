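"""merge / remove / filter / annotate / diff and the entity selectors."""

import pytest

from owlkit import vocab
from owlkit.errors import PatternError, UnresolvedImportError
from owlkit.fixtures import FixtureSpec, generate, write_fixture
from owlkit.io import load_catalog, read_document, write_document
from owlkit.model import (
    AnnotationAssertion,
    Declaration,
    Identifier,
    Literal,
    Named,
    OntologyDocument,
    SubClassOf,
    is_logical,
    signature_of,
)
from owlkit.setops import (
    AnnotationMatch,
    Ancestors,
    Descendants,
    SelfSelector,
    annotate,
    diff,
    filter_axioms,
    merge,
    remove_axioms,
    select_entities,
)
from util import N, doc_of, iri, sub

CHAIN = doc_of(sub("A", "B"), sub("B", "C"))


class TestSelectors:
    def test_self(self):
        assert select_entities(CHAIN, {iri("A")}, [SelfSelector()]) == {iri("A")}

    def test_ancestors_and_descendants(self):
        assert select_entities(CHAIN, {iri("A")}, [Ancestors()]) == {iri("B"), iri("C")}
        assert select_entities(CHAIN, {iri("C")}, [Descendants()]) == {iri("A"), iri("B")}

    def test_annotation_regex_ignores_seed(self):
        d = doc_of(
            *(
                AnnotationAssertion(iri(f"K{i}"), Identifier(vocab.IN_SUBSET),
                                    Literal(f"ChEBI_{i}" if i < 4 else f"other_{i}"))
                for i in range(10)
            )
        )
        got = select_entities(
            d, {iri("A")}, [AnnotationMatch(Identifier(vocab.IN_SUBSET), "ChEBI_.*", is_regex=True)]
        )
        assert got == {iri(f"K{i}") for i in range(4)}

    def test_bad_regex(self):
        with pytest.raises(PatternError):
            select_entities(CHAIN, set(), [AnnotationMatch(iri("p"), "(", is_regex=True)])


class TestRemoveFilter:
    def test_remove_nothing(self):
        assert remove_axioms(CHAIN, set(), {"all"}).axioms == CHAIN.axioms

    def test_remove_touching_entity(self):
        out = remove_axioms(CHAIN, {iri("A")}, {"all"})
        assert out.axioms == {sub("B", "C")}

    def test_filter_full_signature_keeps_logic(self):
        doc, _ = generate(FixtureSpec(n_classes=8, seed=5))
        entities = signature_of(doc).all_entities()
        out = filter_axioms(doc, entities, {"all"})
        assert {ax for ax in doc.axioms if is_logical(ax)} <= out.axioms

    def test_filter_empty_set_empties_logic(self):
        out = filter_axioms(CHAIN, set(), {"all"})
        assert out.axioms == set()

    def test_declaration_kept_while_referenced(self):
        d = doc_of(Declaration(iri("A"), "class"), sub("A", "B"), sub("B", "C"))
        out = remove_axioms(d, {iri("A")}, {"declaration"})
        # A is still referenced by a subclass axiom, so the declaration stays
        assert Declaration(iri("A"), "class") in out.axioms
        out2 = remove_axioms(d, {iri("A")}, {"all"})
        assert Declaration(iri("A"), "class") not in out2.axioms

    def test_partition_property(self):
        """remove and filter split the input's axioms of the selected types."""
        for seed in (1, 6, 11):
            doc, ledger = generate(FixtureSpec(n_classes=10, p_existential=0.5, seed=seed))
            entities = {Identifier(ledger.classes[2]), Identifier(ledger.classes[5])}
            for types in ({"subclass"}, {"logical"}, {"annotation"}):
                removed = remove_axioms(doc, entities, types)
                kept = filter_axioms(doc, entities, types)
                selected_kept = {ax for ax in kept.axioms if not isinstance(ax, Declaration)}
                assert selected_kept.isdisjoint(removed.axioms)
                assert selected_kept | removed.axioms == doc.axioms


class TestMerge:
    def test_identity(self):
        assert merge([CHAIN]).axioms == CHAIN.axioms

    def test_union_count(self):
        x = doc_of(sub("A", "B"))
        y = doc_of(sub("B", "C"), sub("A", "B"))
        assert merge([x, y]).axioms == x.axioms | y.axioms

    def test_associativity(self):
        docs = [generate(FixtureSpec(n_classes=6, seed=s))[0] for s in (1, 2, 3)]
        assert merge(docs).axioms == merge([merge(docs[:2]), docs[2]]).axioms

    def test_collapse_import_closure(self, tmp_path):
        doc, ledger = write_fixture(FixtureSpec(n_classes=5, seed=4, import_depth=1), tmp_path)
        catalog = load_catalog(tmp_path / "catalog.tsv")
        out = merge([doc], collapse_import_closure=True, catalog=catalog)
        assert out.imports == []
        imported_axioms = ledger.imported_documents[0][1].axioms
        assert imported_axioms <= out.axioms
        kept = merge([doc], collapse_import_closure=False)
        assert kept.imports == doc.imports

    def test_collapse_unresolved_import_fails(self):
        d = doc_of()
        d.imports = [Identifier("http://example.org/missing.owl")]
        with pytest.raises(UnresolvedImportError):
            merge([d], collapse_import_closure=True, catalog=None)


class TestAnnotate:
    def test_sets_version_iri_idempotently(self):
        v = Identifier("http://example.org/t/2026-01-01/t.owl")
        out = annotate(CHAIN, version_iri=v)
        assert out.version_iri == v
        assert out.axioms == CHAIN.axioms
        again = annotate(out, version_iri=v)
        assert again == out

    def test_version_reaches_obo_header(self, tmp_path):
        doc, _ = generate(FixtureSpec(n_classes=5, seed=1))
        v = Identifier("http://example.org/fix/1/2026-09-18/fix.owl")
        out = annotate(doc, version_iri=v)
        path = tmp_path / "r.obo"
        write_document(out, path)
        assert f"data-version: {v.iri}" in path.read_text()

    def test_malformed_iri_rejected(self):
        from owlkit.errors import ConfigurationError

        with pytest.raises(ConfigurationError):
            annotate(CHAIN, version_iri=Identifier("not an iri"))


class TestDiff:
    def test_identity_and_asymmetry(self):
        extra = sub("X", "Y")
        other = CHAIN.copy()
        other.axioms.add(extra)
        assert diff(CHAIN, CHAIN).identical()
        d = diff(CHAIN, other)
        assert d.only_in_left == set() and d.only_in_right == {extra}
        swapped = diff(other, CHAIN)
        assert swapped.only_in_left == {extra} and swapped.only_in_right == set()

    def test_io_stability(self, tmp_path):
        doc, _ = generate(FixtureSpec(n_classes=12, p_existential=0.4, seed=7))
        path = tmp_path / "f.ttl"
        write_document(doc, path)
        first = read_document(path)
        write_document(first, tmp_path / "g.ttl")
        assert diff(read_document(tmp_path / "g.ttl"), first).identical()
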