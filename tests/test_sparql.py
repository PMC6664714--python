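"""SPARQL query/verify over the document graph view."""

import os

import pytest

from owlkit import vocab
from owlkit.errors import SparqlParseError
from owlkit.fixtures import FixtureSpec, generate, write_fixture
from owlkit.io import load_catalog
from owlkit.model import AnnotationAssertion, Declaration, Identifier, Literal, Named, SubClassOf
from owlkit.setops import merge
from owlkit.sparql import (
    run_ask,
    run_construct,
    run_select,
    run_update,
    to_graph_view,
    verify,
    write_table,
)
from util import N, doc_of, iri, sub

PFX = (
    "PREFIX rdf: <http://www.w3.org/1999/02/22-rdf-syntax-ns#>\n"
    "PREFIX rdfs: <http://www.w3.org/2000/01/rdf-schema#>\n"
    "PREFIX owl: <http://www.w3.org/2002/07/owl#>\n"
)

LABELED = doc_of(
    Declaration(iri("A"), "class"),
    Declaration(iri("B"), "class"),
    Declaration(iri("C"), "class"),
    AnnotationAssertion(iri("A"), Identifier(vocab.RDFS_LABEL), Literal("uno")),
    AnnotationAssertion(iri("A"), Identifier(vocab.RDFS_LABEL), Literal("one")),
    AnnotationAssertion(iri("B"), Identifier(vocab.RDFS_LABEL), Literal("dos")),
    AnnotationAssertion(iri("B"), Identifier(vocab.RDFS_LABEL), Literal("two")),
    AnnotationAssertion(iri("C"), Identifier(vocab.RDFS_LABEL), Literal("three")),
)

MULTI_LABEL_QUERY = PFX + (
    "SELECT DISTINCT ?subject WHERE { ?subject rdfs:label ?l1 . ?subject rdfs:label ?l2 ."
    " FILTER(?l1 != ?l2) }"
)


class TestGraphView:
    def test_no_imports_no_named_graphs(self):
        view = to_graph_view(LABELED, use_graphs=False)
        assert view.named_graphs == {}

    def test_imports_become_named_graphs(self, tmp_path):
        doc, ledger = write_fixture(FixtureSpec(n_classes=5, seed=6, import_depth=1), tmp_path)
        catalog = load_catalog(tmp_path / "catalog.tsv")
        view = to_graph_view(doc, use_graphs=True, catalog=catalog)
        import_iri = ledger.imported_documents[0][0]
        assert import_iri in view.named_graphs
        # union property: every named-graph triple appears in the default graph
        for graph in view.named_graphs.values():
            for triple in graph:
                assert triple in view.default_graph

    def test_default_graph_equals_merge_for_graphless_queries(self, tmp_path):
        doc, _ = write_fixture(FixtureSpec(n_classes=6, seed=9, import_depth=1), tmp_path)
        catalog = load_catalog(tmp_path / "catalog.tsv")
        q = PFX + "SELECT ?s WHERE { ?s a owl:Class . FILTER(isIRI(?s)) }"
        with_graphs = run_select(to_graph_view(doc, use_graphs=True, catalog=catalog), q)
        merged = merge([doc], collapse_import_closure=True, catalog=catalog)
        collapsed = run_select(to_graph_view(merged), q)
        assert with_graphs.rows == collapsed.rows

    def test_graph_clause_scopes_to_one_import(self, tmp_path):
        doc, ledger = write_fixture(FixtureSpec(n_classes=5, seed=6, import_depth=1), tmp_path)
        catalog = load_catalog(tmp_path / "catalog.tsv")
        view = to_graph_view(doc, use_graphs=True, catalog=catalog)
        import_iri = ledger.imported_documents[0][0]
        q = PFX + f"SELECT ?s WHERE {{ GRAPH <{import_iri}> {{ ?s a owl:Class }} }}"
        rows = run_select(view, q).rows
        assert rows and all("fix#M" in r[0] for r in rows)


class TestQueryForms:
    def test_select_counts_classes(self):
        q = PFX + "SELECT ?s WHERE { ?s a owl:Class }"
        assert len(run_select(to_graph_view(LABELED), q).rows) == 3

    def test_ask(self):
        view = to_graph_view(LABELED)
        assert run_ask(view, PFX + 'ASK { <http://example.org/t#A> rdfs:label "uno" }')
        assert not run_ask(view, PFX + 'ASK { <http://example.org/t#A> rdfs:label "zzz" }')

    def test_construct(self):
        q = PFX + (
            "CONSTRUCT { ?s rdfs:comment ?l } WHERE { ?s rdfs:label ?l . "
            'FILTER(STRSTARTS(STR(?l), "t")) }'
        )
        graph = run_construct(to_graph_view(LABELED), q)
        assert len(graph) == 2  # "two" and "three"

    def test_update_inserts_annotation(self):
        q = PFX + 'INSERT DATA { <http://example.org/t#C> rdfs:comment "note" }'
        out = run_update(LABELED, q)
        added = out.axioms - LABELED.axioms
        assert added == {
            AnnotationAssertion(iri("C"), Identifier(vocab.RDFS_COMMENT), Literal("note"))
        }

    def test_parse_error(self):
        with pytest.raises(SparqlParseError):
            run_select(to_graph_view(LABELED), "SELECT WHERE banana")

    def test_csv_and_tsv_cells_match(self, tmp_path):
        table = run_select(to_graph_view(LABELED), PFX + "SELECT ?s ?l WHERE { ?s rdfs:label ?l }")
        csv_path, tsv_path = tmp_path / "r.csv", tmp_path / "r.tsv"
        write_table(table, csv_path, "csv")
        write_table(table, tsv_path, "tsv")
        import csv as _csv

        csv_rows = list(_csv.reader(open(csv_path)))
        tsv_rows = list(_csv.reader(open(tsv_path), delimiter="\t"))
        assert csv_rows == tsv_rows


class TestVerify:
    def test_conforming_fixture_passes(self, tmp_path):
        doc, _ = generate(FixtureSpec(n_classes=8, seed=14))
        status, results = verify(doc, [("multi.rq", MULTI_LABEL_QUERY)], output_dir=str(tmp_path))
        assert status == 0
        assert os.listdir(tmp_path) == []

    def test_two_multilabeled_classes_yield_two_rows(self, tmp_path):
        status, results = verify(LABELED, [("multi.rq", MULTI_LABEL_QUERY)], output_dir=str(tmp_path))
        assert status == 1
        table = results["multi.rq"]
        assert len(table.rows) == 2
        csv_lines = (tmp_path / "multi.csv").read_text().strip().splitlines()
        assert len(csv_lines) == 1 + 2  # header + 2 data rows

    def test_empty_query_list_passes(self):
        status, results = verify(LABELED, [])
        assert status == 0 and results == {}

    def test_status_zero_iff_zero_rows(self):
        for spec in (FixtureSpec(n_classes=6, seed=2),
                     FixtureSpec(n_classes=8, seed=2, violation_census={"duplicate_label": 1})):
            doc, _ = generate(spec)
            dup = PFX + (
                "SELECT ?s WHERE { ?s rdfs:label ?l . ?o rdfs:label ?l . FILTER(?s != ?o) }"
            )
            status, results = verify(doc, [("d.rq", dup)])
            total = sum(len(t.rows) for t in results.values())
            assert (status == 0) == (total == 0)

    def test_malformed_query_is_usage_error(self):
        with pytest.raises(SparqlParseError):
            verify(LABELED, [("bad.rq", "SELEKT ?x WHERE { }")])
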