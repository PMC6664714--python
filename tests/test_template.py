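"""TSV/CSV template tables to ontology modules."""

import pytest

from owlkit import vocab
from owlkit.errors import TemplateError
from owlkit.model import (
    AnnotationAssertion,
    Declaration,
    EquivalentClasses,
    Identifier,
    Literal,
    Named,
    Some,
    SubClassOf,
)
from owlkit.reasoner import reason
from owlkit.setops import merge
from owlkit.sparql import run_select, to_graph_view
from owlkit.template import expand_template, parse_template

PREFIXES = {"x": "http://example.org/x#", "r": "http://example.org/r#"}


def X(local):
    return Identifier(PREFIXES["x"] + local)


def write_tsv(tmp_path, rows):
    path = tmp_path / "t.tsv"
    path.write_text("\n".join("\t".join(row) for row in rows) + "\n")
    return path


BASIC = [
    ["Term ID", "Name", "Parent"],
    ["ID", "LABEL", "SC %"],
    ["x:1", "alpha", "x:2"],
    ["x:2", "beta", ""],
]


class TestParse:
    def test_valid_table(self, tmp_path):
        table = parse_template(write_tsv(tmp_path, BASIC))
        assert [c.kind for c in table.columns] == ["id", "label", "sc"]
        assert len(table.data_rows) == 2

    def test_unknown_template_string(self, tmp_path):
        with pytest.raises(TemplateError, match="XYZ"):
            parse_template(write_tsv(tmp_path, [["h"], ["XYZ %"], ["v"]]))

    def test_missing_id_column(self, tmp_path):
        with pytest.raises(TemplateError, match="ID"):
            parse_template(write_tsv(tmp_path, [["a", "b"], ["LABEL", "SC %"], ["x", "y"]]))

    def test_arity_mismatch_is_row_addressed(self, tmp_path):
        rows = [["a", "b"], ["ID", "LABEL"], ["x:1", "alpha", "extra"]]
        with pytest.raises(TemplateError, match="row 3"):
            parse_template(write_tsv(tmp_path, rows))

    def test_csv_dialect(self, tmp_path):
        path = tmp_path / "t.csv"
        path.write_text('Term ID,Name\nID,LABEL\nx:1,"alpha, the first"\n')
        table = parse_template(path)
        assert table.data_rows == [["x:1", "alpha, the first"]]


class TestExpand:
    def test_basic_row_expansion(self, tmp_path):
        doc = expand_template(parse_template(write_tsv(tmp_path, BASIC)), PREFIXES)
        assert Declaration(X("1"), "class") in doc.axioms
        assert AnnotationAssertion(X("1"), Identifier(vocab.RDFS_LABEL), Literal("alpha")) in doc.axioms
        assert SubClassOf(Named(X("1")), Named(X("2"))) in doc.axioms
        # empty SC cell contributes no subclass axiom for x:2
        assert not any(
            isinstance(ax, SubClassOf) and ax.sub == Named(X("2")) for ax in doc.axioms
        )

    def test_existential_and_equivalence_patterns(self, tmp_path):
        rows = [
            ["id", "part", "def"],
            ["ID", "SC r:partOf some %", "EC %"],
            ["x:1", "x:2", "x:3"],
        ]
        doc = expand_template(parse_template(write_tsv(tmp_path, rows)), PREFIXES)
        part_of = Identifier(PREFIXES["r"] + "partOf")
        assert SubClassOf(Named(X("1")), Some(part_of, Named(X("2")))) in doc.axioms
        assert EquivalentClasses(frozenset({Named(X("1")), Named(X("3"))})) in doc.axioms

    def test_one_declared_entity_per_row(self, tmp_path):
        rows = [["id"], ["ID"]] + [[f"x:{i}"] for i in range(1, 6)]
        doc = expand_template(parse_template(write_tsv(tmp_path, rows)), PREFIXES)
        declared = [ax for ax in doc.axioms if isinstance(ax, Declaration)]
        assert len(declared) == 5

    def test_unexpandable_curie_is_row_addressed(self, tmp_path):
        rows = [["id"], ["ID"], ["nope:1"]]
        with pytest.raises(TemplateError, match="row 3"):
            expand_template(parse_template(write_tsv(tmp_path, rows)), PREFIXES)

    def test_row_order_independence(self, tmp_path):
        rows_a = BASIC
        rows_b = [BASIC[0], BASIC[1], BASIC[3], BASIC[2]]
        doc_a = expand_template(parse_template(write_tsv(tmp_path, rows_a)), PREFIXES)
        doc_b = expand_template(parse_template(write_tsv(tmp_path, rows_b)), PREFIXES)
        assert doc_a.axioms == doc_b.axioms

    def test_labels_reconstructable_via_sparql(self, tmp_path):
        doc = expand_template(parse_template(write_tsv(tmp_path, BASIC)), PREFIXES)
        q = (
            "PREFIX rdfs: <http://www.w3.org/2000/01/rdf-schema#>\n"
            "SELECT ?subject ?value WHERE { ?subject rdfs:label ?value }"
        )
        rows = run_select(to_graph_view(doc), q).rows
        assert rows == [
            ("http://example.org/x#1", "alpha"),
            ("http://example.org/x#2", "beta"),
        ]

    def test_template_merge_reason_path(self, tmp_path):
        """A template module merged into an editors' document reasons cleanly."""
        editors = expand_template(
            parse_template(
                write_tsv(tmp_path, [["id", "parent"], ["ID", "SC %"], ["x:2", "x:3"], ["x:3", ""]])
            ),
            PREFIXES,
        )
        module = expand_template(parse_template(write_tsv(tmp_path, BASIC)), PREFIXES)
        merged = merge([editors, module])
        out = reason(merged)
        assert SubClassOf(Named(X("1")), Named(X("2"))) in out.axioms
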