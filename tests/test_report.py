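"""QC report battery, profiles, output formats, and repair."""

from collections import Counter

import pytest

from owlkit import vocab
from owlkit.errors import ProfileError, RepairError
from owlkit.fixtures import FixtureSpec, generate
from owlkit.model import (
    AnnotationAssertion,
    Declaration,
    Identifier,
    Literal,
    Named,
    SubClassOf,
    strip_annotations,
)
from owlkit.report import (
    LEVELS,
    Violation,
    default_profile,
    load_profile,
    read_report_yaml,
    repair,
    run_report,
    write_report,
)
from util import N, doc_of, iri, sub


class TestDefaultProfile:
    def test_default_fail_on_is_error(self):
        assert default_profile().fail_on == "ERROR"

    def test_three_levels_present(self):
        levels = {c.level for c in default_profile().checks}
        assert levels == set(LEVELS)

    def test_paper_named_checks_present_at_stated_levels(self):
        by_name = {c.name: c.level for c in default_profile().checks}
        assert by_name["missing_label"] == "ERROR"
        assert by_name["duplicate_label"] == "ERROR"
        assert by_name["equivalent_class_pair"] == "WARN"
        assert by_name["self_reference"] == "WARN"
        assert by_name["trailing_whitespace"] == "WARN"
        assert by_name["invalid_xref_syntax"] == "WARN"
        assert by_name["definition_format"] == "INFO"
        assert by_name["missing_definition"] == "INFO"

    def test_every_check_has_doc_url(self):
        assert all(c.doc_url for c in default_profile().checks)


class TestRunReport:
    def test_clean_fixture_reports_nothing(self):
        doc, _ = generate(FixtureSpec(n_classes=5, seed=17))
        violations, failed = run_report(doc)
        assert violations == [] and failed is False

    def test_missing_label_fails_by_default(self):
        doc, _ = generate(FixtureSpec(n_classes=8, seed=17, violation_census={"missing_label": 1}))
        violations, failed = run_report(doc)
        assert failed is True
        assert any(v.rule_name == "missing_label" and v.level == "ERROR" for v in violations)

    def test_fail_on_none_never_fails(self):
        doc, _ = generate(FixtureSpec(n_classes=8, seed=17, violation_census={"missing_label": 1}))
        violations, failed = run_report(doc, default_profile(fail_on="none"))
        assert violations and failed is False

    def test_fail_on_is_monotone(self):
        doc, _ = generate(
            FixtureSpec(n_classes=10, seed=23, violation_census={"trailing_whitespace": 1})
        )
        outcomes = {level: run_report(doc, default_profile(fail_on=level))[1] for level in LEVELS}
        assert outcomes == {"ERROR": False, "WARN": True, "INFO": True}
        assert run_report(doc, default_profile(fail_on="none"))[1] is False

    def test_determinism(self):
        doc, _ = generate(FixtureSpec(n_classes=10, seed=2, violation_census={"duplicate_label": 1}))
        assert run_report(doc) == run_report(doc)

    def test_census_recovery(self):
        census = {
            "missing_label": 2,
            "duplicate_definition": 1,
            "multiple_definitions": 1,
            "self_reference": 1,
            "invalid_xref_syntax": 2,
            "equivalent_class_pair": 1,
            "missing_ontology_title": 1,
            "definition_format": 1,
        }
        doc, ledger = generate(FixtureSpec(n_classes=25, seed=19, violation_census=census))
        violations, _ = run_report(doc)
        assert Counter(v.rule_name for v in violations) == ledger.violation_counts()
        by_rule = {}
        for v in violations:
            by_rule.setdefault(v.rule_name, set()).add(v.subject.iri)
        for rule, subjects in ledger.violations.items():
            assert by_rule[rule] == set(subjects), rule


class TestProfiles:
    def test_override_exclude_and_custom(self, tmp_path):
        (tmp_path / "custom.rq").write_text(
            "PREFIX rdfs: <http://www.w3.org/2000/01/rdf-schema#>\n"
            "SELECT ?subject WHERE { ?subject rdfs:subClassOf ?subject }"
        )
        profile_path = tmp_path / "profile.txt"
        profile_path.write_text(
            "WARN\tmissing_label\n"
            "EXCLUDE\tmissing_definition\n"
            "ERROR\tmy_self_ref\tcustom.rq\n"
        )
        profile = load_profile(profile_path)
        by_name = {c.name: c for c in profile.checks}
        assert by_name["missing_label"].level == "WARN"
        assert "missing_definition" not in by_name
        assert by_name["my_self_ref"].level == "ERROR"

        doc = doc_of(sub("A", "A"))
        violations, failed = run_report(doc, profile)
        assert any(v.rule_name == "my_self_ref" for v in violations)
        assert failed

    def test_bad_custom_query_names_the_check(self, tmp_path):
        (tmp_path / "broken.rq").write_text("SELEKT nope")
        profile_path = tmp_path / "p.txt"
        profile_path.write_text("ERROR\tbroken_check\tbroken.rq\n")
        profile = load_profile(profile_path)
        with pytest.raises(ProfileError, match="broken_check"):
            run_report(doc_of(), profile)


class TestWriteReport:
    VIOLATIONS = [
        Violation("missing_label", "ERROR", iri("A"), Identifier(vocab.RDFS_LABEL), ""),
        Violation("trailing_whitespace", "WARN", iri("B"), Identifier(vocab.RDFS_LABEL), "x "),
        Violation("missing_definition", "INFO", iri("C"), Identifier(vocab.DEFINITION), ""),
    ]

    def test_tsv_rows(self, tmp_path):
        path = tmp_path / "r.tsv"
        write_report(self.VIOLATIONS, "tsv", path)
        lines = path.read_text().strip().splitlines()
        assert lines[0].split("\t") == ["level", "rule", "subject", "property", "value"]
        assert len(lines) == 1 + 3

    def test_empty_report_is_header_only(self, tmp_path):
        path = tmp_path / "r.tsv"
        write_report([], "tsv", path)
        assert len(path.read_text().strip().splitlines()) == 1

    def test_yaml_round_trip(self, tmp_path):
        path = tmp_path / "r.yaml"
        write_report(self.VIOLATIONS, "yaml", path)
        assert read_report_yaml(path) == sorted(self.VIOLATIONS, key=Violation.sort_key)


class TestRepair:
    def test_duplicate_axiom_annotations_merge(self):
        ann1 = frozenset({(iri("p"), Literal("v"))})
        ann2 = frozenset({(iri("p"), Literal("w"))})
        d = doc_of(SubClassOf(N("A"), N("B"), ann1), SubClassOf(N("A"), N("B"), ann2))
        out = repair(d)
        assert out.axioms == {SubClassOf(N("A"), N("B"), ann1 | ann2)}

    def test_deprecated_reference_rewritten(self):
        d = doc_of(
            sub("C", "D"),
            AnnotationAssertion(iri("D"), Identifier(vocab.OWL_DEPRECATED),
                                Literal("true", datatype=vocab.XSD_BOOLEAN)),
            AnnotationAssertion(iri("D"), Identifier(vocab.REPLACED_BY), iri("Dprime")),
            AnnotationAssertion(iri("D"), Identifier(vocab.RDFS_LABEL), Literal("obsolete D")),
        )
        out = repair(d)
        assert sub("C", "Dprime") in out.axioms
        assert sub("C", "D") not in out.axioms
        # annotations on the deprecated term itself are retained
        assert AnnotationAssertion(iri("D"), Identifier(vocab.RDFS_LABEL), Literal("obsolete D")) in out.axioms

    def test_replacement_chains_resolve_transitively(self):
        def deprecate(old, new):
            return [
                AnnotationAssertion(iri(old), Identifier(vocab.OWL_DEPRECATED),
                                    Literal("true", datatype=vocab.XSD_BOOLEAN)),
                AnnotationAssertion(iri(old), Identifier(vocab.REPLACED_BY), iri(new)),
            ]

        d = doc_of(sub("C", "D"), *deprecate("D", "D2"), *deprecate("D2", "D3"))
        out = repair(d)
        assert sub("C", "D3") in out.axioms

    def test_replacement_cycle_is_an_error(self):
        d = doc_of(
            sub("C", "D"),
            AnnotationAssertion(iri("D"), Identifier(vocab.OWL_DEPRECATED),
                                Literal("true", datatype=vocab.XSD_BOOLEAN)),
            AnnotationAssertion(iri("D"), Identifier(vocab.REPLACED_BY), iri("E")),
            AnnotationAssertion(iri("E"), Identifier(vocab.OWL_DEPRECATED),
                                Literal("true", datatype=vocab.XSD_BOOLEAN)),
            AnnotationAssertion(iri("E"), Identifier(vocab.REPLACED_BY), iri("D")),
        )
        with pytest.raises(RepairError, match="cycle"):
            repair(d)

    def test_repair_preserves_entailments_among_live_terms(self):
        from owlkit.oracle import ClosureOracle
        from owlkit.model import Identifier as Id

        doc, ledger = generate(
            FixtureSpec(
                n_classes=12,
                p_existential=0.5,
                seed=29,
                violation_census={"duplicate_axiom": 1, "deprecated_with_replacement": 1},
            )
        )
        deprecated = set(ledger.violations["deprecated_with_replacement"])
        out = repair(doc)
        before = ClosureOracle(doc).named_subsumptions()
        after = ClosureOracle(out).named_subsumptions()
        for a, b in before:
            if a.iri in deprecated or b.iri in deprecated:
                continue
            assert (a, b) in after
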