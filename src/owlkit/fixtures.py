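"""Synthetic test ontologies with known ground truth.

The generator builds a rooted DAG taxonomy (every class picks 1–2 parents
among earlier classes) with unique labels and well-formed definitions,
genus-differentia equivalence definitions ``C ≡ P ⊓ ∃R.F`` on a configurable
fraction of classes, optional chains of imported documents, and an injected
violation census. Everything derives from one integer seed, so identical
spec + seed always yields byte-identical serialized fixtures.

The accompanying ledger is computed by *independent* simple algorithms — the
exhaustive closure oracle and plain graph reachability — never by the modules
under test, so tests can compare classifier/extractor/report output against
it.
"""

from __future__ import annotations

import os
import random
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Set, Tuple

import networkx as nx
import yaml

from . import vocab
from .errors import ConfigurationError
from .model import (
    AnnotationAssertion,
    Declaration,
    DisjointClasses,
    EquivalentClasses,
    Identifier,
    Literal,
    Named,
    OntologyDocument,
    Some,
    SubClassOf,
    intersection,
)
from .oracle import ClosureOracle, reachable_ancestors

NS = "http://example.org/fix#"

INJECTABLE_RULES = (
    "missing_label",
    "duplicate_label",
    "duplicate_definition",
    "multiple_definitions",
    "self_reference",
    "trailing_whitespace",
    "invalid_xref_syntax",
    "definition_format",
    "missing_definition",
    "missing_ontology_license",
    "missing_ontology_title",
    "equivalent_class_pair",
    "unsatisfiable",
    "duplicate_axiom",
    "deprecated_with_replacement",
)


@dataclass
class FixtureSpec:
    n_classes: int = 20
    n_properties: int = 2
    p_existential: float = 0.3
    violation_census: Dict[str, int] = field(default_factory=dict)
    import_depth: int = 0
    seed: int = 0

    def validate(self):
        if self.n_classes < 1 or self.n_properties < 0 or self.import_depth < 0:
            raise ConfigurationError("counts must be non-negative (and at least one class)")
        if not 0.0 <= self.p_existential <= 1.0:
            raise ConfigurationError("p_existential must be a probability")
        for rule, count in self.violation_census.items():
            if rule not in INJECTABLE_RULES:
                raise ConfigurationError(f"unknown violation rule {rule!r}")
            if count < 0:
                raise ConfigurationError(f"negative count for {rule!r}")


@dataclass
class FixtureLedger:
    """Ground truth, computed independently of the modules under test."""

    classes: List[str] = field(default_factory=list)
    properties: List[str] = field(default_factory=list)
    asserted_edges: List[Tuple[str, str]] = field(default_factory=list)
    # transitive reduction of the entailed named-class hierarchy, between
    # equivalence-group representatives (least IRI), per the closure oracle
    inferred_direct_edges: Set[Tuple[str, str]] = field(default_factory=set)
    equivalent_pairs: Set[Tuple[str, str]] = field(default_factory=set)
    unsatisfiable: Set[str] = field(default_factory=set)
    violations: Dict[str, List[str]] = field(default_factory=dict)
    mireot_seed: Optional[str] = None
    mireot_expected_classes: Set[str] = field(default_factory=set)
    imported_documents: List[Tuple[str, OntologyDocument]] = field(default_factory=list)

    def violation_counts(self) -> Dict[str, int]:
        return {rule: len(subjects) for rule, subjects in self.violations.items()}

    def to_mapping(self) -> dict:
        return {
            "classes": list(self.classes),
            "properties": list(self.properties),
            "asserted_edges": [list(e) for e in sorted(self.asserted_edges)],
            "inferred_direct_edges": [list(e) for e in sorted(self.inferred_direct_edges)],
            "equivalent_pairs": [list(e) for e in sorted(self.equivalent_pairs)],
            "unsatisfiable": sorted(self.unsatisfiable),
            "violations": {k: sorted(v) for k, v in self.violations.items()},
            "mireot_seed": self.mireot_seed,
            "mireot_expected_classes": sorted(self.mireot_expected_classes),
            "imports": [iri for iri, _ in self.imported_documents],
        }


_LABEL = Identifier(vocab.RDFS_LABEL)
_DEF = Identifier(vocab.DEFINITION)
_XREF = Identifier(vocab.XREF)
_COMMENT = Identifier(vocab.RDFS_COMMENT)


def _cls(i: int) -> Identifier:
    return Identifier(f"{NS}C{i:04d}")


def _label_of(doc: OntologyDocument, cls: Identifier) -> Optional[AnnotationAssertion]:
    for ax in doc.axioms:
        if isinstance(ax, AnnotationAssertion) and ax.subject == cls and ax.property == _LABEL:
            return ax
    return None


def _def_of(doc: OntologyDocument, cls: Identifier) -> Optional[AnnotationAssertion]:
    for ax in doc.axioms:
        if isinstance(ax, AnnotationAssertion) and ax.subject == cls and ax.property == _DEF:
            return ax
    return None


def generate(spec: FixtureSpec) -> Tuple[OntologyDocument, FixtureLedger]:
    spec.validate()
    rng = random.Random(spec.seed)
    ledger = FixtureLedger()

    doc = OntologyDocument(
        ontology_iri=Identifier(f"http://example.org/fix/{spec.seed}.owl"),
        prefixes={"fix": NS},
        ontology_annotations={
            (Identifier(vocab.TITLE), Literal(f"Fixture ontology {spec.seed}")),
            (Identifier(vocab.LICENSE), Identifier("https://creativecommons.org/licenses/by/4.0/")),
        },
    )

    classes = [_cls(i) for i in range(1, spec.n_classes + 1)]
    props = [Identifier(f"{NS}R{j:02d}") for j in range(1, spec.n_properties + 1)]
    ledger.classes = [c.iri for c in classes]
    ledger.properties = [p.iri for p in props]

    for c in classes:
        doc.axioms.add(Declaration(c, "class"))
    for p in props:
        doc.axioms.add(Declaration(p, "object_property"))
        doc.axioms.add(AnnotationAssertion(p, _LABEL, Literal(f"relation {p.iri[-2:]}")))

    for i, c in enumerate(classes, start=1):
        doc.axioms.add(AnnotationAssertion(c, _LABEL, Literal(f"class {i:04d}")))
        doc.axioms.add(AnnotationAssertion(c, _DEF, Literal(f"A fixture class numbered {i:04d}.")))
        doc.axioms.add(AnnotationAssertion(c, _XREF, Literal(f"FIX:{i:04d}")))

    parents: Dict[int, List[int]] = {}
    for i in range(2, spec.n_classes + 1):
        k = 1 if spec.n_classes < 4 else rng.choice((1, 1, 2))
        choices = sorted(rng.sample(range(1, i), min(k, i - 1)))
        parents[i] = choices
        for j in choices:
            doc.axioms.add(SubClassOf(Named(_cls(i)), Named(_cls(j))))
            ledger.asserted_edges.append((_cls(i).iri, _cls(j).iri))

    # genus-differentia definitions and some asserted existentials
    if props:
        for i in range(3, spec.n_classes + 1):
            if rng.random() < spec.p_existential:
                genus = _cls(parents[i][0])
                prop = props[rng.randrange(len(props))]
                filler = _cls(rng.randrange(1, i))
                doc.axioms.add(
                    EquivalentClasses(
                        frozenset({Named(_cls(i)), intersection([Named(genus), Some(prop, Named(filler))])})
                    )
                )
            elif rng.random() < spec.p_existential:
                prop = props[rng.randrange(len(props))]
                filler = _cls(rng.randrange(1, i))
                doc.axioms.add(SubClassOf(Named(_cls(i)), Some(prop, Named(filler))))

    _inject_violations(doc, spec, rng, ledger)
    _build_imports(doc, spec, ledger)
    _finish_ledger(doc, spec, ledger)
    return doc, ledger


# ---------------------------------------------------------------------------
# violation injection


def _inject_violations(doc, spec, rng, ledger):
    census = dict(spec.violation_census)
    # victims are distinct non-root classes so injections never interact
    pool = list(range(2, spec.n_classes + 1))
    rng.shuffle(pool)
    needed = 0
    for rule, count in census.items():
        needed += {"duplicate_label": 2, "duplicate_definition": 2, "duplicate_axiom": 0,
                   "missing_ontology_license": 0, "missing_ontology_title": 0,
                   "equivalent_class_pair": 1, "unsatisfiable": 0,
                   "deprecated_with_replacement": 2}.get(rule, 1) * count
    if needed > len(pool):
        raise ConfigurationError(
            f"census needs {needed} victim classes but only {len(pool)} are available"
        )

    def take() -> Identifier:
        return _cls(pool.pop())

    fresh_index = [spec.n_classes]

    def fresh(label_stub: str) -> Identifier:
        fresh_index[0] += 1
        i = fresh_index[0]
        c = _cls(i)
        doc.axioms.add(Declaration(c, "class"))
        doc.axioms.add(AnnotationAssertion(c, _LABEL, Literal(f"{label_stub} {i:04d}")))
        doc.axioms.add(AnnotationAssertion(c, _DEF, Literal(f"An injected class numbered {i:04d}.")))
        doc.axioms.add(AnnotationAssertion(c, _XREF, Literal(f"FIX:{i:04d}")))
        return c

    for rule in sorted(census):
        count = census[rule]
        subjects: List[str] = []
        for _ in range(count):
            if rule == "missing_label":
                victim = take()
                doc.axioms.discard(_label_of(doc, victim))
                subjects.append(victim.iri)
            elif rule == "missing_definition":
                victim = take()
                doc.axioms.discard(_def_of(doc, victim))
                subjects.append(victim.iri)
            elif rule == "duplicate_label":
                a, b = take(), take()
                label = _label_of(doc, a).value
                doc.axioms.discard(_label_of(doc, b))
                doc.axioms.add(AnnotationAssertion(b, _LABEL, label))
                subjects.append(min(a.iri, b.iri))
            elif rule == "duplicate_definition":
                a, b = take(), take()
                definition = _def_of(doc, a).value
                doc.axioms.discard(_def_of(doc, b))
                doc.axioms.add(AnnotationAssertion(b, _DEF, definition))
                subjects.append(min(a.iri, b.iri))
            elif rule == "multiple_definitions":
                victim = take()
                doc.axioms.add(
                    AnnotationAssertion(victim, _DEF, Literal(f"Another definition of {victim.iri[-4:]}."))
                )
                subjects.append(victim.iri)
            elif rule == "self_reference":
                victim = take()
                doc.axioms.add(SubClassOf(Named(victim), Named(victim)))
                subjects.append(victim.iri)
            elif rule == "trailing_whitespace":
                victim = take()
                old = _label_of(doc, victim)
                doc.axioms.discard(old)
                doc.axioms.add(AnnotationAssertion(victim, _LABEL, Literal(old.value.lexical + " ")))
                subjects.append(victim.iri)
            elif rule == "invalid_xref_syntax":
                victim = take()
                doc.axioms.add(AnnotationAssertion(victim, _XREF, Literal("not a valid xref")))
                subjects.append(victim.iri)
            elif rule == "definition_format":
                victim = take()
                doc.axioms.discard(_def_of(doc, victim))
                doc.axioms.add(
                    AnnotationAssertion(victim, _DEF, Literal("lower-case definition without period"))
                )
                subjects.append(victim.iri)
            elif rule == "missing_ontology_license":
                doc.ontology_annotations = {
                    (p, v) for p, v in doc.ontology_annotations if p.iri != vocab.LICENSE
                }
                subjects.append(doc.ontology_iri.iri)
            elif rule == "missing_ontology_title":
                doc.ontology_annotations = {
                    (p, v) for p, v in doc.ontology_annotations if p.iri != vocab.TITLE
                }
                subjects.append(doc.ontology_iri.iri)
            elif rule == "equivalent_class_pair":
                victim = take()
                twin = fresh("equivalent twin")
                doc.axioms.add(EquivalentClasses(frozenset({Named(twin), Named(victim)})))
                subjects.append(min(victim.iri, twin.iri))
            elif rule == "unsatisfiable":
                left = fresh("disjoint left")
                right = fresh("disjoint right")
                bad = fresh("unsatisfiable")
                doc.axioms.add(SubClassOf(Named(left), Named(_cls(1))))
                doc.axioms.add(SubClassOf(Named(right), Named(_cls(1))))
                doc.axioms.add(SubClassOf(Named(bad), Named(left)))
                doc.axioms.add(SubClassOf(Named(bad), Named(right)))
                doc.axioms.add(DisjointClasses(frozenset({left, right})))
                subjects.append(bad.iri)
            elif rule == "duplicate_axiom":
                # two copies of one subclass axiom, differing only in their
                # annotations (both carry annotations so RDF round-trips stay exact)
                sub, sup = sorted(ledger.asserted_edges)[0]
                bare = SubClassOf(Named(Identifier(sub)), Named(Identifier(sup)))
                doc.axioms.discard(bare)
                doc.axioms.add(
                    SubClassOf(Named(Identifier(sub)), Named(Identifier(sup)),
                               frozenset({(_COMMENT, Literal("from editor A"))}))
                )
                doc.axioms.add(
                    SubClassOf(Named(Identifier(sub)), Named(Identifier(sup)),
                               frozenset({(_COMMENT, Literal("from editor B"))}))
                )
                subjects.append(sub)
            elif rule == "deprecated_with_replacement":
                old, new = take(), take()
                doc.axioms.add(
                    AnnotationAssertion(old, Identifier(vocab.OWL_DEPRECATED),
                                        Literal("true", datatype=vocab.XSD_BOOLEAN))
                )
                doc.axioms.add(AnnotationAssertion(old, Identifier(vocab.REPLACED_BY), new))
                subjects.append(old.iri)
        if subjects:
            ledger.violations[rule] = subjects


# ---------------------------------------------------------------------------
# imports


def _build_imports(doc, spec, ledger):
    parent = doc
    for depth in range(1, spec.import_depth + 1):
        iri = Identifier(f"http://example.org/fix/{spec.seed}/imp{depth}.owl")
        imported = OntologyDocument(
            ontology_iri=iri,
            prefixes={"fix": NS},
            ontology_annotations={
                (Identifier(vocab.TITLE), Literal(f"Import level {depth}")),
                (Identifier(vocab.LICENSE), Identifier("https://creativecommons.org/licenses/by/4.0/")),
            },
        )
        base = 1000 * depth
        members = [Identifier(f"{NS}M{base + k:05d}") for k in range(1, 4)]
        for k, m in enumerate(members, start=1):
            imported.axioms.add(Declaration(m, "class"))
            imported.axioms.add(AnnotationAssertion(m, _LABEL, Literal(f"imported class {base + k:05d}")))
            imported.axioms.add(
                AnnotationAssertion(m, _DEF, Literal(f"An imported class numbered {base + k:05d}."))
            )
        imported.axioms.add(SubClassOf(Named(members[1]), Named(members[0])))
        imported.axioms.add(SubClassOf(Named(members[2]), Named(members[1])))
        parent.imports.append(iri)
        ledger.imported_documents.append((iri.iri, imported))
        parent = imported


# ---------------------------------------------------------------------------
# ledger bookkeeping (independent oracles only)


def _finish_ledger(doc, spec, ledger):
    oracle = ClosureOracle(doc)
    subs = oracle.named_subsumptions()
    unsat = {c.iri for c in oracle.unsatisfiable()}
    ledger.unsatisfiable = unsat

    named = sorted({a for a, _ in subs} | {b for _, b in subs} | {Identifier(c) for c in ledger.classes})
    named = [c for c in named if c.iri not in unsat]
    mutual = {(a, b) for (a, b) in subs if (b, a) in subs and a.iri not in unsat and b.iri not in unsat}
    ledger.equivalent_pairs = {(min(a.iri, b.iri), max(a.iri, b.iri)) for a, b in mutual}
    # unsatisfiable classes are mutually equivalent (all collapse to Nothing)
    for a in unsat:
        for b in unsat:
            if a < b:
                ledger.equivalent_pairs.add((a, b))

    # the report's equivalence check is taxonomy-driven, so its ground truth
    # is the oracle's mutual-subsumption pairs (covering both injected twins
    # and any equivalences arising from colliding definitions)
    if ledger.equivalent_pairs:
        ledger.violations["equivalent_class_pair"] = [a for a, _b in sorted(ledger.equivalent_pairs)]
    else:
        ledger.violations.pop("equivalent_class_pair", None)

    rep: Dict[Identifier, Identifier] = {}
    for c in named:
        group = {c} | {b for (a, b) in mutual if a == c}
        rep[c] = min(group)
    g = nx.DiGraph()
    g.add_nodes_from({r.iri for r in rep.values()})
    for a, b in subs:
        if a.iri in unsat or b.iri in unsat:
            continue
        ra, rb = rep[a], rep[b]
        if ra != rb:
            g.add_edge(ra.iri, rb.iri)
    reduced = nx.transitive_reduction(g)
    ledger.inferred_direct_edges = set(reduced.edges())

    # designated MIREOT seed: the last class, with its ancestor closure
    if spec.n_classes >= 1:
        seed_cls = Identifier(ledger.classes[-1])
        ledger.mireot_seed = seed_cls.iri
        ledger.mireot_expected_classes = {
            c.iri for c in reachable_ancestors(doc, [seed_cls])
        }


# ---------------------------------------------------------------------------
# writing fixtures to disk


def write_fixture(spec: FixtureSpec, out_dir) -> Tuple[OntologyDocument, FixtureLedger]:
    """Write ``fixture.ttl`` and ``fixture.obo``, any imported ontologies, a
    ``catalog.tsv`` and the ``ledger.yaml``."""
    from .io import write_document

    doc, ledger = generate(spec)
    os.makedirs(out_dir, exist_ok=True)
    write_document(doc, os.path.join(out_dir, "fixture.ttl"))
    write_document(doc, os.path.join(out_dir, "fixture.obo"))
    catalog_lines = []
    for index, (iri, imported) in enumerate(ledger.imported_documents, start=1):
        name = f"import{index}.ttl"
        write_document(imported, os.path.join(out_dir, name))
        catalog_lines.append(f"{iri}\t{name}")
    with open(os.path.join(out_dir, "catalog.tsv"), "w", encoding="utf-8") as handle:
        handle.write("\n".join(catalog_lines) + ("\n" if catalog_lines else ""))
    with open(os.path.join(out_dir, "ledger.yaml"), "w", encoding="utf-8") as handle:
        yaml.safe_dump(ledger.to_mapping(), handle, sort_keys=True)
    return doc, ledger


def load_spec(path) -> FixtureSpec:
    data = yaml.safe_load(open(path, encoding="utf-8")) or {}
    return FixtureSpec(
        n_classes=int(data.get("n_classes", 20)),
        n_properties=int(data.get("n_properties", 2)),
        p_existential=float(data.get("p_existential", 0.3)),
        violation_census={str(k): int(v) for k, v in (data.get("violation_census") or {}).items()},
        import_depth=int(data.get("import_depth", 0)),
        seed=int(data.get("seed", 0)),
    )
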