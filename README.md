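# owlkit

An ontology workflow toolkit: a Python library and chainable command-line
tool for the release engineering of bio-ontologies — quality-control checks,
reasoning-based validation and classification, axiom
relaxation/reduction/materialization, import-module extraction, merging,
SPARQL query/verify, configurable reports, automatic repair, and
spreadsheet-driven term generation. Everything runs locally over a
self-contained EL-fragment OWL model: no external reasoner, triple store, or
network service.

It is written for ontology maintainers who assemble release pipelines from
composable steps (typically under `make`): check the editors' file, refresh
import modules from term lists, build the release products, convert formats.

## The model in brief

Documents are sets of axioms over OWL 2 EL class expressions — named classes,
existential restrictions `R some B`, intersections — plus disjointness,
subproperty, declaration, and annotation axioms. The classifier normalizes to
the standard EL normal forms and saturates with completion rules to a
fixpoint, giving sound and complete named-class subsumption
`A ⊑ B` in polynomial time; *coherence* means no class is subsumed by `⊥`.
The release transformations around it:

* **reason** — halt if incoherent, else assert all direct inferred
  `A ⊑ B` axioms;
* **relax** — from each definition `A ≡ C₁ ⊓ … ⊓ Cₙ` assert every `A ⊑ Cᵢ`,
  so consumers can navigate without a reasoner;
* **reduce** — transitive reduction of the asserted subclass graph (removes
  redundant and duplicate edges, keeps what relax asserted);
* **materialize** — assert entailed `A ⊑ R some B` with most-specific named
  fillers;
* **extract** — MIREOT (ancestors of requested terms) or syntactic-locality
  modules (BOT/TOP/STAR), which provably preserve all entailments over the
  seed signature.

Formats: Turtle, RDF/XML, and OBO flat file 1.4 (a documented subset), all
with byte-deterministic serialization. See `docs/methods.md` for the fine
print and `docs/checks.md` for the QC check catalogue.

## Worked example

Generate a reproducible 25-class test ontology with one import, then build a
release in a single chained command (the in-memory ontology flows from step
to step; `--output` snapshots it without breaking the chain):

```sh
owlkit fixtures --spec spec.yaml --out fx
owlkit -v --catalog fx/catalog.tsv \
    merge --input fx/fixture.ttl \
    reason \
    relax \
    reduce \
    annotate --version-iri http://example.org/fix/2026/release.owl --output release.ttl \
    convert --output release.obo
```

prints (to stderr, with `-v`):

```
reason: 2 inferred axioms asserted
annotate: wrote release.ttl (155 axioms)
convert: wrote release.obo (155 axioms)
```

— the merged ontology was coherent, two subsumptions that only follow from
logical definitions were asserted as plain `subClassOf` axioms, and the
release carries the version IRI in both formats (`release.obo` begins
`data-version: http://example.org/fix/2026/release.owl`).

Running the QC battery on an ontology with injected problems (two labels
stripped, one trailing space):

```sh
owlkit report --input fxd/fixture.ttl --output report.tsv   # exit status 1
```

```
level   rule                   subject                          property     value
ERROR   missing_label          http://example.org/fix#C0016    rdfs:label
ERROR   missing_label          http://example.org/fix#C0024    rdfs:label
WARN    equivalent_class_pair  http://example.org/fix#C0019                 http://example.org/fix#C0024
WARN    trailing_whitespace    http://example.org/fix#C0018    rdfs:label   "class 0018 "
```

The two ERROR rows are the injected missing labels and make the exit status
non-zero (the default `--fail-on ERROR`); the trailing-whitespace WARN is the
third injection; and the `equivalent_class_pair` WARN is real reasoning — two
of the randomly generated classes happen to carry the same logical
definition, so the classifier infers them equivalent. `owlkit diff` between
the editors' file and the release lists exactly the asserted/removed axioms
(23 lines here), never serialization noise.

The full walkthrough, executed verbatim by the integration tests, is in
`docs/examples.md`.

## Commands

`convert` `reason` `relax` `reduce` `materialize` `extract` `remove` `filter`
`merge` `annotate` `diff` `query` `verify` `report` `repair` `template`
`fixtures` — run `owlkit <command> --input f --output g [options]`, or chain
them. Exit codes: 0 success, 1 check failures (verify/report violations,
incoherence), 2 usage errors, 3 I/O or parse errors.

## Acceptance script

`python scripts/acceptance.py --seed <int> --out results/acceptance.json`
re-runs the whole stack from scratch on seeded synthetic ontologies: the
verify gate, locality-module extraction, the chained
merge→reason→relax→reduce→annotate→convert release build (with every added
axiom re-checked against an independent entailment oracle), report census
recovery, and a classifier-vs-oracle comparison on a batch of small random
ontologies. It writes its JSON result object to `--out` and exits non-zero if
any stage misbehaves.
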