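# QC checks

Every built-in check of the default report profile, with a suggested manual
fix. Severity levels: **ERROR** (must fix before release; fails the report by
default), **WARN** (fix soon), **INFO** (style recommendation).

## missing-label (ERROR)

A class has no `rdfs:label`. Fix: add exactly one human-readable label.

## duplicate-label (ERROR)

Two distinct classes share a label (reported once per pair, under the
lexicographically smaller IRI). Fix: rename one of the classes, or merge the
terms if they are genuinely the same and deprecate the loser.

## duplicate-definition (ERROR)

Two distinct classes share a textual definition. Fix: write definitions that
distinguish the two terms, or merge them.

## multiple-definitions (ERROR)

One class carries more than one textual definition. Fix: keep a single
definition; move alternatives into comments or synonyms.

## equivalent-class-pair (WARN)

Two distinct named classes are *inferred* to be equivalent — usually an
accident of two identical logical definitions. Fix: differentiate the
definitions, or assert the equivalence deliberately and document it.

## self-reference (WARN)

A class is asserted to be a subclass of itself. Fix: delete the axiom (it is
a tautology; `reduce` also removes it).

## trailing-whitespace (WARN)

An annotation value starts or ends with whitespace. Fix: trim the value.

## invalid-xref-syntax (WARN)

A database cross-reference does not match `PREFIX:LOCAL` (nonempty parts, no
whitespace, no extra colon). Fix: use a registered prefix and a bare local
identifier.

## missing-ontology-license (WARN)

The ontology header has no `dcterms:license`. Fix: add a license IRI.

## missing-ontology-title (WARN)

The ontology header has no `dcterms:title`. Fix: add a title.

## definition-format (INFO)

A definition does not begin with an uppercase letter and end with a period.
Fix: reword to the community convention.

## missing-definition (INFO)

A class has no textual definition. Fix: add one, with provenance xrefs.

## custom-checks

Custom checks are SPARQL SELECT queries added through a profile line
`LEVEL<TAB>name<TAB>query-path`. The query must bind `?subject` and may bind
`?property` and `?value`; every returned row becomes one violation at the
configured level.
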