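# Methods

This note records what the toolkit computes, the assumptions baked into each
operation, and the design choices made where more than one reading was
defensible. It states no empirical result that the test suite does not itself
compute.

## The data model and its fragment

Documents are sets of immutable axioms over a deliberately small class-
expression grammar: named classes, existential restrictions `R some B`, and
intersections (flattened, order-free). Logical axioms are subclass,
equivalence (≥ 2 members), disjointness (named members), and subproperty
assertions; entity declarations and annotation assertions carry everything
else. Two axioms are equal iff their logical content *and* their axiom
annotations are equal, so "duplicate axioms" — same logic, different
provenance — coexist in one document until `repair` collapses them.

Anything outside the grammar (unions, complements, universal or cardinality
restrictions, property chains, inverses, ABox assertions) is a loud
parse-time error, never silently dropped. This is the fragment the large OBO
ontologies effectively live in (OWL 2 EL plus disjointness), and it is what
makes polynomial-time, dependency-free reasoning possible.

## Reasoning

`classify` normalizes all logical axioms into the four standard EL normal
forms (A ⊑ B; A₁ ⊓ A₂ ⊑ B; A ⊑ ∃R.B; ∃R.B ⊑ A), minting auxiliary names for
complex subexpressions deterministically (a SHA-1 of the expression's
canonical rendering, so repeated runs and processes agree), and saturates
with the usual completion rules to a fixpoint. Disjointness compiles to
`B ⊓ C ⊑ ⊥`. Soundness and completeness for named-class subsumption in this
fragment follow from the standard completion-rule argument; the test suite
additionally cross-checks the classifier against an *independent* exhaustive
closure oracle (expression-level structural rules run to fixpoint — cubic,
fine for a dozen classes) on hundreds of seeded random ontologies.

Choices worth knowing:

* There is no ABox, so an ontology is always consistent; *incoherence* means
  unsatisfiable classes, and `reason` halts on it listing them.
* Subproperty axioms are carried through every operation but do **not**
  participate in existential subsumption (`R ⊑ S` does not make
  `∃R.B ⊑ ∃S.B`). This keeps the completion rules minimal; the axioms are
  preserved so a richer reasoner could use them.
* `reason` asserts one `SubClassOf(named, named)` axiom per direct inferred
  edge, for every member of an equivalence group, and never asserts
  `owl:Thing` as a superclass. Unsatisfiable classes are grouped into a
  single taxonomy node (they are all equivalent to `owl:Nothing`).
* Entailment queries (`is_entailed`) support subclass axioms only and work by
  naming both sides with fresh definitional auxiliaries — a conservative
  extension — and re-saturating.

## relax / reduce / materialize

`relax` asserts each top-level conjunct of every equivalence definition as a
subclass axiom (both directions for named≡named). It never recurses into
nested intersections inside fillers. Every added axiom is entailed by the
input (checked against the oracle in tests).

`reduce` removes redundant named-named subclass axioms. Redundancy is judged
against the **asserted named-subclass graph**: an edge is removed iff the
remaining asserted edges still connect its endpoints (self-references are
tautologies and removed outright). Candidates are processed greedily in
lexicographic (sub IRI, sup IRI) order with re-checking, so interacting
redundancies resolve deterministically. We deliberately do *not* use full
entailment here: an `A ⊑ B` whose only support is A's equivalence definition
is exactly the navigability axiom `relax` just asserted, and an
entailment-based reduce would always delete it again, making the standard
relax→reduce release sequence a no-op. Under the graph reading, reduce is
conservative by construction, idempotent, and removes duplicates and
transitive shortcuts — which is the documented purpose of running it after
relax.

`materialize` asserts `A ⊑ R some B` for entailed most-specific named
fillers, read off the saturation's canonical model (an R-successor of A whose
label set contains B witnesses the entailment). "Most-specific" keeps a
filler unless a strictly more specific entailed filler exists; among
equivalent fillers the lexicographically least IRI is kept. Only named
fillers are materialized.

## Module extraction

MIREOT copies the requested bottom terms and their ancestors along asserted
named subclass edges, stopping at (and including) any top terms; each
retained class keeps its declaration, label, definition, and the retained
`is_a` edges. Additional annotation properties can be requested explicitly.

TOP/BOT/STAR are syntactic locality modules: an axiom is local when replacing
out-of-signature symbols by ⊥ (BOT) or ⊤ (TOP) turns it into a tautology;
non-local axioms join the module and grow the signature until a fixpoint.
STAR alternates ⊥- and ⊤-extraction to a fixpoint and is therefore a subset
of both. Declarations and annotations of module entities travel with the
module. The locality test gives the usual guarantee: a ⊥-module preserves all
subsumptions over the seed signature (oracle-checked in tests).

`--annotate-with-source` adds one provenance annotation per declared entity;
the property defaults to `rdfs:isDefinedBy` and is configurable, since no
standard fixes it.

## remove / filter

Both commands share one selection predicate — an axiom of a selected type
whose signature intersects the entity set — with `remove` deleting exactly
those axioms and `filter` copying exactly those axioms, so the two outputs
partition the input's axioms of the selected types. Declarations are the one
carve-out: `remove` keeps a selected declaration while the entity is still
referenced elsewhere, and `filter` adds the declarations its kept axioms
need. Entity selectors (`self`, `ancestors`, `descendants`, annotation
match with optional regex, entity type) apply left-to-right; ancestors and
descendants walk asserted named subclass edges only.

## SPARQL

No host RDF stack is assumed: the engine is a small SPARQL 1.1 subset
(SELECT/ASK/CONSTRUCT/UPDATE; basic graph patterns, OPTIONAL, UNION, GRAPH,
FILTER with [NOT] EXISTS; BOUND/REGEX/STR/LANG/DATATYPE/isIRI/isBlank/
isLiteral/CONTAINS/STRSTARTS/STRENDS/UCASE/LCASE/STRLEN; comparison and
boolean operators) evaluated over the document's RDF view. SELECT rows are
always sorted by their rendered cells, so results are deterministic;
`ORDER BY`/`LIMIT` clauses are accepted and ignored. With `--use-graphs`,
every ontology in the import closure becomes a named graph keyed by its
ontology IRI and the default graph is their union. `verify` exits 0 iff every
SELECT returns zero rows and dumps offending rows as RFC 4180 CSV (UTF-8,
header always present); a malformed query is a usage error (exit 2), not a
violation.

## The RDF mapping and serialization

The document↔graph mapping follows the standard OWL-to-RDF patterns:
restrictions and intersections are blank nodes, n-ary disjointness uses
`owl:AllDisjointClasses`, axiom annotations use the `owl:Axiom` reification
pattern. Blank node labels are minted in sorted-axiom order and triples are
written sorted, so serialization is a pure function of the document — no
timestamps, no ordering nondeterminism; byte-identical files on every run.
Reading is strict: every triple must be accounted for, and recognized but
unsupported vocabulary raises an error naming the construct.

Two representational limits are inherent to the standard mapping and
documented rather than papered over: an equivalence axiom with more than two
members serializes as pairwise triples and reads back as pairwise axioms
(the generator and round-trip guarantees therefore use two-member
equivalences), and a document holding both a bare axiom and an annotated
duplicate of it cannot be distinguished in RDF (on read, the bare copy is
suppressed when reification blocks exist; the generator gives both duplicate
copies annotations so round trips stay exact).

## OBO flat file 1.4

The OBO-expressible subset is: class/property declarations (annotation
properties via `is_metadata_tag`), `name`, `def` (with its xref list as axiom
annotations), `subset`, `xref`, `is_a` between named classes, `relationship`
for named existentials, `equivalent_to` and `intersection_of` definitions,
`is_obsolete`, and `replaced_by` — the tags the release workflows here touch.
An axiom counts as expressible only when its subject term is *declared*
(a stanza implies a declaration on read, so undeclared subjects would not
round-trip); only plain literals survive OBO tag syntax, so typed or
language-tagged values are non-expressible, as are axiom annotations outside
def-xrefs, disjointness, and subproperty axioms. Conversion to OBO is lossy
by default (the dropped complement is exactly the non-expressible set) and
strict mode turns the drop into an error listing the offenders. Identifier
translation uses the standard rule `X:123 ↔ .../obo/X_123`.

## QC report

The default battery: ERROR = missing_label, duplicate_label,
duplicate_definition, multiple_definitions; WARN = equivalent_class_pair
(taxonomy-driven, so *inferred* equivalences count), self_reference,
trailing_whitespace, invalid_xref_syntax, missing_ontology_license,
missing_ontology_title; INFO = definition_format (start uppercase, end with a
period), missing_definition. Checks are SPARQL SELECTs binding `?subject`
(optionally `?property`, `?value`); duplicate-style checks report one row per
unordered pair (the lexicographically smaller subject). The xref syntax rule
is `PREFIX:LOCAL`, nonempty parts, no whitespace or extra colons. Profiles
override levels (`LEVEL<TAB>name`), exclude checks (`EXCLUDE<TAB>name`), or
add custom SPARQL checks (`LEVEL<TAB>name<TAB>query-path`). `fail_on`
compares against the severity order ERROR > WARN > INFO; `none` never fails.
Annotation property IRIs (label, definition, xref, subset, deprecation,
replacement) default to the OBO community's standard properties.

`repair` fixes the two mechanical problems: duplicate axioms are collapsed to
one axiom carrying the union of the annotation sets, and logical-axiom
references to deprecated classes with a replacement annotation are rewritten
to the replacement, following chains transitively and raising on cycles.
Rewrites that create self-subsumptions drop them; annotations on the
deprecated term itself are retained.

## Templates

Template tables carry human headers in row 1 (ignored), template strings in
row 2, and data from row 3. The supported strings are `ID`, `LABEL`, `TYPE`,
`A <property>`, `SC %`, `SC <R> some %`, `EC %`, `EC <R> some %`; cells are
CURIEs/IRIs, never labels, and anything else is rejected loudly —
predictable behavior was preferred over silent partial support of a larger
grammar. Expansion is deterministic and row-order independent at the
axiom-set level.

## The synthetic world

The fixture generator emulates the shape of a curated OBO-style ontology: a
rooted DAG (each class picks 1–2 parents among earlier classes), unique
labels, definitions that satisfy the formatting convention, xrefs, ontology
title and license, genus-differentia definitions `C ≡ P ⊓ ∃R.F` on a
configurable fraction of classes (default 0.3 — roughly the density of
logical definitions in mid-size OBO ontologies), optional import chains, and
an injected violation census. Default sizes (20 classes, 2 properties) keep
the exhaustive oracle fast while exercising every code path; everything
derives from one integer seed and serializes byte-identically.

The ledger shipped with each fixture is computed by independent algorithms —
the expression-closure oracle and plain graph reachability (networkx) — never
by the modules under test. Injections are placed on disjoint victim classes
so censuses never interact; the equivalence-pair census is taken from the
oracle, since colliding random definitions can legitimately create inferred
equivalences beyond the injected ones.

What a green test does *not* establish: fixtures are not statistically
realistic ontologies (no term-name realism, no OBO ID policies, no deep
multiple inheritance, no property hierarchies in definitions), so performance
and QC behavior on a real 50 000-term ontology is out of scope here.

## Known limitations

* EL fragment only; no HermiT-parity OWL-DL reasoning. Richer axioms are
  rejected at parse time by design.
* Subproperty axioms do not feed existential subsumption (above).
* Equivalence axioms with > 2 members split pairwise through RDF.
* `verify`/`query` support the SPARQL subset above — no property paths,
  BIND, aggregates, or federation.
* No network access anywhere; imports resolve only through a local catalog.
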