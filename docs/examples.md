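# Worked example: a release workflow

Every command line below is executed verbatim by the integration tests
(`tests/test_docs_examples.py`) in a scratch directory, with the declared
exit codes checked. Lines ending in `# exit: N` are expected to exit with
status N; all others must exit 0.

First, a reproducible input ontology. The `fixtures` command turns a spec
into a Turtle file, an OBO rendering, an import chain with a catalog, and a
ground-truth ledger. Save this as `spec.yaml`:

```yaml
n_classes: 25
n_properties: 2
p_existential: 0.4
import_depth: 1
seed: 2026
```

Then run the workflow:

```sh
owlkit fixtures --spec spec.yaml --out fx
owlkit verify --input fx/fixture.ttl --queries queries/duplicate-label.rq --output-dir reports
owlkit extract --input fx/fixture.ttl --method bot --term fix:C0025 --annotate-with-source true --output imports/module.ttl
owlkit --catalog fx/catalog.tsv merge --input fx/fixture.ttl reason relax reduce annotate --version-iri http://example.org/fix/2026/release.owl --output release.ttl convert --output release.obo
owlkit report --input release.ttl --output reports/release-report.tsv
owlkit diff --left fx/fixture.ttl --right release.ttl --output reports/release-diff.txt
owlkit query --input release.ttl --query queries/labels.rq reports/labels.csv
```

The chained `merge … reason relax reduce annotate … convert` line is the
release product build: merge the import closure, halt unless the ontology is
coherent, assert the inferred direct superclasses, make definitions navigable,
drop redundant edges, stamp the version IRI, and emit both release formats —
all without serializing between steps.

The verify query used above (`queries/duplicate-label.rq`) selects offending
rows, so an empty result means a passing check:

```sparql
PREFIX rdfs: <http://www.w3.org/2000/01/rdf-schema#>
SELECT ?subject ?other WHERE {
  ?subject rdfs:label ?label .
  ?other rdfs:label ?label .
  FILTER(STR(?subject) < STR(?other))
}
```

And `queries/labels.rq` is the classic release report, a table of terms and
labels:

```sparql
PREFIX rdfs: <http://www.w3.org/2000/01/rdf-schema#>
PREFIX owl: <http://www.w3.org/2002/07/owl#>
SELECT ?term ?label WHERE {
  ?term a owl:Class .
  ?term rdfs:label ?label .
  FILTER(isIRI(?term))
}
```

A failing QC gate stops a pipeline. Injecting a violation census into the
fixture and re-running report demonstrates the non-zero exit (`spec-dirty.yaml`
is `spec.yaml` plus a `violation_census: {missing_label: 2}` entry):

```sh
owlkit fixtures --spec spec-dirty.yaml --out fx-dirty
owlkit report --input fx-dirty/fixture.ttl --output reports/dirty.tsv  # exit: 1
owlkit report --input fx-dirty/fixture.ttl --fail-on none --output reports/dirty-ok.tsv
```

Templated term generation plugs into the same chain — a table becomes a
module, which merges into the editors' file (`terms.tsv` is shown in the
test):

```sh
owlkit template --template terms.tsv --prefix "fix: http://example.org/fix#" --output template-module.ttl
owlkit merge --input release.ttl --input template-module.ttl reason --output merged-release.ttl
```
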