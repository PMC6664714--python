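"""Shared helpers for the test suite."""

from owlkit.model import (
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

EX = "http://example.org/t#"


def iri(name: str) -> Identifier:
    return Identifier(EX + name)


def N(name) -> Named:
    return Named(name if isinstance(name, Identifier) else iri(name))


def sub(a, b) -> SubClassOf:
    return SubClassOf(N(a), N(b))


def doc_of(*axioms, **kwargs) -> OntologyDocument:
    d = OntologyDocument(prefixes={"t": EX}, **kwargs)
    d.axioms = set(axioms)
    return d
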