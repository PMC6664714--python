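"""RDF/XML reader and writer (subset).

Reads the common RDF/XML shapes: `rdf:Description` and typed node elements,
`rdf:about`/`rdf:resource`/`rdf:nodeID`, nested node elements, literal
property elements with `rdf:datatype`/`xml:lang`, and
`rdf:parseType="Collection"`. The writer emits one sorted
`rdf:Description` block per subject, which keeps serialization
byte-deterministic.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from typing import Dict, List, Optional, Tuple
from xml.sax.saxutils import escape, quoteattr

from . import vocab
from .errors import ParseError
from .model import Identifier, Literal, contract_iri
from .rdf import BNode, Graph, Object

_RDF_NS = "{" + vocab.RDF + "}"
_XML_LANG = "{http://www.w3.org/XML/1998/namespace}lang"


def _tag_iri(tag: str) -> str:
    if not tag.startswith("{"):
        raise ParseError(f"unqualified element {tag!r} in RDF/XML")
    ns, local = tag[1:].split("}", 1)
    return ns + local


class _RdfXmlReader:
    def __init__(self, path=None):
        self.graph = Graph()
        self._n = 0
        self.path = path

    def _fresh(self) -> BNode:
        self._n += 1
        return BNode(f"gen{self._n}")

    def read(self, text: str) -> Graph:
        try:
            root = ET.fromstring(text)
        except ET.ParseError as exc:
            raise ParseError(f"XML syntax error: {exc}", self.path) from exc
        if _tag_iri(root.tag) != vocab.RDF + "RDF":
            # a single node element document
            self._node(root)
            return self.graph
        for child in root:
            self._node(child)
        return self.graph

    def _subject_of(self, elem) -> Object:
        about = elem.get(_RDF_NS + "about")
        node_id = elem.get(_RDF_NS + "nodeID")
        if about is not None:
            return Identifier(about)
        if node_id is not None:
            return BNode(node_id)
        return self._fresh()

    def _node(self, elem) -> Object:
        subject = self._subject_of(elem)
        tag = _tag_iri(elem.tag)
        if tag != vocab.RDF + "Description":
            self.graph.add((subject, Identifier(vocab.RDF_TYPE), Identifier(tag)))
        for attr, value in elem.attrib.items():
            if attr.startswith(_RDF_NS) or attr == _XML_LANG:
                continue
            self.graph.add((subject, Identifier(_tag_iri(attr)), Literal(value)))
        for prop in elem:
            self._property(subject, prop)
        return subject

    def _property(self, subject, prop):
        pred = Identifier(_tag_iri(prop.tag))
        resource = prop.get(_RDF_NS + "resource")
        node_id = prop.get(_RDF_NS + "nodeID")
        parse_type = prop.get(_RDF_NS + "parseType")
        datatype = prop.get(_RDF_NS + "datatype")
        lang = prop.get(_XML_LANG)
        children = list(prop)
        if resource is not None:
            self.graph.add((subject, pred, Identifier(resource)))
        elif node_id is not None:
            self.graph.add((subject, pred, BNode(node_id)))
        elif parse_type == "Collection":
            items = [self._node(c) for c in children]
            head: Object = Identifier(vocab.RDF_NIL)
            for item in reversed(items):
                cons = self._fresh()
                self.graph.add((cons, Identifier(vocab.RDF_FIRST), item))
                self.graph.add((cons, Identifier(vocab.RDF_REST), head))
                head = cons
            self.graph.add((subject, pred, head))
        elif parse_type == "Resource":
            inner = self._fresh()
            self.graph.add((subject, pred, inner))
            for p in children:
                self._property(inner, p)
        elif children:
            if len(children) != 1:
                raise ParseError("property element with multiple child nodes", self.path)
            self.graph.add((subject, pred, self._node(children[0])))
        else:
            text = prop.text or ""
            self.graph.add((subject, pred, Literal(text, datatype=datatype, lang=lang)))


def parse_rdfxml(text: str, path=None) -> Graph:
    return _RdfXmlReader(path).read(text)


def _split_iri(iri: str) -> Tuple[str, str]:
    for sep in ("#", "/"):
        idx = iri.rfind(sep)
        if idx > 0 and idx < len(iri) - 1:
            local = iri[idx + 1 :]
            if local and (local[0].isalpha() or local[0] == "_") and all(
                c.isalnum() or c in "_.-" for c in local
            ):
                return iri[: idx + 1], local
    raise ValueError(iri)


def write_rdfxml(graph: Graph, prefixes: Dict[str, str]) -> str:
    """Deterministic RDF/XML: sorted subjects, one Description block each."""
    # namespace table: declared prefixes plus autogenerated ones for predicates
    ns_to_prefix: Dict[str, str] = {}
    for prefix, ns in sorted(prefixes.items()):
        ns_to_prefix.setdefault(ns, prefix)
    auto = 0
    preds = sorted({t[1].iri for t in graph})
    for pred in preds:
        try:
            ns, _local = _split_iri(pred)
        except ValueError as exc:
            raise ParseError(f"predicate IRI not QName-splittable: {pred}") from exc
        if ns not in ns_to_prefix:
            auto += 1
            ns_to_prefix[ns] = f"ns{auto}"

    def qname(iri: str) -> str:
        ns, local = _split_iri(iri)
        return f"{ns_to_prefix[ns]}:{local}"

    lines = ['<?xml version="1.0" encoding="UTF-8"?>']
    decls = "".join(
        f'\n    xmlns:{p}={quoteattr(ns)}' for ns, p in sorted(ns_to_prefix.items(), key=lambda kv: kv[1])
    )
    lines.append(f"<rdf:RDF{decls}>")

    by_subject: Dict[Object, List] = {}
    for t in graph.sorted_triples():
        by_subject.setdefault(t[0], []).append(t)

    def subject_key(s):
        return (isinstance(s, BNode), str(s))

    for s in sorted(by_subject, key=subject_key):
        if isinstance(s, BNode):
            lines.append(f"  <rdf:Description rdf:nodeID={quoteattr(s.id)}>")
        else:
            lines.append(f"  <rdf:Description rdf:about={quoteattr(s.iri)}>")
        for _s, p, o in by_subject[s]:
            pq = qname(p.iri)
            if isinstance(o, Identifier):
                lines.append(f"    <{pq} rdf:resource={quoteattr(o.iri)}/>")
            elif isinstance(o, BNode):
                lines.append(f"    <{pq} rdf:nodeID={quoteattr(o.id)}/>")
            else:
                attrs = ""
                if o.lang:
                    attrs = f" xml:lang={quoteattr(o.lang)}"
                elif o.datatype and o.datatype != vocab.XSD_STRING:
                    attrs = f" rdf:datatype={quoteattr(o.datatype)}"
                lines.append(f"    <{pq}{attrs}>{escape(o.lexical)}</{pq}>")
        lines.append("  </rdf:Description>")
    lines.append("</rdf:RDF>")
    return "\n".join(lines) + "\n"
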