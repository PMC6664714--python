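"""Reading and writing ontology documents, plus catalog-based import
resolution.

Formats: Turtle (``.ttl``), RDF/XML (``.owl``), OBO flat file 1.4 (``.obo``).
The format is inferred from the extension unless given explicitly; content is
never sniffed. Serialization is byte-deterministic: the same document always
produces the same file. There is no network retrieval anywhere — imports
resolve only through a local catalog.
"""

from __future__ import annotations

import os
import xml.etree.ElementTree as ET
from typing import Dict, List, Optional, Set

from . import vocab
from .errors import ConfigurationError, UnresolvedImportError, UsageError
from .mapping import doc_to_graph, graph_to_doc
from .model import Identifier, OntologyDocument
from .obo import parse_obo, write_obo
from .rdfxml import parse_rdfxml, write_rdfxml
from .turtle import parse_turtle, write_turtle

FORMATS = ("turtle", "rdfxml", "obo")

_EXTENSIONS = {".ttl": "turtle", ".owl": "rdfxml", ".rdf": "rdfxml", ".obo": "obo"}


def format_for_path(path: str, explicit: Optional[str] = None) -> str:
    if explicit is not None:
        if explicit not in FORMATS:
            raise UsageError(f"unknown format {explicit!r}; supported: {', '.join(FORMATS)}")
        return explicit
    ext = os.path.splitext(str(path))[1].lower()
    if ext not in _EXTENSIONS:
        raise UsageError(f"cannot infer format from extension {ext!r}; pass an explicit format")
    return _EXTENSIONS[ext]


def read_document(path, format: Optional[str] = None) -> OntologyDocument:
    fmt = format_for_path(path, format)
    with open(path, "r", encoding="utf-8") as handle:
        text = handle.read()
    if fmt == "obo":
        return parse_obo(text, path=str(path))
    if fmt == "turtle":
        graph, prefixes = parse_turtle(text, path=str(path))
        merged = dict(vocab.DEFAULT_PREFIXES)
        merged.update(prefixes)
        return graph_to_doc(graph, merged, path=str(path))
    graph = parse_rdfxml(text, path=str(path))
    return graph_to_doc(graph, dict(vocab.DEFAULT_PREFIXES), path=str(path))


def serialize_document(doc: OntologyDocument, format: str, strict: bool = False) -> str:
    if format == "obo":
        return write_obo(doc, strict=strict)
    prefixes = dict(vocab.DEFAULT_PREFIXES)
    prefixes.update(doc.prefixes)
    graph = doc_to_graph(doc)
    if format == "turtle":
        return write_turtle(graph, prefixes)
    if format == "rdfxml":
        return write_rdfxml(graph, prefixes)
    raise UsageError(f"unknown format {format!r}")


def write_document(doc: OntologyDocument, path, format: Optional[str] = None, strict: bool = False) -> None:
    fmt = format_for_path(path, format)
    text = serialize_document(doc, fmt, strict=strict)
    with open(path, "w", encoding="utf-8", newline="\n") as handle:
        handle.write(text)


# ---------------------------------------------------------------------------
# catalogs and import resolution


class Catalog:
    """Maps ontology IRIs to local file paths. Lookups on unmapped IRIs are
    errors; nothing is ever fetched from the network."""

    def __init__(self, mapping: Optional[Dict[str, str]] = None):
        self.mapping: Dict[str, str] = dict(mapping or {})

    def resolve(self, iri: Identifier) -> str:
        path = self.mapping.get(iri.iri)
        if path is None:
            raise UnresolvedImportError(iri.iri)
        return path

    def add(self, iri: str, path: str) -> None:
        self.mapping[iri] = path


def load_catalog(path) -> Catalog:
    """Load an XML catalog (``<uri name=... uri=...>`` entries) or a simple
    two-column TSV (``iri<TAB>path``). Relative paths resolve against the
    catalog file's directory."""
    base = os.path.dirname(os.path.abspath(str(path)))
    catalog = Catalog()
    text = open(path, "r", encoding="utf-8").read()
    if str(path).endswith(".xml") or text.lstrip().startswith("<"):
        root = ET.fromstring(text)
        for elem in root.iter():
            if elem.tag.endswith("uri"):
                name, uri = elem.get("name"), elem.get("uri")
                if name and uri:
                    catalog.add(name, os.path.normpath(os.path.join(base, uri)))
    else:
        for lineno, line in enumerate(text.splitlines(), start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ConfigurationError(f"{path}:{lineno}: catalog lines are iri<TAB>path")
            catalog.add(parts[0], os.path.normpath(os.path.join(base, parts[1])))
    return catalog


def resolve_imports(doc: OntologyDocument, catalog: Optional[Catalog]) -> List[OntologyDocument]:
    """The import closure in depth-first, declaration order; each ontology is
    loaded exactly once and cycles are broken on revisit."""
    if not doc.imports:
        return []
    if catalog is None:
        raise UnresolvedImportError(doc.imports[0].iri)
    closure: List[OntologyDocument] = []
    visited: Set[str] = set()
    if doc.ontology_iri is not None:
        visited.add(doc.ontology_iri.iri)

    def visit(d: OntologyDocument):
        for imp in d.imports:
            if imp.iri in visited:
                continue  # revisit: already loaded or a cycle back to a parent
            visited.add(imp.iri)
            loaded = read_document(catalog.resolve(imp))
            closure.append(loaded)
            visit(loaded)

    visit(doc)
    return closure
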