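"""Turtle reader and writer over the internal triple store.

The reader covers the Turtle constructs OWL documents actually use: prefix
directives, prefixed names, IRIs, typed/tagged literals, blank-node property
lists ``[...]``, collections ``(...)``, the ``a`` keyword, and object/verb
lists. The writer is deliberately plain — one triple per line, sorted — so
output is byte-deterministic.
"""

from __future__ import annotations

import re
from typing import Dict, List, Optional, Tuple

from . import vocab
from .errors import ParseError
from .model import Identifier, Literal, contract_iri
from .rdf import BNode, Graph, Object, render_term

_TOKEN_RE = re.compile(
    r"""
      (?P<WS>\s+|\#[^\n]*)
    | (?P<IRIREF><[^<>"{}|^`\\\s]*>)
    | (?P<STRING>"(?:[^"\\\n]|\\.)*")
    | (?P<PREFIX_KW>@prefix|PREFIX)
    | (?P<BASE_KW>@base|BASE)
    | (?P<LANGTAG>@[A-Za-z]+(?:-[A-Za-z0-9]+)*)
    | (?P<DTYPE>\^\^)
    | (?P<BLANK>_:[A-Za-z0-9_.-]+)
    | (?P<PNAME>[A-Za-z0-9_.-]*:[A-Za-z0-9_.%-]*)
    | (?P<NUMBER>[+-]?\d+(?:\.\d+)?(?:[eE][+-]?\d+)?)
    | (?P<BOOL>true|false)
    | (?P<A>\ba\b)
    | (?P<PUNCT>[.;,\[\]()])
    """,
    re.VERBOSE,
)

_ESCAPES = {"t": "\t", "n": "\n", "r": "\r", "b": "\b", "f": "\f", '"': '"', "'": "'", "\\": "\\"}


def _unescape(s: str, path, line) -> str:
    out = []
    i = 0
    while i < len(s):
        c = s[i]
        if c != "\\":
            out.append(c)
            i += 1
            continue
        if i + 1 >= len(s):
            raise ParseError("dangling escape in literal", path, line)
        e = s[i + 1]
        if e in _ESCAPES:
            out.append(_ESCAPES[e])
            i += 2
        elif e == "u":
            out.append(chr(int(s[i + 2 : i + 6], 16)))
            i += 6
        elif e == "U":
            out.append(chr(int(s[i + 2 : i + 10], 16)))
            i += 10
        else:
            raise ParseError(f"bad escape \\{e}", path, line)
    return "".join(out)


def _escape(s: str) -> str:
    return (
        s.replace("\\", "\\\\")
        .replace('"', '\\"')
        .replace("\n", "\\n")
        .replace("\r", "\\r")
        .replace("\t", "\\t")
    )


class _Tokens:
    def __init__(self, text: str, path=None):
        self.path = path
        self.items: List[Tuple[str, str, int]] = []
        line = 1
        pos = 0
        while pos < len(text):
            m = _TOKEN_RE.match(text, pos)
            if not m:
                raise ParseError(f"unexpected character {text[pos]!r}", path, line)
            kind = m.lastgroup
            value = m.group()
            if kind != "WS":
                self.items.append((kind, value, line))
            line += value.count("\n")
            pos = m.end()
        self.i = 0

    def peek(self):
        return self.items[self.i] if self.i < len(self.items) else (None, None, self.items[-1][2] if self.items else 1)

    def next(self):
        tok = self.peek()
        if tok[0] is None:
            raise ParseError("unexpected end of file", self.path, tok[2])
        self.i += 1
        return tok

    def expect(self, kind=None, value=None):
        tok = self.next()
        if (kind and tok[0] != kind) or (value and tok[1] != value):
            raise ParseError(f"expected {value or kind}, got {tok[1]!r}", self.path, tok[2])
        return tok

    @property
    def done(self):
        return self.i >= len(self.items)


class TurtleParser:
    def __init__(self, text: str, path=None):
        self.toks = _Tokens(text, path)
        self.path = path
        self.prefixes: Dict[str, str] = {}
        self.graph = Graph()
        self._bnode_n = 0

    def _fresh_bnode(self) -> BNode:
        self._bnode_n += 1
        return BNode(f"gen{self._bnode_n}")

    def parse(self) -> Tuple[Graph, Dict[str, str]]:
        while not self.toks.done:
            kind, value, line = self.toks.peek()
            if kind == "PREFIX_KW":
                self.toks.next()
                _, pname, pl = self.toks.expect("PNAME")
                if not pname.endswith(":"):
                    raise ParseError("bad prefix declaration", self.path, pl)
                _, iri, _ = self.toks.expect("IRIREF")
                self.prefixes[pname[:-1]] = iri[1:-1]
                if value == "@prefix":
                    self.toks.expect("PUNCT", ".")
            elif kind == "BASE_KW":
                self.toks.next()
                self.toks.expect("IRIREF")
                if value == "@base":
                    self.toks.expect("PUNCT", ".")
            else:
                self._triples()
                self.toks.expect("PUNCT", ".")
        return self.graph, self.prefixes

    def _triples(self):
        kind, value, line = self.toks.peek()
        if kind == "PUNCT" and value == "[":
            subject = self._bnode_property_list()
            k, v, _ = self.toks.peek()
            if not (k == "PUNCT" and v == "."):
                self._predicate_object_list(subject)
        else:
            subject = self._term(subject_position=True)
            self._predicate_object_list(subject)

    def _predicate_object_list(self, subject):
        while True:
            predicate = self._verb()
            while True:
                obj = self._object()
                self.graph.add((subject, predicate, obj))
                k, v, _ = self.toks.peek()
                if k == "PUNCT" and v == ",":
                    self.toks.next()
                    continue
                break
            k, v, _ = self.toks.peek()
            if k == "PUNCT" and v == ";":
                self.toks.next()
                k, v, _ = self.toks.peek()
                if k == "PUNCT" and v in ".]":
                    break  # trailing semicolon
                continue
            break

    def _verb(self) -> Identifier:
        kind, value, line = self.toks.peek()
        if kind == "A":
            self.toks.next()
            return Identifier(vocab.RDF_TYPE)
        term = self._term()
        if not isinstance(term, Identifier):
            raise ParseError("predicate must be an IRI", self.path, line)
        return term

    def _object(self) -> Object:
        kind, value, line = self.toks.peek()
        if kind == "PUNCT" and value == "[":
            return self._bnode_property_list()
        if kind == "PUNCT" and value == "(":
            return self._collection()
        if kind == "STRING":
            return self._literal()
        if kind == "NUMBER":
            self.toks.next()
            dt = vocab.XSD_DECIMAL if ("." in value or "e" in value or "E" in value) else vocab.XSD_INTEGER
            return Literal(value, datatype=dt)
        if kind == "BOOL":
            self.toks.next()
            return Literal(value, datatype=vocab.XSD_BOOLEAN)
        return self._term()

    def _literal(self) -> Literal:
        kind, value, line = self.toks.next()
        lexical = _unescape(value[1:-1], self.path, line)
        k, v, _ = self.toks.peek()
        if k == "LANGTAG":
            self.toks.next()
            return Literal(lexical, lang=v[1:])
        if k == "DTYPE":
            self.toks.next()
            dt = self._term()
            if not isinstance(dt, Identifier):
                raise ParseError("datatype must be an IRI", self.path, line)
            return Literal(lexical, datatype=dt.iri)
        return Literal(lexical)

    def _term(self, subject_position: bool = False):
        kind, value, line = self.toks.next()
        if kind == "IRIREF":
            return Identifier(value[1:-1])
        if kind == "PNAME":
            prefix, local = value.split(":", 1)
            if prefix not in self.prefixes:
                raise ParseError(f"undeclared prefix {prefix!r}", self.path, line)
            return Identifier(self.prefixes[prefix] + _pname_unescape(local))
        if kind == "BLANK":
            return BNode(value[2:])
        raise ParseError(f"unexpected token {value!r}", self.path, line)

    def _bnode_property_list(self) -> BNode:
        self.toks.expect("PUNCT", "[")
        node = self._fresh_bnode()
        k, v, _ = self.toks.peek()
        if not (k == "PUNCT" and v == "]"):
            self._predicate_object_list(node)
        self.toks.expect("PUNCT", "]")
        return node

    def _collection(self):
        self.toks.expect("PUNCT", "(")
        items = []
        while True:
            k, v, _ = self.toks.peek()
            if k == "PUNCT" and v == ")":
                self.toks.next()
                break
            items.append(self._object())
        head: Object = Identifier(vocab.RDF_NIL)
        for item in reversed(items):
            node = self._fresh_bnode()
            self.graph.add((node, Identifier(vocab.RDF_FIRST), item))
            self.graph.add((node, Identifier(vocab.RDF_REST), head))
            head = node
        return head


def _pname_unescape(local: str) -> str:
    return local  # percent sequences pass through untouched


def parse_turtle(text: str, path=None) -> Tuple[Graph, Dict[str, str]]:
    return TurtleParser(text, path).parse()


def _render(term: Object, prefixes: Dict[str, str]) -> str:
    if isinstance(term, Identifier):
        if term.iri == vocab.RDF_TYPE:
            return "a"
        curie = contract_iri(term.iri, prefixes)
        return curie if curie else f"<{term.iri}>"
    if isinstance(term, BNode):
        return f"_:{term.id}"
    out = f'"{_escape(term.lexical)}"'
    if term.lang:
        out += f"@{term.lang}"
    elif term.datatype and term.datatype != vocab.XSD_STRING:
        dt = contract_iri(term.datatype, prefixes)
        out += "^^" + (dt if dt else f"<{term.datatype}>")
    return out


def write_turtle(graph: Graph, prefixes: Dict[str, str]) -> str:
    """Serialize deterministically: prefixes sorted by name, one triple per
    line sorted by subject/predicate/object rendering."""
    lines = [f"@prefix {p}: <{ns}> ." for p, ns in sorted(prefixes.items())]
    if lines:
        lines.append("")
    for s, p, o in graph.sorted_triples():
        lines.append(f"{_render(s, prefixes)} {_render(p, prefixes)} {_render(o, prefixes)} .")
    return "\n".join(lines) + "\n"
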