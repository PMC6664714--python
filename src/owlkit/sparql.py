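"""SPARQL 1.1 subset engine over the document's RDF view.

Supported: SELECT (DISTINCT) / ASK / CONSTRUCT / UPDATE (INSERT DATA, DELETE
DATA, DELETE/INSERT ... WHERE, DELETE WHERE), basic graph patterns, OPTIONAL,
UNION, GRAPH, FILTER with [NOT] EXISTS and the common builtins (BOUND, REGEX,
STR, LANG, DATATYPE, isIRI/isBlank/isLiteral, CONTAINS, STRSTARTS, STRENDS,
UCASE, LCASE), comparison and boolean operators.

Results are deterministic: SELECT rows are sorted by their rendered cells.
The ``verify`` operation exits 0 iff every SELECT returns zero rows; violating
rows are dumped as RFC 4180 CSV, one file per failing query.
"""

from __future__ import annotations

import csv
import io as _io
import os
import re
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple, Union

from . import vocab
from .errors import SparqlParseError, UnresolvedImportError
from .mapping import doc_to_graph, graph_to_doc
from .model import Identifier, Literal, OntologyDocument
from .rdf import BNode, Graph, Object, render_term

# ---------------------------------------------------------------------------
# graph view


@dataclass
class GraphView:
    default_graph: Graph
    named_graphs: Dict[str, Graph] = field(default_factory=dict)


def to_graph_view(doc: OntologyDocument, use_graphs: bool = False, catalog=None) -> GraphView:
    """RDF view of a document. With ``use_graphs`` each ontology in the import
    closure becomes a named graph keyed by its ontology IRI and the default
    graph is the union of all graphs; otherwise the default graph is just the
    document itself and there are no named graphs."""
    base = doc_to_graph(doc)
    if not use_graphs:
        return GraphView(default_graph=base)
    from .io import resolve_imports

    named: Dict[str, Graph] = {}
    if doc.ontology_iri is not None:
        named[doc.ontology_iri.iri] = base
    default = base.copy()
    for imported in resolve_imports(doc, catalog):
        g = doc_to_graph(imported)
        key = imported.ontology_iri.iri if imported.ontology_iri else f"urn:x-owlkit:import-{len(named)}"
        named[key] = g
        default = default.union(g)
    return GraphView(default_graph=default, named_graphs=named)


# ---------------------------------------------------------------------------
# tokenizer


_TOKEN_RE = re.compile(
    r"""
      (?P<WS>\s+|\#[^\n]*)
    | (?P<IRIREF><[^<>"{}|^`\\\s]*>)
    | (?P<STRING>"(?:[^"\\\n]|\\.)*"|'(?:[^'\\\n]|\\.)*')
    | (?P<VAR>[?$][A-Za-z_][A-Za-z0-9_]*)
    | (?P<NUMBER>[+-]?\d+(?:\.\d+)?)
    | (?P<PNAME>[A-Za-z][A-Za-z0-9_.-]*:[A-Za-z0-9_.%-]*|[A-Za-z][A-Za-z0-9_.-]*:)
    | (?P<BLANK>_:[A-Za-z0-9_]+)
    | (?P<KEYWORD>[A-Za-z][A-Za-z_]*)
    | (?P<LANGTAG>@[A-Za-z]+(?:-[A-Za-z0-9]+)*)
    | (?P<OP>\^\^|\|\||&&|!=|<=|>=|[{}().,;*=<>!/\[\]])
    """,
    re.VERBOSE,
)


class _Tokens:
    def __init__(self, text: str, path=None):
        self.path = path
        self.items: List[Tuple[str, str, int]] = []
        line, pos = 1, 0
        while pos < len(text):
            m = _TOKEN_RE.match(text, pos)
            if not m:
                raise SparqlParseError(f"unexpected character {text[pos]!r}", path, line)
            if m.lastgroup != "WS":
                self.items.append((m.lastgroup, m.group(), line))
            line += m.group().count("\n")
            pos = m.end()
        self.i = 0

    def peek(self, ahead: int = 0):
        j = self.i + ahead
        return self.items[j] if j < len(self.items) else (None, "", -1)

    def next(self):
        tok = self.peek()
        if tok[0] is None:
            raise SparqlParseError("unexpected end of query", self.path)
        self.i += 1
        return tok

    def take_keyword(self, word: str) -> bool:
        kind, value, _ = self.peek()
        if kind == "KEYWORD" and value.upper() == word:
            self.next()
            return True
        return False

    def expect_op(self, op: str):
        kind, value, line = self.next()
        if value != op:
            raise SparqlParseError(f"expected {op!r}, got {value!r}", self.path, line)

    @property
    def done(self):
        return self.i >= len(self.items)


# ---------------------------------------------------------------------------
# AST


@dataclass
class Var:
    name: str


Term = Union[Identifier, Literal, BNode, Var]
TriplePattern = Tuple[Term, Term, Term]


@dataclass
class Group:
    elements: List = field(default_factory=list)  # ('bgp', [tp]) | ('filter', expr) | ('optional', Group) | ('union', [Group]) | ('graph', term, Group)


@dataclass
class SelectQuery:
    variables: List[str]  # empty means *
    distinct: bool
    pattern: Group


@dataclass
class AskQuery:
    pattern: Group


@dataclass
class ConstructQuery:
    template: List[TriplePattern]
    pattern: Group


@dataclass
class UpdateOp:
    delete_data: List[TriplePattern] = field(default_factory=list)
    insert_data: List[TriplePattern] = field(default_factory=list)
    delete_template: Optional[List[TriplePattern]] = None
    insert_template: Optional[List[TriplePattern]] = None
    pattern: Optional[Group] = None


class _Parser:
    def __init__(self, text: str, path=None):
        self.toks = _Tokens(text, path)
        self.path = path
        self.prefixes: Dict[str, str] = {}
        self._bnode_n = 0

    # -- entry points -------------------------------------------------------

    def parse_query(self):
        self._prologue()
        kind, value, line = self.toks.peek()
        if kind != "KEYWORD":
            raise SparqlParseError(f"expected query form, got {value!r}", self.path, line)
        form = value.upper()
        if form == "SELECT":
            return self._select()
        if form == "ASK":
            self.toks.next()
            self.toks.take_keyword("WHERE")
            return AskQuery(self._group())
        if form == "CONSTRUCT":
            self.toks.next()
            self.toks.expect_op("{")
            template = self._triples_block(stop="}")
            self.toks.expect_op("}")
            if not self.toks.take_keyword("WHERE"):
                raise SparqlParseError("CONSTRUCT needs WHERE", self.path, line)
            return ConstructQuery(template, self._group())
        raise SparqlParseError(f"unsupported query form {value!r}", self.path, line)

    def parse_update(self) -> List[UpdateOp]:
        ops: List[UpdateOp] = []
        while True:
            self._prologue()
            if self.toks.done:
                break
            ops.append(self._update_op())
            if not self.toks.done:
                kind, value, _ = self.toks.peek()
                if value == ";":
                    self.toks.next()
                    continue
            break
        if not self.toks.done:
            kind, value, line = self.toks.peek()
            raise SparqlParseError(f"trailing tokens at {value!r}", self.path, line)
        return ops

    def _update_op(self) -> UpdateOp:
        kind, value, line = self.toks.next()
        word = value.upper()
        op = UpdateOp()
        if word == "INSERT":
            if self.toks.take_keyword("DATA"):
                op.insert_data = self._quad_data()
                return op
            op.insert_template = self._template_block()
        elif word == "DELETE":
            if self.toks.take_keyword("DATA"):
                op.delete_data = self._quad_data()
                return op
            if self.toks.take_keyword("WHERE"):
                group = self._group()
                bgps = [e for e in group.elements if e[0] == "bgp"]
                op.delete_template = [tp for e in bgps for tp in e[1]]
                op.pattern = group
                return op
            op.delete_template = self._template_block()
            if self.toks.take_keyword("INSERT"):
                op.insert_template = self._template_block()
        else:
            raise SparqlParseError(f"unsupported update form {value!r}", self.path, line)
        if not self.toks.take_keyword("WHERE"):
            raise SparqlParseError("update needs WHERE clause", self.path, line)
        op.pattern = self._group()
        return op

    def _quad_data(self) -> List[TriplePattern]:
        self.toks.expect_op("{")
        triples = self._triples_block(stop="}")
        self.toks.expect_op("}")
        for tp in triples:
            if any(isinstance(t, Var) for t in tp):
                raise SparqlParseError("variables not allowed in DATA block", self.path)
        return triples

    def _template_block(self) -> List[TriplePattern]:
        self.toks.expect_op("{")
        triples = self._triples_block(stop="}")
        self.toks.expect_op("}")
        return triples

    # -- prologue -----------------------------------------------------------

    def _prologue(self):
        while True:
            if self.toks.take_keyword("PREFIX"):
                kind, value, line = self.toks.next()
                if kind != "PNAME" or not value.endswith(":"):
                    raise SparqlParseError("bad PREFIX declaration", self.path, line)
                prefix = value[:-1]
                kind, iri, line = self.toks.next()
                if kind != "IRIREF":
                    raise SparqlParseError("bad PREFIX IRI", self.path, line)
                self.prefixes[prefix] = iri[1:-1]
            elif self.toks.take_keyword("BASE"):
                self.toks.next()
            else:
                return

    # -- select ---------------------------------------------------------------

    def _select(self) -> SelectQuery:
        self.toks.next()  # SELECT
        distinct = self.toks.take_keyword("DISTINCT")
        self.toks.take_keyword("REDUCED")
        variables: List[str] = []
        while True:
            kind, value, line = self.toks.peek()
            if value == "*":
                self.toks.next()
                break
            if kind == "VAR":
                self.toks.next()
                variables.append(value[1:])
                continue
            break
        if not self.toks.take_keyword("WHERE"):
            raise SparqlParseError("SELECT needs WHERE", self.path)
        pattern = self._group()
        # trailing solution modifiers are accepted but ignored (output is
        # always deterministically sorted)
        while not self.toks.done:
            kind, value, line = self.toks.peek()
            if kind == "KEYWORD" and value.upper() in ("ORDER", "LIMIT", "OFFSET", "BY", "ASC", "DESC"):
                self.toks.next()
                continue
            if kind in ("VAR", "NUMBER") or value in ("(", ")"):
                self.toks.next()
                continue
            raise SparqlParseError(f"trailing tokens at {value!r}", self.path, line)
        return SelectQuery(variables, distinct, pattern)

    # -- group graph pattern --------------------------------------------------

    def _group(self) -> Group:
        self.toks.expect_op("{")
        group = Group()
        while True:
            kind, value, line = self.toks.peek()
            if value == "}":
                self.toks.next()
                return group
            if kind == "KEYWORD" and value.upper() == "FILTER":
                self.toks.next()
                group.elements.append(("filter", self._expr_primary_filter()))
            elif kind == "KEYWORD" and value.upper() == "OPTIONAL":
                self.toks.next()
                group.elements.append(("optional", self._group()))
            elif kind == "KEYWORD" and value.upper() == "GRAPH":
                self.toks.next()
                term = self._term()
                group.elements.append(("graph", term, self._group()))
            elif value == "{":
                first = self._group()
                branches = [first]
                while self.toks.take_keyword("UNION"):
                    branches.append(self._group())
                group.elements.append(("union", branches))
            else:
                triples = self._triples_block(stop=None)
                group.elements.append(("bgp", triples))
            kind, value, _ = self.toks.peek()
            if value == ".":
                self.toks.next()

    def _triples_block(self, stop) -> List[TriplePattern]:
        triples: List[TriplePattern] = []
        while True:
            kind, value, _ = self.toks.peek()
            if value in ("}", None) or (
                kind == "KEYWORD" and value.upper() in ("FILTER", "OPTIONAL", "GRAPH", "UNION")
            ) or value == "{":
                return triples
            subject = self._term()
            while True:
                pred = self._verb()
                while True:
                    obj = self._term()
                    triples.append((subject, pred, obj))
                    kind, value, _ = self.toks.peek()
                    if value == ",":
                        self.toks.next()
                        continue
                    break
                kind, value, _ = self.toks.peek()
                if value == ";":
                    self.toks.next()
                    kind, value, _ = self.toks.peek()
                    if value in (".", "}"):
                        break
                    continue
                break
            kind, value, _ = self.toks.peek()
            if value == ".":
                self.toks.next()
                continue
            return triples

    def _verb(self) -> Term:
        kind, value, line = self.toks.peek()
        if kind == "KEYWORD" and value == "a":
            self.toks.next()
            return Identifier(vocab.RDF_TYPE)
        return self._term()

    def _term(self) -> Term:
        kind, value, line = self.toks.next()
        if kind == "VAR":
            return Var(value[1:])
        if kind == "IRIREF":
            return Identifier(value[1:-1])
        if kind == "PNAME":
            prefix, local = value.split(":", 1)
            if prefix not in self.prefixes:
                raise SparqlParseError(f"undeclared prefix {prefix!r}", self.path, line)
            return Identifier(self.prefixes[prefix] + local)
        if kind == "BLANK":
            return Var(f"_bnode_{value[2:]}")
        if kind == "STRING":
            lexical = value[1:-1].replace('\\"', '"').replace("\\'", "'").replace("\\n", "\n").replace("\\\\", "\\")
            nk, nv, _ = self.toks.peek()
            if nk == "LANGTAG":
                self.toks.next()
                return Literal(lexical, lang=nv[1:])
            if nv == "^^":
                self.toks.next()
                dt = self._term()
                return Literal(lexical, datatype=dt.iri)
            return Literal(lexical)
        if kind == "NUMBER":
            dt = vocab.XSD_DECIMAL if "." in value else vocab.XSD_INTEGER
            return Literal(value, datatype=dt)
        if kind == "KEYWORD" and value in ("true", "false"):
            return Literal(value, datatype=vocab.XSD_BOOLEAN)
        raise SparqlParseError(f"unexpected token {value!r}", self.path, line)

    # -- expressions ----------------------------------------------------------

    def _expr_primary_filter(self):
        kind, value, _ = self.toks.peek()
        if kind == "KEYWORD" and value.upper() in ("EXISTS", "NOT"):
            return self._exists()
        self.toks.expect_op("(")
        expr = self._expr()
        self.toks.expect_op(")")
        return expr

    def _exists(self):
        kind, value, line = self.toks.next()
        negate = False
        if value.upper() == "NOT":
            negate = True
            if not self.toks.take_keyword("EXISTS"):
                raise SparqlParseError("expected EXISTS after NOT", self.path, line)
        group = self._group()
        node = ("exists", group)
        return ("!", node) if negate else node

    def _expr(self):
        left = self._expr_and()
        while self.toks.peek()[1] == "||":
            self.toks.next()
            left = ("||", left, self._expr_and())
        return left

    def _expr_and(self):
        left = self._expr_rel()
        while self.toks.peek()[1] == "&&":
            self.toks.next()
            left = ("&&", left, self._expr_rel())
        return left

    def _expr_rel(self):
        left = self._expr_unary()
        kind, value, _ = self.toks.peek()
        if value in ("=", "!=", "<", "<=", ">", ">="):
            self.toks.next()
            return (value, left, self._expr_unary())
        return left

    def _expr_unary(self):
        kind, value, _ = self.toks.peek()
        if value == "!":
            self.toks.next()
            return ("!", self._expr_unary())
        return self._expr_primary()

    _FUNCS = {
        "BOUND", "REGEX", "STR", "LANG", "DATATYPE", "ISIRI", "ISURI", "ISBLANK",
        "ISLITERAL", "CONTAINS", "STRSTARTS", "STRENDS", "UCASE", "LCASE", "STRLEN",
    }

    def _expr_primary(self):
        kind, value, line = self.toks.peek()
        if value == "(":
            self.toks.next()
            expr = self._expr()
            self.toks.expect_op(")")
            return expr
        if kind == "KEYWORD" and value.upper() in ("EXISTS", "NOT"):
            return self._exists()
        if kind == "KEYWORD" and value.upper() in self._FUNCS:
            name = value.upper()
            self.toks.next()
            self.toks.expect_op("(")
            args = [self._expr()]
            while self.toks.peek()[1] == ",":
                self.toks.next()
                args.append(self._expr())
            self.toks.expect_op(")")
            return ("call", name, args)
        return ("term", self._term())


# ---------------------------------------------------------------------------
# evaluation


class _Unbound:
    pass


_UNBOUND = _Unbound()


@dataclass
class ResultTable:
    header: List[str]
    rows: List[Tuple[str, ...]]

    def __len__(self):
        return len(self.rows)


def _render_cell(value) -> str:
    if isinstance(value, Identifier):
        return value.iri
    if isinstance(value, Literal):
        return value.lexical
    if isinstance(value, BNode):
        return f"_:{value.id}"
    return ""


class _Evaluator:
    def __init__(self, view: GraphView):
        self.view = view

    def eval_group(self, group: Group, graph: Graph, bindings: List[dict]) -> List[dict]:
        rows = bindings
        filters = []
        for element in group.elements:
            if element[0] == "filter":
                filters.append(element[1])
            elif element[0] == "bgp":
                for tp in element[1]:
                    rows = self._match(tp, graph, rows)
            elif element[0] == "optional":
                rows = self._optional(element[1], graph, rows)
            elif element[0] == "union":
                merged = []
                for branch in element[1]:
                    merged.extend(self.eval_group(branch, graph, rows))
                rows = merged
            elif element[0] == "graph":
                rows = self._graph(element[1], element[2], rows)
        for expr in filters:
            rows = [row for row in rows if self._truth(expr, row, graph)]
        return rows

    def _match(self, tp: TriplePattern, graph: Graph, rows: List[dict]) -> List[dict]:
        out = []
        for row in rows:
            s, p, o = (self._resolve(t, row) for t in tp)
            cs = None if isinstance(s, Var) else s
            cp = None if isinstance(p, Var) else p
            co = None if isinstance(o, Var) else o
            for ts, tp_, to in graph.triples(cs, cp, co):
                new = dict(row)
                ok = True
                for term, bound in ((s, ts), (p, tp_), (o, to)):
                    if isinstance(term, Var):
                        if term.name in new and new[term.name] != bound:
                            ok = False
                            break
                        new[term.name] = bound
                if ok:
                    out.append(new)
        return out

    def _resolve(self, term: Term, row: dict):
        if isinstance(term, Var) and term.name in row:
            return row[term.name]
        return term

    def _optional(self, group: Group, graph: Graph, rows: List[dict]) -> List[dict]:
        out = []
        for row in rows:
            extended = self.eval_group(group, graph, [row])
            out.extend(extended if extended else [row])
        return out

    def _graph(self, term: Term, group: Group, rows: List[dict]) -> List[dict]:
        out = []
        for row in rows:
            resolved = self._resolve(term, row)
            if isinstance(resolved, Var):
                for iri in sorted(self.view.named_graphs):
                    seeded = dict(row)
                    seeded[resolved.name] = Identifier(iri)
                    out.extend(self.eval_group(group, self.view.named_graphs[iri], [seeded]))
            elif isinstance(resolved, Identifier):
                g = self.view.named_graphs.get(resolved.iri)
                if g is not None:
                    out.extend(self.eval_group(group, g, [row]))
        return out

    # -- expression evaluation ----------------------------------------------

    def _truth(self, expr, row: dict, graph: Graph) -> bool:
        value = self._eval(expr, row, graph)
        if isinstance(value, bool):
            return value
        if isinstance(value, Literal):
            if value.datatype == vocab.XSD_BOOLEAN:
                return value.lexical == "true"
            return bool(value.lexical)
        return False  # unbound or non-boolean → error → false

    def _eval(self, expr, row: dict, graph: Graph):
        op = expr[0]
        if op == "term":
            term = expr[1]
            if isinstance(term, Var):
                return row.get(term.name, _UNBOUND)
            return term
        if op == "exists":
            return bool(self.eval_group(expr[1], graph, [dict(row)]))
        if op == "!":
            return not self._truth(expr[1], row, graph)
        if op == "||":
            return self._truth(expr[1], row, graph) or self._truth(expr[2], row, graph)
        if op == "&&":
            return self._truth(expr[1], row, graph) and self._truth(expr[2], row, graph)
        if op in ("=", "!=", "<", "<=", ">", ">="):
            left = self._eval(expr[1], row, graph)
            right = self._eval(expr[2], row, graph)
            if left is _UNBOUND or right is _UNBOUND:
                return False
            if op == "=":
                return self._cmp_eq(left, right)
            if op == "!=":
                return not self._cmp_eq(left, right)
            lnum, rnum = self._numeric(left), self._numeric(right)
            if lnum is not None and rnum is not None:
                a, b = lnum, rnum
            else:
                a, b = self._string(left), self._string(right)
            return {"<": a < b, "<=": a <= b, ">": a > b, ">=": a >= b}[op]
        if op == "call":
            return self._call(expr[1], expr[2], row, graph)
        raise SparqlParseError(f"cannot evaluate {expr!r}")

    @staticmethod
    def _cmp_eq(left, right) -> bool:
        if isinstance(left, bool) or isinstance(right, bool):
            return left == right
        if isinstance(left, str) or isinstance(right, str):
            return _Evaluator._string(left) == _Evaluator._string(right)
        return left == right

    @staticmethod
    def _numeric(value):
        if isinstance(value, Literal) and value.datatype in (
            vocab.XSD_INTEGER,
            vocab.XSD_DECIMAL,
        ):
            try:
                return float(value.lexical)
            except ValueError:
                return None
        if isinstance(value, (int, float)) and not isinstance(value, bool):
            return float(value)
        return None

    @staticmethod
    def _string(value) -> str:
        if isinstance(value, str):
            return value
        if isinstance(value, Identifier):
            return value.iri
        if isinstance(value, Literal):
            return value.lexical
        if isinstance(value, BNode):
            return f"_:{value.id}"
        return ""

    def _call(self, name: str, args, row: dict, graph: Graph):
        values = [self._eval(a, row, graph) for a in args]
        if name == "BOUND":
            return values[0] is not _UNBOUND
        if any(v is _UNBOUND for v in values):
            return False
        if name == "STR":
            return self._string(values[0])
        if name in ("ISIRI", "ISURI"):
            return isinstance(values[0], Identifier)
        if name == "ISBLANK":
            return isinstance(values[0], BNode)
        if name == "ISLITERAL":
            return isinstance(values[0], Literal)
        if name == "LANG":
            return values[0].lang or "" if isinstance(values[0], Literal) else ""
        if name == "DATATYPE":
            v = values[0]
            if isinstance(v, Literal):
                return Identifier(v.datatype or vocab.XSD_STRING)
            return False
        if name == "REGEX":
            flags = 0
            if len(values) > 2 and "i" in self._string(values[2]):
                flags = re.IGNORECASE
            try:
                return re.search(self._string(values[1]), self._string(values[0]), flags) is not None
            except re.error as exc:
                raise SparqlParseError(f"bad regex: {exc}") from exc
        if name == "CONTAINS":
            return self._string(values[1]) in self._string(values[0])
        if name == "STRSTARTS":
            return self._string(values[0]).startswith(self._string(values[1]))
        if name == "STRENDS":
            return self._string(values[0]).endswith(self._string(values[1]))
        if name == "UCASE":
            return self._string(values[0]).upper()
        if name == "LCASE":
            return self._string(values[0]).lower()
        if name == "STRLEN":
            return float(len(self._string(values[0])))
        raise SparqlParseError(f"unsupported function {name}")


def _collect_vars(group: Group) -> List[str]:
    seen: List[str] = []

    def walk_tp(tp):
        for t in tp:
            if isinstance(t, Var) and not t.name.startswith("_bnode_") and t.name not in seen:
                seen.append(t.name)

    def walk(g: Group):
        for element in g.elements:
            if element[0] == "bgp":
                for tp in element[1]:
                    walk_tp(tp)
            elif element[0] == "optional":
                walk(element[1])
            elif element[0] == "union":
                for branch in element[1]:
                    walk(branch)
            elif element[0] == "graph":
                if isinstance(element[1], Var):
                    seen.append(element[1].name) if element[1].name not in seen else None
                walk(element[2])

    walk(group)
    return seen


# ---------------------------------------------------------------------------
# public operations


def run_select(view: GraphView, query: str, path=None) -> ResultTable:
    parsed = _Parser(query, path).parse_query()
    if not isinstance(parsed, SelectQuery):
        raise SparqlParseError("expected a SELECT query", path)
    rows = _Evaluator(view).eval_group(parsed.pattern, view.default_graph, [{}])
    header = parsed.variables or _collect_vars(parsed.pattern)
    table = []
    for row in rows:
        table.append(tuple(_render_cell(row.get(v, _UNBOUND)) for v in header))
    if parsed.distinct:
        table = list(dict.fromkeys(table))
    table.sort()
    return ResultTable(header=list(header), rows=table)


def run_ask(view: GraphView, query: str, path=None) -> bool:
    parsed = _Parser(query, path).parse_query()
    if not isinstance(parsed, AskQuery):
        raise SparqlParseError("expected an ASK query", path)
    return bool(_Evaluator(view).eval_group(parsed.pattern, view.default_graph, [{}]))


def run_construct(view: GraphView, query: str, path=None) -> Graph:
    parsed = _Parser(query, path).parse_query()
    if not isinstance(parsed, ConstructQuery):
        raise SparqlParseError("expected a CONSTRUCT query", path)
    rows = _Evaluator(view).eval_group(parsed.pattern, view.default_graph, [{}])
    out = Graph()
    bnode_counter = [0]
    for row in rows:
        local: Dict[str, BNode] = {}

        def inst(term):
            if isinstance(term, Var):
                if term.name.startswith("_bnode_"):
                    if term.name not in local:
                        bnode_counter[0] += 1
                        local[term.name] = BNode(f"c{bnode_counter[0]}")
                    return local[term.name]
                return row.get(term.name, _UNBOUND)
            return term

        for tp in parsed.template:
            s, p, o = (inst(t) for t in tp)
            if _UNBOUND in (s, p, o) or isinstance(s, Literal) or not isinstance(p, Identifier):
                continue
            out.add((s, p, o))
    return out


def run_update(doc: OntologyDocument, query: str, path=None) -> OntologyDocument:
    """Apply a SPARQL UPDATE to the document's RDF view and convert the graph
    back into a document (erroring on now-unsupported constructs)."""
    ops = _Parser(query, path).parse_update()
    graph = doc_to_graph(doc)
    view = GraphView(default_graph=graph)
    evaluator = _Evaluator(view)
    for op in ops:
        for tp in op.delete_data:
            graph.discard(tp)  # type: ignore[arg-type]
        for tp in op.insert_data:
            graph.add(tp)  # type: ignore[arg-type]
        if op.pattern is not None:
            rows = evaluator.eval_group(op.pattern, graph, [{}])

            def inst(term, row):
                if isinstance(term, Var):
                    return row.get(term.name, _UNBOUND)
                return term

            pending_del, pending_add = [], []
            for row in rows:
                for tp in op.delete_template or []:
                    t = tuple(inst(x, row) for x in tp)
                    if _UNBOUND not in t:
                        pending_del.append(t)
                for tp in op.insert_template or []:
                    t = tuple(inst(x, row) for x in tp)
                    if _UNBOUND not in t:
                        pending_add.append(t)
            for t in pending_del:
                graph.discard(t)  # type: ignore[arg-type]
            for t in pending_add:
                graph.add(t)  # type: ignore[arg-type]
    prefixes = dict(vocab.DEFAULT_PREFIXES)
    prefixes.update(doc.prefixes)
    return graph_to_doc(graph, prefixes, path=path)


def write_table(table: ResultTable, path, dialect: str = "csv") -> None:
    """RFC 4180 CSV (or TSV), UTF-8, header row always present."""
    with open(path, "w", encoding="utf-8", newline="") as handle:
        if dialect == "tsv":
            writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        else:
            writer = csv.writer(handle, lineterminator="\r\n")
        writer.writerow(table.header)
        writer.writerows(table.rows)


def verify(
    doc: OntologyDocument,
    queries: Sequence[Tuple[str, str]],
    output_dir: Optional[str] = None,
    use_graphs: bool = False,
    catalog=None,
) -> Tuple[int, Dict[str, ResultTable]]:
    """Run violation SELECT queries: exit status 0 iff every query returns
    zero rows. Offending queries' rows are written as CSV into
    ``output_dir``. A query that fails to parse yields status 2 and writes
    nothing."""
    view = to_graph_view(doc, use_graphs=use_graphs, catalog=catalog)
    results: Dict[str, ResultTable] = {}
    tables: List[Tuple[str, ResultTable]] = []
    for name, text in queries:
        tables.append((name, run_select(view, text, path=name)))  # parse errors propagate
    status = 0
    for name, table in tables:
        results[name] = table
        if table.rows:
            status = 1
            if output_dir is not None:
                os.makedirs(output_dir, exist_ok=True)
                stem = os.path.splitext(os.path.basename(name))[0]
                write_table(table, os.path.join(output_dir, stem + ".csv"))
    return status, results
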