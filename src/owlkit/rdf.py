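"""A minimal RDF triple store.

Nodes are :class:`~owlkit.model.Identifier` (IRIs), :class:`BNode`, and
:class:`~owlkit.model.Literal`. The store keeps simple SPO/POS indexes —
documents at desk scale never need more.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Iterator, Optional, Set, Tuple, Union

from .model import Identifier, Literal


@dataclass(frozen=True, order=True)
class BNode:
    id: str

    def __str__(self) -> str:
        return f"_:{self.id}"


Node = Union[Identifier, BNode]
Object = Union[Identifier, BNode, Literal]
Triple = Tuple[Node, Identifier, Object]


def render_term(term: Object) -> str:
    """Deterministic N-Triples-ish rendering used for sorting."""
    if isinstance(term, Identifier):
        return f"<{term.iri}>"
    if isinstance(term, BNode):
        return f"_:{term.id}"
    out = '"' + term.lexical.replace("\\", "\\\\").replace('"', '\\"') + '"'
    if term.lang:
        out += f"@{term.lang}"
    elif term.datatype:
        out += f"^^<{term.datatype}>"
    return out


class Graph:
    def __init__(self, triples: Iterable[Triple] = ()):
        self._triples: Set[Triple] = set()
        self._by_sp: Dict[Tuple[Node, Identifier], Set[Object]] = {}
        self._by_p: Dict[Identifier, Set[Triple]] = {}
        for t in triples:
            self.add(t)

    def __len__(self) -> int:
        return len(self._triples)

    def __iter__(self) -> Iterator[Triple]:
        return iter(self._triples)

    def __contains__(self, triple: Triple) -> bool:
        return triple in self._triples

    def add(self, triple: Triple) -> None:
        if triple in self._triples:
            return
        s, p, o = triple
        self._triples.add(triple)
        self._by_sp.setdefault((s, p), set()).add(o)
        self._by_p.setdefault(p, set()).add(triple)

    def discard(self, triple: Triple) -> None:
        if triple not in self._triples:
            return
        s, p, o = triple
        self._triples.discard(triple)
        self._by_sp[(s, p)].discard(o)
        self._by_p[p].discard(triple)

    def triples(
        self,
        s: Optional[Node] = None,
        p: Optional[Identifier] = None,
        o: Optional[Object] = None,
    ) -> Iterator[Triple]:
        if s is not None and p is not None:
            for obj in self._by_sp.get((s, p), ()):
                if o is None or o == obj:
                    yield (s, p, obj)
            return
        pool = self._by_p.get(p, self._triples) if p is not None else self._triples
        for t in pool:
            if (s is None or t[0] == s) and (o is None or t[2] == o):
                yield t

    def objects(self, s: Node, p: Identifier) -> Iterator[Object]:
        yield from self._by_sp.get((s, p), ())

    def object(self, s: Node, p: Identifier) -> Optional[Object]:
        for o in self._by_sp.get((s, p), ()):
            return o
        return None

    def subjects(self, p: Identifier, o: Optional[Object] = None) -> Iterator[Node]:
        for t in self._by_p.get(p, ()):
            if o is None or t[2] == o:
                yield t[0]

    def sorted_triples(self) -> list:
        return sorted(self._triples, key=lambda t: tuple(render_term(x) for x in t))

    def copy(self) -> "Graph":
        return Graph(self._triples)

    def union(self, other: "Graph") -> "Graph":
        g = self.copy()
        for t in other:
            g.add(t)
        return g
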