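"""Module extraction: MIREOT and syntactic-locality (TOP/BOT/STAR) methods.

MIREOT copies a minimal slice: the requested "bottom" terms, their ancestors
along asserted named subclass edges up to (and including) optional "top"
terms, each retained class's declaration, label and definition, and the
retained is_a edges.

The locality-based methods test each axiom syntactically: out-of-signature
symbols are replaced by ⊥ (BOT) or ⊤ (TOP) and the axiom is dropped when the
replacement makes it a tautology; the signature grows with every kept axiom
until a fixpoint. This is the standard realization of the guarantee that the
module preserves all entailments over the seed signature. STAR alternates ⊥-
and ⊤-extraction to a fixpoint and yields the smallest modules.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import FrozenSet, Iterable, Optional, Set

from . import vocab
from .errors import ConfigurationError, UnknownTermError
from .model import (
    And,
    AnnotationAssertion,
    Axiom,
    ClassExpression,
    Declaration,
    DisjointClasses,
    EquivalentClasses,
    Identifier,
    Named,
    OntologyDocument,
    Some,
    SubClassOf,
    SubPropertyOf,
    axiom_signature,
    is_logical,
    signature_of,
)

SOURCE_PROPERTY = Identifier(vocab.RDFS_IS_DEFINED_BY)


@dataclass
class ExtractRequest:
    method: str  # mireot | top | bot | star
    bottom_terms: FrozenSet[Identifier] = frozenset()
    top_terms: FrozenSet[Identifier] = frozenset()
    seed: FrozenSet[Identifier] = frozenset()
    annotate_with_source: bool = False
    source_iri: Optional[Identifier] = None
    source_property: Identifier = SOURCE_PROPERTY
    # extra annotation properties MIREOT should carry beyond label + definition
    extra_annotation_properties: FrozenSet[Identifier] = frozenset()


def extract(doc: OntologyDocument, req: ExtractRequest) -> OntologyDocument:
    if req.method == "mireot":
        module = extract_mireot(doc, req)
    elif req.method in ("top", "bot", "star"):
        module = extract_slme(doc, req)
    else:
        raise ConfigurationError(f"unknown extraction method {req.method!r}")
    if req.annotate_with_source:
        module = annotate_sources(module, req)
    return module


# ---------------------------------------------------------------------------
# MIREOT


def extract_mireot(doc: OntologyDocument, req: ExtractRequest) -> OntologyDocument:
    if not req.bottom_terms:
        raise ConfigurationError("mireot requires at least one bottom term")
    known = {c for ax in doc.axioms for c in axiom_signature(ax)}
    missing = sorted(t for t in req.bottom_terms if t not in known)
    if missing:
        raise UnknownTermError(missing)

    parents = {}
    for ax in doc.axioms:
        if isinstance(ax, SubClassOf) and isinstance(ax.sub, Named) and isinstance(ax.sup, Named):
            parents.setdefault(ax.sub.cls, set()).add(ax.sup.cls)

    keep: Set[Identifier] = set()
    stack = sorted(req.bottom_terms)
    while stack:
        term = stack.pop()
        if term in keep:
            continue
        keep.add(term)
        if term in req.top_terms:
            continue  # stop at (but include) top terms
        for p in parents.get(term, ()):
            if p.iri != vocab.OWL_THING:
                stack.append(p)

    carried = {Identifier(vocab.RDFS_LABEL), Identifier(vocab.DEFINITION)} | set(
        req.extra_annotation_properties
    )
    module = OntologyDocument(prefixes=dict(doc.prefixes))
    for cls in keep:
        module.axioms.add(Declaration(cls, "class"))
    for ax in doc.axioms:
        if isinstance(ax, SubClassOf) and isinstance(ax.sub, Named) and isinstance(ax.sup, Named):
            if ax.sub.cls in keep and ax.sup.cls in keep and ax.sub.cls not in req.top_terms:
                module.axioms.add(SubClassOf(ax.sub, ax.sup))
        elif isinstance(ax, AnnotationAssertion):
            if ax.subject in keep and ax.property in carried:
                module.axioms.add(ax)
    return module


# ---------------------------------------------------------------------------
# Syntactic locality


def _bot_equivalent(ce: ClassExpression, sig: Set[Identifier]) -> bool:
    """Does ce collapse to ⊥ when out-of-signature symbols are replaced by ⊥?"""
    if isinstance(ce, Named):
        if ce.cls.iri == vocab.OWL_NOTHING:
            return True
        if ce.cls.iri == vocab.OWL_THING:
            return False
        return ce.cls not in sig
    if isinstance(ce, Some):
        return ce.property not in sig or _bot_equivalent(ce.filler, sig)
    return any(_bot_equivalent(op, sig) for op in ce.operands)


def _top_equivalent(ce: ClassExpression, sig: Set[Identifier]) -> bool:
    """Does ce collapse to ⊤ when out-of-signature symbols are replaced by ⊤?"""
    if isinstance(ce, Named):
        if ce.cls.iri == vocab.OWL_THING:
            return True
        if ce.cls.iri == vocab.OWL_NOTHING:
            return False
        return ce.cls not in sig
    if isinstance(ce, Some):
        return ce.property not in sig and _top_equivalent(ce.filler, sig)
    return all(_top_equivalent(op, sig) for op in ce.operands)


def _syntactically_top(ce: ClassExpression) -> bool:
    if isinstance(ce, Named):
        return ce.cls.iri == vocab.OWL_THING
    if isinstance(ce, And):
        return all(_syntactically_top(op) for op in ce.operands)
    return False


def _is_local(ax: Axiom, sig: Set[Identifier], flavor: str) -> bool:
    """Syntactic ⊥- or ⊤-locality of one logical axiom w.r.t. a signature."""
    if flavor == "bot":
        if isinstance(ax, SubClassOf):
            return _bot_equivalent(ax.sub, sig) or _syntactically_top(ax.sup)
        if isinstance(ax, EquivalentClasses):
            return all(_bot_equivalent(m, sig) for m in ax.members)
        if isinstance(ax, DisjointClasses):
            in_sig = [m for m in ax.members if m in sig and m.iri != vocab.OWL_NOTHING]
            return len(in_sig) <= 1
        if isinstance(ax, SubPropertyOf):
            return ax.sub not in sig
    else:
        if isinstance(ax, SubClassOf):
            return _top_equivalent(ax.sup, sig)
        if isinstance(ax, EquivalentClasses):
            return all(_top_equivalent(m, sig) for m in ax.members)
        if isinstance(ax, DisjointClasses):
            return False  # disjointness never becomes a tautology under ⊤
        if isinstance(ax, SubPropertyOf):
            return ax.sup not in sig
    return True  # non-logical axioms carry no entailments


def _locality_module(axioms: Set[Axiom], seed_sig: Set[Identifier], flavor: str) -> Set[Axiom]:
    logical = [ax for ax in axioms if is_logical(ax)]
    sig = set(seed_sig)
    module: Set[Axiom] = set()
    changed = True
    while changed:
        changed = False
        for ax in logical:
            if ax in module:
                continue
            if not _is_local(ax, sig, flavor):
                module.add(ax)
                sig |= axiom_signature(ax)
                changed = True
    return module


def extract_slme(doc: OntologyDocument, req: ExtractRequest) -> OntologyDocument:
    if not req.seed:
        raise ConfigurationError(f"{req.method} extraction requires a seed")
    known = {c for ax in doc.axioms for c in axiom_signature(ax)}
    kept_seed = {t for t in req.seed if t in known}
    if not kept_seed:
        raise UnknownTermError(sorted(req.seed))

    if req.method == "bot":
        module_axioms = _locality_module(doc.axioms, kept_seed, "bot")
    elif req.method == "top":
        module_axioms = _locality_module(doc.axioms, kept_seed, "top")
    else:  # star: alternate ⊥ and ⊤ extraction to a fixpoint
        module_axioms = set(ax for ax in doc.axioms if is_logical(ax))
        flavor = "bot"
        while True:
            nxt = _locality_module(module_axioms, kept_seed, flavor)
            if nxt == module_axioms:
                break
            module_axioms = nxt
            flavor = "top" if flavor == "bot" else "bot"

    module = OntologyDocument(prefixes=dict(doc.prefixes))
    module.axioms = set(module_axioms)
    sig = signature_of(module.axioms)
    entities = sig.all_entities() | kept_seed
    # needed declarations and the entities' annotations travel with the module
    for ax in doc.axioms:
        if isinstance(ax, Declaration) and ax.entity in entities:
            module.axioms.add(ax)
        elif isinstance(ax, AnnotationAssertion) and ax.subject in entities:
            module.axioms.add(ax)
    return module


def annotate_sources(module: OntologyDocument, req: ExtractRequest) -> OntologyDocument:
    """Add one provenance annotation per declared entity naming the ontology
    the term was extracted from. Idempotent."""
    if req.source_iri is None:
        raise ConfigurationError("--annotate-with-source requires a source IRI")
    out = module.copy()
    for ax in sorted(module.axioms, key=lambda a: getattr(a, "entity", Identifier("")).iri):
        if isinstance(ax, Declaration):
            out.axioms.add(
                AnnotationAssertion(ax.entity, req.source_property, req.source_iri)
            )
    return out
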