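"""In-memory triple/graph model and the structural queries the mapper needs.

RDF sources are parsed with :mod:`rdflib` and converted into a small set of
immutable terms (:class:`Iri`, :class:`BlankNodeId`, :class:`LiteralValue`)
plus :class:`Triple` and :class:`RdfGraph`.  The model keeps set semantics
for triples and a prefix -> namespace map taken from the document's declared
prefixes.

Determinism conventions used throughout the package:

* canonical node order is literals < blank nodes < IRIs, then lexicographic
  within each class (:func:`node_sort_key`);
* every list-returning query is sorted by that order so the emitted JSON is
  reproducible byte-for-byte regardless of parse order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Dict, FrozenSet, List, Optional, Union

import rdflib

from .errors import ConfigError, ContractError, InputError, ParseError

logger = logging.getLogger(__name__)

RDF_NS = "http://www.w3.org/1999/02/22-rdf-syntax-ns#"
RDFS_NS = "http://www.w3.org/2000/01/rdf-schema#"
XSD_NS = "http://www.w3.org/2001/XMLSchema#"

XSD_STRING = XSD_NS + "string"
RDF_LANGSTRING = RDF_NS + "langString"
RDF_TYPE = RDF_NS + "type"
RDF_FIRST = RDF_NS + "first"
RDF_REST = RDF_NS + "rest"
RDF_NIL = RDF_NS + "nil"
RDF_BAG = RDF_NS + "Bag"
RDF_SEQ = RDF_NS + "Seq"
RDF_ALT = RDF_NS + "Alt"
RDFS_CLASS = RDFS_NS + "Class"
RDF_PROPERTY = RDF_NS + "Property"
RDFS_SUBCLASSOF = RDFS_NS + "subClassOf"
RDFS_SUBPROPERTYOF = RDFS_NS + "subPropertyOf"
RDFS_DOMAIN = RDFS_NS + "domain"
RDFS_RANGE = RDFS_NS + "range"


@dataclass(frozen=True)
class Iri:
    """An absolute IRI reference."""

    value: str

    def __post_init__(self) -> None:
        if not self.value:
            raise ContractError("IRI must be a non-empty string")


@dataclass(frozen=True)
class BlankNodeId:
    """A blank node, identified by a label scoped to one graph."""

    label: str

    def __post_init__(self) -> None:
        if not self.label:
            raise ContractError("blank node label must be non-empty")


@dataclass(frozen=True)
class LiteralValue:
    """A literal: lexical form + datatype IRI + optional language tag.

    Plain literals are normalised to ``xsd:string``; language-tagged
    literals always carry the ``rdf:langString`` datatype, so every literal
    has an explicit datatype when it reaches the mapping layer.
    """

    lexical: str
    datatype: Iri = Iri(XSD_STRING)
    language: Optional[str] = None

    def __post_init__(self) -> None:
        if self.language and self.datatype.value != RDF_LANGSTRING:
            object.__setattr__(self, "datatype", Iri(RDF_LANGSTRING))


RdfNode = Union[Iri, BlankNodeId, LiteralValue]


def node_sort_key(node: RdfNode) -> tuple:
    """Canonical total order over nodes: literal < blank < IRI."""
    if isinstance(node, LiteralValue):
        return (0, node.lexical, node.datatype.value, node.language or "")
    if isinstance(node, BlankNodeId):
        return (1, node.label)
    return (2, node.value)


@dataclass(frozen=True)
class Triple:
    """One RDF statement (subject, predicate, object)."""

    subject: RdfNode
    predicate: Iri
    object: RdfNode

    def __post_init__(self) -> None:
        if isinstance(self.subject, LiteralValue):
            raise ContractError("triple subject cannot be a literal")
        if not isinstance(self.predicate, Iri):
            raise ContractError("triple predicate must be an IRI")


class SpecialNodeKind(str, Enum):
    PLAIN = "plain"
    CONTAINER_BAG = "container_bag"
    CONTAINER_SEQ = "container_seq"
    CONTAINER_ALT = "container_alt"
    COLLECTION = "collection"


CONTAINER_CLASS_TO_KIND = {
    RDF_BAG: SpecialNodeKind.CONTAINER_BAG,
    RDF_SEQ: SpecialNodeKind.CONTAINER_SEQ,
    RDF_ALT: SpecialNodeKind.CONTAINER_ALT,
}


@dataclass
class RdfGraph:
    """A finite set of triples plus the document's prefix -> namespace map."""

    triples: FrozenSet[Triple]
    namespaces: Dict[str, str]
    _index: Optional[Dict[RdfNode, List[Triple]]] = field(
        default=None, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        self.triples = frozenset(self.triples)

    def subject_index(self) -> Dict[RdfNode, List[Triple]]:
        """Subject -> sorted outgoing triples, built once and cached."""
        if self._index is None:
            idx: Dict[RdfNode, List[Triple]] = {}
            for t in self.triples:
                idx.setdefault(t.subject, []).append(t)
            for ts in idx.values():
                ts.sort(key=lambda t: (t.predicate.value, node_sort_key(t.object)))
            self._index = idx
        return self._index


def triples_with_subject(graph: RdfGraph, node: RdfNode) -> List[Triple]:
    """All triples whose subject is ``node``, in canonical (predicate, object) order."""
    if isinstance(node, LiteralValue):
        raise ContractError("literals cannot be subjects")
    return list(graph.subject_index().get(node, ()))


def subjects(graph: RdfGraph) -> List[RdfNode]:
    """Distinct top-level subjects in canonical order.

    Blank nodes that occur in object position are excluded: they are inlined
    at each reference site during expansion instead of being emitted as
    top-level resources.  Blank subjects never referenced as objects stay
    top-level so no description is silently dropped.
    """
    object_blanks = {
        t.object for t in graph.triples if isinstance(t.object, BlankNodeId)
    }
    subs = {t.subject for t in graph.triples}
    keep = [
        s
        for s in subs
        if not (isinstance(s, BlankNodeId) and s in object_blanks)
    ]
    return sorted(keep, key=node_sort_key)


def detect_special_node(graph: RdfGraph, node: RdfNode) -> SpecialNodeKind:
    """Classify ``node`` as a container (Bag/Seq/Alt), a collection head, or plain.

    Container typing takes precedence when both patterns are present.
    ``rdf:nil`` counts as an (empty) collection head.
    """
    if isinstance(node, LiteralValue):
        raise ContractError("literals cannot be containers or collections")
    ts = triples_with_subject(graph, node)
    for t in ts:
        if (
            t.predicate.value == RDF_TYPE
            and isinstance(t.object, Iri)
            and t.object.value in CONTAINER_CLASS_TO_KIND
        ):
            return CONTAINER_CLASS_TO_KIND[t.object.value]
    if isinstance(node, Iri) and node.value == RDF_NIL:
        return SpecialNodeKind.COLLECTION
    if any(t.predicate.value == RDF_FIRST for t in ts):
        return SpecialNodeKind.COLLECTION
    return SpecialNodeKind.PLAIN


_EXT_TO_FORMAT = {
    ".rdf": "xml",
    ".xml": "xml",
    ".owl": "xml",
    ".ttl": "turtle",
}

_SYNTAX_TO_FORMAT = {"rdfxml": "xml", "turtle": "turtle"}


def _term_to_node(term) -> RdfNode:
    if isinstance(term, rdflib.Literal):
        if term.language:
            return LiteralValue(str(term), Iri(RDF_LANGSTRING), term.language)
        dt = str(term.datatype) if term.datatype is not None else XSD_STRING
        return LiteralValue(str(term), Iri(dt))
    if isinstance(term, rdflib.BNode):
        return BlankNodeId(str(term))
    return Iri(str(term))


def _node_to_term(node: RdfNode):
    if isinstance(node, LiteralValue):
        if node.language:
            return rdflib.Literal(node.lexical, lang=node.language)
        if node.datatype.value == XSD_STRING:
            return rdflib.Literal(node.lexical)
        return rdflib.Literal(node.lexical, datatype=rdflib.URIRef(node.datatype.value))
    if isinstance(node, BlankNodeId):
        return rdflib.BNode(node.label)
    return rdflib.URIRef(node.value)


def from_rdflib(g: "rdflib.Graph") -> RdfGraph:
    """Convert an rdflib graph into the package's model."""
    triples = frozenset(
        Triple(_term_to_node(s), Iri(str(p)), _term_to_node(o)) for s, p, o in g
    )
    namespaces = {prefix: str(ns) for prefix, ns in g.namespaces()}
    return RdfGraph(triples, namespaces)


def to_rdflib(graph: RdfGraph) -> "rdflib.Graph":
    """Convert the package model back into an rdflib graph (for serialization)."""
    g = rdflib.Graph(bind_namespaces="none")
    for prefix, ns in graph.namespaces.items():
        g.bind(prefix, ns, override=True, replace=True)
    for t in graph.triples:
        g.add((_node_to_term(t.subject), rdflib.URIRef(t.predicate.value), _node_to_term(t.object)))
    return g


def write_rdfxml(graph: RdfGraph, path) -> Path:
    """Serialize a graph as RDF/XML, declaring every namespace of the graph.

    rdflib's RDF/XML serializer only declares prefixes it uses for element
    names (predicates); prefixes that occur solely inside subject/object
    IRIs would be dropped and a later load would lose the CURIE mapping.
    The missing ``xmlns`` declarations are injected into the root element.
    """
    data = to_rdflib(graph).serialize(format="xml")
    start = data.index("<rdf:RDF")
    head_end = data.index(">", start)
    head = data[start:head_end]
    extra = "".join(
        f'\n   xmlns:{prefix}="{ns}"'
        for prefix, ns in sorted(graph.namespaces.items())
        if f"xmlns:{prefix}=" not in head
    )
    data = data[:head_end] + extra + data[head_end:]
    p = Path(path)
    p.write_text(data, encoding="utf-8")
    return p


def load_graph(path, syntax: str = "auto") -> RdfGraph:
    """Parse an RDF/XML or Turtle file into an :class:`RdfGraph`.

    ``syntax="auto"`` selects the parser by extension (.rdf/.xml/.owl are
    RDF/XML, .ttl is Turtle).  The namespace map of the result contains
    exactly the prefixes declared by the document.
    """
    p = Path(path)
    if not p.exists():
        raise InputError(f"input file not found: {p}")
    if syntax == "auto":
        fmt = _EXT_TO_FORMAT.get(p.suffix.lower())
        if fmt is None:
            raise ConfigError(
                f"cannot infer RDF syntax from extension {p.suffix!r} of {p}; "
                "pass syntax='rdfxml' or syntax='turtle'"
            )
    else:
        fmt = _SYNTAX_TO_FORMAT.get(syntax)
        if fmt is None:
            raise ConfigError(f"unknown syntax {syntax!r}")
    g = rdflib.Graph(bind_namespaces="none")
    try:
        g.parse(str(p), format=fmt)
    except Exception as exc:  # rdflib raises parser-specific exceptions
        raise ParseError(f"failed to parse {p} as {fmt}: {exc}") from exc
    return from_rdflib(g)
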