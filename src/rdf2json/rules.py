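"""The ten graph-fragment -> JSON mapping rules.

Each public function is a pure transformation from a piece of an
:class:`~rdf2json.model.RdfGraph` to a JSON value (plain ``dict``/``list``/
``str``; ``dict`` insertion order is the canonical key order).

Value objects come in five mutually exclusive shapes:

* literal-shape        ``{"value", "datatype"[, "lang"]}``
* reference-shape      ``{"rdf:resource": <CURIE or IRI>}``
* nested-shape         a recursively expanded blank-node description
* container-shape      ``{"rdf:type": "rdf:Bag|Seq|Alt", "rdf:_1": ..., ...}``
* collection-shape     ``{"rdf:type": "rdf:List", "items": [...]}``

Blank-node expansion is implemented with an explicit work stack, so graphs
with deeply nested blank nodes (tested to depth 10 000) convert without
exhausting the interpreter stack, and a blank node revisited along one
expansion branch is emitted as a ``{"rdf:nodeID": label}`` back-reference
instead of looping forever.
"""

from __future__ import annotations

import logging
import re
from typing import Dict, FrozenSet, List, Optional, Tuple, Union

from .errors import ContractError
from .model import (
    CONTAINER_CLASS_TO_KIND,
    RDF_FIRST,
    RDF_NIL,
    RDF_NS,
    RDF_REST,
    RDF_TYPE,
    RDFS_DOMAIN,
    RDFS_RANGE,
    RDFS_SUBCLASSOF,
    RDFS_SUBPROPERTYOF,
    BlankNodeId,
    Iri,
    LiteralValue,
    RdfGraph,
    RdfNode,
    SpecialNodeKind,
    detect_special_node,
    node_sort_key,
    triples_with_subject,
)

logger = logging.getLogger(__name__)

JsonValue = Union[dict, list, str]

#: local-name syntax accepted when abbreviating an IRI to a CURIE
_LOCAL_NAME_RE = re.compile(r"^[A-Za-z_][A-Za-z0-9_.\-]*$")

_CONTAINER_KIND_LABEL = {
    SpecialNodeKind.CONTAINER_BAG: "rdf:Bag",
    SpecialNodeKind.CONTAINER_SEQ: "rdf:Seq",
    SpecialNodeKind.CONTAINER_ALT: "rdf:Alt",
}

#: schema predicates and their fixed output keys, in output order
SCHEMA_PREDICATES: List[Tuple[str, str]] = [
    (RDFS_SUBCLASSOF, "rdfs:subClassOf"),
    (RDFS_SUBPROPERTYOF, "rdfs:subPropertyOf"),
    (RDFS_DOMAIN, "rdfs:domain"),
    (RDFS_RANGE, "rdfs:range"),
]
_SCHEMA_SET = {iri for iri, _ in SCHEMA_PREDICATES}


def map_namespaces(ns: Dict[str, str]) -> Dict[str, str]:
    """Namespace map -> root ``"namespaces"`` object, prefixes sorted."""
    return {prefix: ns[prefix] for prefix in sorted(ns)}


def compact_iri(iri: Union[Iri, str], ns: Dict[str, str]) -> str:
    """Abbreviate an IRI to ``prefix:local`` when a declared namespace matches.

    The longest matching namespace wins; ties on length are broken by the
    lexicographically smallest prefix.  If no namespace yields a valid local
    name the full IRI string is returned.
    """
    value = iri.value if isinstance(iri, Iri) else iri
    best: Optional[Tuple[int, str, str]] = None  # (-len(base), prefix, local)
    for prefix, base in ns.items():
        if base and value.startswith(base):
            local = value[len(base):]
            if local and _LOCAL_NAME_RE.match(local):
                cand = (-len(base), prefix, local)
                if best is None or cand < best:
                    best = cand
    if best is None:
        return value
    return f"{best[1]}:{best[2]}"


def map_literal(lit: LiteralValue, ns: Dict[str, str]) -> dict:
    """Literal -> literal-shape value object (lexical form kept as a string)."""
    obj = {"value": lit.lexical, "datatype": compact_iri(lit.datatype, ns)}
    if lit.language:
        obj["lang"] = lit.language
    return obj


def map_reference(target: Iri, ns: Dict[str, str]) -> dict:
    """IRI object -> reference-shape value object."""
    return {"rdf:resource": compact_iri(target, ns)}


def merge_values(values: list):
    """Merge the values of one repeated (subject, predicate) group.

    A single value is returned as-is; two or more become an array in the
    order given (callers supply values in canonical node order).
    """
    if not values:
        raise ContractError("merge_values requires at least one value")
    if len(values) == 1:
        return values[0]
    return list(values)


def _ordinal(pred: Iri) -> Optional[int]:
    """Member index N for an ``rdf:_N`` container-membership predicate."""
    prefix = RDF_NS + "_"
    if pred.value.startswith(prefix) and pred.value[len(prefix):].isdigit():
        return int(pred.value[len(prefix):])
    return None


# ---------------------------------------------------------------------------
# Iterative expansion machine
#
# A task is (node, path, parent, key, kind, with_schema):
#   node        the iri/blank node to materialise
#   path        frozenset of nodes on the current expansion branch
#   parent/key  where to store the result (dict key or list index);
#               placeholders are inserted in final key order first, so the
#               DFS processing order never affects the output key order
#   kind        a SpecialNodeKind to force, or None to auto-detect
#   with_schema True only for top-level resources: rdfs:subClassOf /
#               subPropertyOf / domain / range become plain-string keys
# ---------------------------------------------------------------------------

def _emit_group(graph, ns, values, parent, key, child_path, tasks):
    """Store one predicate group: scalars immediately, blanks as sub-tasks."""

    def one(v, container, slot):
        if isinstance(v, LiteralValue):
            container[slot] = map_literal(v, ns)
        elif isinstance(v, Iri):
            container[slot] = map_reference(v, ns)
        else:
            container[slot] = None
            tasks.append((v, child_path, container, slot, None, False))

    if len(values) == 1:
        one(values[0], parent, key)
    else:
        lst: list = [None] * len(values)
        parent[key] = lst
        for i, v in enumerate(values):
            one(v, lst, i)


def _plain_shell(graph, ns, node, path, with_schema, tasks):
    ts = triples_with_subject(graph, node)
    child_path = path | {node}
    groups: Dict[str, List[RdfNode]] = {}
    for t in ts:
        if with_schema and t.predicate.value in _SCHEMA_SET:
            continue
        groups.setdefault(compact_iri(t.predicate, ns), []).append(t.object)
    obj: dict = {}
    for key in sorted(groups):
        vals = sorted(groups[key], key=node_sort_key)
        _emit_group(graph, ns, vals, obj, key, child_path, tasks)
    if with_schema:
        inject_schema_relations(obj, graph, node, ns)
    return obj


def _container_shell(graph, ns, node, path, kind, tasks):
    ts = triples_with_subject(graph, node)
    child_path = path | {node}
    obj: dict = {"rdf:type": _CONTAINER_KIND_LABEL[kind]}
    ordinals: Dict[int, List[RdfNode]] = {}
    siblings: Dict[str, List[RdfNode]] = {}
    for t in ts:
        n = _ordinal(t.predicate)
        if n is not None:
            ordinals.setdefault(n, []).append(t.object)
        elif t.predicate.value == RDF_TYPE:
            if not (isinstance(t.object, Iri) and t.object.value in CONTAINER_CLASS_TO_KIND):
                logger.warning(
                    "container %s carries extra rdf:type %s; dropped", node, t.object
                )
        else:
            siblings.setdefault(compact_iri(t.predicate, ns), []).append(t.object)
    ns_sorted = sorted(ordinals)
    if ns_sorted and ns_sorted != list(range(1, len(ns_sorted) + 1)):
        logger.warning(
            "container %s has gaps in its ordinal members %s; mapped as-is",
            node,
            ns_sorted,
        )
    for n in ns_sorted:
        vals = sorted(ordinals[n], key=node_sort_key)
        _emit_group(graph, ns, vals, obj, f"rdf:_{n}", child_path, tasks)
    for key in sorted(siblings):
        vals = sorted(siblings[key], key=node_sort_key)
        _emit_group(graph, ns, vals, obj, key, child_path, tasks)
    return obj


def _collection_shell(graph, ns, head, path, tasks):
    items: List[RdfNode] = []
    spine: set = set()
    cur: RdfNode = head
    while True:
        if isinstance(cur, Iri) and cur.value == RDF_NIL:
            break
        if cur in spine:
            logger.warning("cyclic rdf:rest chain at %s; truncated", cur)
            break
        spine.add(cur)
        ts = triples_with_subject(graph, cur)
        firsts = sorted(
            (t.object for t in ts if t.predicate.value == RDF_FIRST),
            key=node_sort_key,
        )
        rests = sorted(
            (t.object for t in ts if t.predicate.value == RDF_REST),
            key=node_sort_key,
        )
        if not firsts:
            logger.warning("collection cell %s has no rdf:first; chain truncated", cur)
            break
        if len(firsts) > 1:
            logger.warning("collection cell %s has %d rdf:first values", cur, len(firsts))
        items.append(firsts[0])
        if not rests:
            logger.warning("collection chain from %s not terminated by rdf:nil", head)
            break
        nxt = rests[0]
        if isinstance(nxt, LiteralValue):
            logger.warning("collection cell %s has a literal rdf:rest; truncated", cur)
            break
        cur = nxt
    child_path = path | spine | {head}
    obj: dict = {"rdf:type": "rdf:List"}
    lst: list = [None] * len(items)
    obj["items"] = lst
    for i, v in enumerate(items):
        if isinstance(v, LiteralValue):
            lst[i] = map_literal(v, ns)
        elif isinstance(v, Iri):
            lst[i] = map_reference(v, ns)
        else:
            tasks.append((v, child_path, lst, i, None, False))
    return obj


def _run(graph: RdfGraph, ns: Dict[str, str], tasks: list) -> None:
    while tasks:
        node, path, parent, key, kind, with_schema = tasks.pop()
        if isinstance(node, BlankNodeId) and node in path:
            parent[key] = {"rdf:nodeID": node.label}
            continue
        if kind is None:
            kind = detect_special_node(graph, node)
        if kind is SpecialNodeKind.COLLECTION:
            obj = _collection_shell(graph, ns, node, path, tasks)
        elif kind in _CONTAINER_KIND_LABEL:
            obj = _container_shell(graph, ns, node, path, kind, tasks)
        else:
            obj = _plain_shell(graph, ns, node, path, with_schema, tasks)
        parent[key] = obj


def _expand(graph, node, path, ns, kind, with_schema) -> dict:
    root: dict = {"v": None}
    tasks = [(node, frozenset(path), root, "v", kind, with_schema)]
    _run(graph, ns, tasks)
    return root["v"]


def expand_blank(
    graph: RdfGraph,
    node: BlankNodeId,
    path: FrozenSet[RdfNode] = frozenset(),
    ns: Optional[Dict[str, str]] = None,
) -> dict:
    """Recursively expand a blank node into a nested value object.

    ``path`` holds the blank nodes already being expanded on this branch;
    revisiting one yields a ``{"rdf:nodeID": label}`` back-reference, which
    guarantees termination on cyclic graphs.  Container/collection patterns
    on the node delegate to :func:`map_container` / :func:`map_collection`.
    """
    if not isinstance(node, BlankNodeId):
        raise ContractError("expand_blank requires a blank node")
    return _expand(graph, node, path, ns if ns is not None else graph.namespaces, None, False)


def map_container(
    graph: RdfGraph,
    node: RdfNode,
    kind: SpecialNodeKind,
    ns: Optional[Dict[str, str]] = None,
) -> dict:
    """Bag/Seq/Alt node -> container-shape object with ordinal ``rdf:_N`` keys."""
    if kind not in _CONTAINER_KIND_LABEL:
        raise ContractError(f"{kind} is not a container kind")
    return _expand(graph, node, frozenset(), ns if ns is not None else graph.namespaces, kind, False)


def map_collection(
    graph: RdfGraph,
    head: RdfNode,
    ns: Optional[Dict[str, str]] = None,
) -> dict:
    """rdf:first/rdf:rest chain -> ``{"rdf:type": "rdf:List", "items": [...]}``."""
    return _expand(
        graph,
        head,
        frozenset(),
        ns if ns is not None else graph.namespaces,
        SpecialNodeKind.COLLECTION,
        False,
    )


def inject_schema_relations(
    resource: dict,
    graph: RdfGraph,
    subject: RdfNode,
    ns: Optional[Dict[str, str]] = None,
) -> dict:
    """Add rdfs:subClassOf / subPropertyOf / domain / range keys to a resource.

    Values are plain IRI strings (CURIE-compacted), not reference-shape
    objects; repeated relations merge into arrays.  A malformed schema
    triple whose object is a literal maps as a literal-shape object with a
    warning.
    """
    if ns is None:
        ns = graph.namespaces
    ts = triples_with_subject(graph, subject)
    for pred_iri, key in SCHEMA_PREDICATES:
        objs = sorted(
            (t.object for t in ts if t.predicate.value == pred_iri),
            key=node_sort_key,
        )
        if not objs:
            continue
        vals = []
        for o in objs:
            if isinstance(o, Iri):
                vals.append(compact_iri(o, ns))
            elif isinstance(o, LiteralValue):
                logger.warning(
                    "schema relation %s of %s has literal object %r", key, subject, o.lexical
                )
                vals.append(map_literal(o, ns))
            else:
                vals.append(expand_blank(graph, o, frozenset({subject}), ns))
        resource[key] = merge_values(vals)
    return resource


def build_resource_object(
    graph: RdfGraph,
    subject: RdfNode,
    ns: Optional[Dict[str, str]] = None,
) -> dict:
    """Build the full JSON object for one top-level subject.

    Ordinary predicate groups come first in lexicographic key order, then
    the four schema-relation keys.  A subject that is itself a typed
    container or a collection head maps directly to that shape.
    """
    if ns is None:
        ns = graph.namespaces
    kind = detect_special_node(graph, subject)
    if kind is SpecialNodeKind.PLAIN:
        return _expand(graph, subject, frozenset(), ns, SpecialNodeKind.PLAIN, True)
    return _expand(graph, subject, frozenset(), ns, kind, False)
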