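"""Independent brute-force reference mapper used to cross-check the driver.

This is a deliberately naive reimplementation of the graph -> document
contract: plain recursion, linear scans over the triple set (no indexes),
and its own CURIE compaction.  It shares only the term dataclasses with the
package under test.
"""

import re

from rdf2json.model import (
    RDF_ALT,
    RDF_BAG,
    RDF_FIRST,
    RDF_NIL,
    RDF_NS,
    RDF_REST,
    RDF_SEQ,
    RDF_TYPE,
    RDFS_DOMAIN,
    RDFS_RANGE,
    RDFS_SUBCLASSOF,
    RDFS_SUBPROPERTYOF,
    BlankNodeId,
    Iri,
    LiteralValue,
)

_LOCAL = re.compile(r"^[A-Za-z_][A-Za-z0-9_.\-]*$")
_SCHEMA = [
    (RDFS_SUBCLASSOF, "rdfs:subClassOf"),
    (RDFS_SUBPROPERTYOF, "rdfs:subPropertyOf"),
    (RDFS_DOMAIN, "rdfs:domain"),
    (RDFS_RANGE, "rdfs:range"),
]
_CONTAINERS = {RDF_BAG: "rdf:Bag", RDF_SEQ: "rdf:Seq", RDF_ALT: "rdf:Alt"}


def _key(node):
    if isinstance(node, LiteralValue):
        return (0, node.lexical, node.datatype.value, node.language or "")
    if isinstance(node, BlankNodeId):
        return (1, node.label)
    return (2, node.value)


def oracle_migrate(graph):
    ns = graph.namespaces
    trips = sorted(graph.triples, key=lambda t: (_key(t.subject), t.predicate.value, _key(t.object)))

    def compact(iri_str):
        matches = []
        for prefix, base in ns.items():
            if base and iri_str.startswith(base):
                local = iri_str[len(base):]
                if local and _LOCAL.match(local):
                    matches.append((len(base), prefix, local))
        if not matches:
            return iri_str
        length = max(m[0] for m in matches)
        _, prefix, local = min(m for m in matches if m[0] == length)
        return f"{prefix}:{local}"

    def lit(v):
        obj = {"value": v.lexical, "datatype": compact(v.datatype.value)}
        if v.language:
            obj["lang"] = v.language
        return obj

    def outgoing(node):
        return [t for t in trips if t.subject == node]

    def classify(node):
        ts = outgoing(node)
        for t in ts:
            if t.predicate.value == RDF_TYPE and isinstance(t.object, Iri):
                if t.object.value in _CONTAINERS:
                    return _CONTAINERS[t.object.value]
        if isinstance(node, Iri) and node.value == RDF_NIL:
            return "list"
        if any(t.predicate.value == RDF_FIRST for t in ts):
            return "list"
        return "plain"

    def value_of(o, path):
        if isinstance(o, LiteralValue):
            return lit(o)
        if isinstance(o, Iri):
            return {"rdf:resource": compact(o.value)}
        if o in path:
            return {"rdf:nodeID": o.label}
        kind = classify(o)
        if kind == "list":
            return collection(o, path)
        if kind in _CONTAINERS.values():
            return container(o, kind, path)
        return plain(o, path, top=False)

    def group(node, path, preds_skip):
        ts = outgoing(node)
        groups = {}
        for t in ts:
            if t.predicate.value in preds_skip:
                continue
            groups.setdefault(compact(t.predicate.value), []).append(t.object)
        obj = {}
        for k in sorted(groups):
            vals = [value_of(v, path) for v in sorted(groups[k], key=_key)]
            obj[k] = vals[0] if len(vals) == 1 else vals
        return obj

    def plain(node, path, top):
        path = path | {node}
        skip = {p for p, _ in _SCHEMA} if top else set()
        obj = group(node, path, skip)
        if top:
            ts = outgoing(node)
            for pred, key in _SCHEMA:
                objs = sorted((t.object for t in ts if t.predicate.value == pred), key=_key)
                if not objs:
                    continue
                vals = [
                    compact(o.value) if isinstance(o, Iri)
                    else lit(o) if isinstance(o, LiteralValue)
                    else plain(o, path, top=False)
                    for o in objs
                ]
                obj[key] = vals[0] if len(vals) == 1 else vals
        return obj

    def container(node, label, path):
        path = path | {node}
        ts = outgoing(node)
        obj = {"rdf:type": label}
        ordinals, siblings = {}, {}
        for t in ts:
            pv = t.predicate.value
            if pv.startswith(RDF_NS + "_") and pv[len(RDF_NS) + 1:].isdigit():
                ordinals.setdefault(int(pv[len(RDF_NS) + 1:]), []).append(t.object)
            elif pv == RDF_TYPE:
                continue
            else:
                siblings.setdefault(compact(pv), []).append(t.object)
        for n in sorted(ordinals):
            vals = [value_of(v, path) for v in sorted(ordinals[n], key=_key)]
            obj[f"rdf:_{n}"] = vals[0] if len(vals) == 1 else vals
        for k in sorted(siblings):
            vals = [value_of(v, path) for v in sorted(siblings[k], key=_key)]
            obj[k] = vals[0] if len(vals) == 1 else vals
        return obj

    def collection(head, path):
        items, spine, cur = [], set(), head
        while True:
            if isinstance(cur, Iri) and cur.value == RDF_NIL:
                break
            if cur in spine:
                break
            spine.add(cur)
            ts = outgoing(cur)
            firsts = sorted((t.object for t in ts if t.predicate.value == RDF_FIRST), key=_key)
            rests = sorted((t.object for t in ts if t.predicate.value == RDF_REST), key=_key)
            if not firsts:
                break
            items.append(firsts[0])
            if not rests or isinstance(rests[0], LiteralValue):
                break
            cur = rests[0]
        path = path | spine | {head}
        return {
            "rdf:type": "rdf:List",
            "items": [value_of(v, path) for v in items],
        }

    object_blanks = {t.object for t in trips if isinstance(t.object, BlankNodeId)}
    subs = sorted(
        {
            t.subject
            for t in trips
            if not (isinstance(t.subject, BlankNodeId) and t.subject in object_blanks)
        },
        key=_key,
    )
    resources = {}
    for s in subs:
        key = f"_:{s.label}" if isinstance(s, BlankNodeId) else compact(s.value)
        kind = classify(s)
        if kind == "list":
            resources[key] = collection(s, frozenset())
        elif kind in _CONTAINERS.values():
            resources[key] = container(s, kind, frozenset())
        else:
            resources[key] = plain(s, frozenset(), top=True)
    return {
        "namespaces": {p: ns[p] for p in sorted(ns)},
        "resources": resources,
    }
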