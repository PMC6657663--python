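"""Inverse interpreter: root JSON document -> rdflib graph.

Reconstructs the triple set a document describes (fresh blank-node labels),
so that mapping a cycle-free generated graph and interpreting the result
back yields a graph isomorphic to the input.  Used only as a test oracle.
"""

import rdflib
from rdflib import BNode, Literal, URIRef

RDF_NS = "http://www.w3.org/1999/02/22-rdf-syntax-ns#"
RDFS_NS = "http://www.w3.org/2000/01/rdf-schema#"
XSD_STRING = "http://www.w3.org/2001/XMLSchema#string"
RDF_LANGSTRING = RDF_NS + "langString"

_SCHEMA_KEYS = {
    "rdfs:subClassOf": RDFS_NS + "subClassOf",
    "rdfs:subPropertyOf": RDFS_NS + "subPropertyOf",
    "rdfs:domain": RDFS_NS + "domain",
    "rdfs:range": RDFS_NS + "range",
}
_CONTAINER_LABELS = {
    "rdf:Bag": RDF_NS + "Bag",
    "rdf:Seq": RDF_NS + "Seq",
    "rdf:Alt": RDF_NS + "Alt",
}


def interpret(doc):
    ns = doc.get("namespaces", {})
    g = rdflib.Graph(bind_namespaces="none")

    def expand(name):
        if ":" in name:
            prefix, local = name.split(":", 1)
            if prefix in ns:
                return URIRef(ns[prefix] + local)
        return URIRef(name)

    def literal_term(v):
        if "lang" in v:
            return Literal(v["value"], lang=v["lang"])
        dt = str(expand(v["datatype"]))
        if dt == XSD_STRING:
            return Literal(v["value"])
        return Literal(v["value"], datatype=URIRef(dt))

    def value_term(v):
        """Turn one value object into an RDF term, adding any nested triples."""
        if "value" in v:
            return literal_term(v)
        if "rdf:resource" in v:
            return expand(v["rdf:resource"])
        type_label = v.get("rdf:type")
        if type_label == "rdf:List":
            items = v["items"]
            if not items:
                return URIRef(RDF_NS + "nil")
            cells = [BNode() for _ in items]
            for i, item in enumerate(items):
                g.add((cells[i], URIRef(RDF_NS + "first"), value_term(item)))
                nxt = cells[i + 1] if i + 1 < len(items) else URIRef(RDF_NS + "nil")
                g.add((cells[i], URIRef(RDF_NS + "rest"), nxt))
            return cells[0]
        if type_label in _CONTAINER_LABELS:
            b = BNode()
            g.add((b, URIRef(RDF_NS + "type"), URIRef(_CONTAINER_LABELS[type_label])))
            for k, x in v.items():
                if k == "rdf:type":
                    continue
                pred = (
                    URIRef(RDF_NS + k[4:])
                    if k.startswith("rdf:_") and k[5:].isdigit()
                    else expand(k)
                )
                for item in x if isinstance(x, list) else [x]:
                    g.add((b, pred, value_term(item)))
            return b
        # nested blank description
        b = BNode()
        add_properties(b, v, schema_as_strings=False)
        return b

    def add_properties(subject_term, obj, schema_as_strings):
        for k, v in obj.items():
            if schema_as_strings and k in _SCHEMA_KEYS:
                pred = URIRef(_SCHEMA_KEYS[k])
                for item in v if isinstance(v, list) else [v]:
                    if isinstance(item, str):
                        g.add((subject_term, pred, expand(item)))
                    else:
                        g.add((subject_term, pred, value_term(item)))
                continue
            pred = expand(k)
            for item in v if isinstance(v, list) else [v]:
                g.add((subject_term, pred, value_term(item)))

    for key, robj in doc.get("resources", {}).items():
        subject = BNode() if key.startswith("_:") else expand(key)
        type_label = robj.get("rdf:type")
        if type_label == "rdf:List" or type_label in _CONTAINER_LABELS:
            # re-use value_term machinery, then copy triples onto the subject
            term = value_term(robj)
            if isinstance(term, BNode) or str(term) == RDF_NS + "nil":
                # rename the fresh node to the (possibly IRI) subject
                if str(term) != str(subject):
                    for p, o in list(g.predicate_objects(term)):
                        g.remove((term, p, o))
                        g.add((subject, p, o))
        else:
            add_properties(subject, robj, schema_as_strings=True)
    return g
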