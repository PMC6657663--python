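"""Hand-written source/expected pairs covering every mapping rule.

Each case is (id, format, source text, expected root document).  The
expected documents are written out by hand from the mapping contracts —
never generated by the code under test — and compared byte-for-byte after
canonical serialization.
"""

EX = "http://example.org/v#"
RDF = "http://www.w3.org/1999/02/22-rdf-syntax-ns#"
RDFS = "http://www.w3.org/2000/01/rdf-schema#"
XSD = "http://www.w3.org/2001/XMLSchema#"

_T_PRE = f"@prefix ex: <{EX}> .\n@prefix rdf: <{RDF}> .\n@prefix rdfs: <{RDFS}> .\n@prefix xsd: <{XSD}> .\n"
_NS_ALL = {"ex": EX, "rdf": RDF, "rdfs": RDFS, "xsd": XSD}


def _doc(resources, ns=_NS_ALL):
    return {"namespaces": dict(sorted(ns.items())), "resources": resources}


def _s(value):
    return {"value": value, "datatype": "xsd:string"}


CASES = [
    # --- namespaces become the root "namespaces" object -------------------
    (
        "namespaces_declared_prefixes",
        "turtle",
        f'@prefix ex: <{EX}> .\n@prefix xsd: <{XSD}> .\nex:a ex:p "v" .\n',
        {
            "namespaces": {"ex": EX, "xsd": XSD},
            "resources": {"ex:a": {"ex:p": _s("v")}},
        },
    ),
    (
        "namespaces_empty_document",
        "rdfxml",
        f'<?xml version="1.0"?>\n<rdf:RDF xmlns:rdf="{RDF}" xmlns:ex="{EX}">\n</rdf:RDF>\n',
        {"namespaces": {"ex": EX, "rdf": RDF}, "resources": {}},
    ),
    # --- literal values carry value/datatype/lang -------------------------
    (
        "literal_typed",
        "turtle",
        _T_PRE + 'ex:a ex:p "42"^^xsd:integer .\n',
        _doc({"ex:a": {"ex:p": {"value": "42", "datatype": "xsd:integer"}}}),
    ),
    (
        "literal_language_tagged",
        "turtle",
        _T_PRE + 'ex:a ex:p "protein"@en .\n',
        _doc(
            {
                "ex:a": {
                    "ex:p": {
                        "value": "protein",
                        "datatype": "rdf:langString",
                        "lang": "en",
                    }
                }
            }
        ),
    ),
    # --- IRI values become rdf:resource references ------------------------
    (
        "reference_compacted",
        "turtle",
        _T_PRE + "ex:a ex:p ex:b .\n",
        _doc({"ex:a": {"ex:p": {"rdf:resource": "ex:b"}}}),
    ),
    (
        "reference_uncompactable",
        "turtle",
        _T_PRE + "ex:a ex:p <http://other.org/path/to/item> .\n",
        _doc({"ex:a": {"ex:p": {"rdf:resource": "http://other.org/path/to/item"}}}),
    ),
    # --- blank nodes expand recursively ------------------------------------
    (
        "blank_node_nested",
        "turtle",
        _T_PRE + 'ex:a ex:p [ ex:x "1"^^xsd:integer ] .\n',
        _doc({"ex:a": {"ex:p": {"ex:x": {"value": "1", "datatype": "xsd:integer"}}}}),
    ),
    (
        "blank_node_two_levels",
        "turtle",
        _T_PRE + 'ex:a ex:p [ ex:x "1" ; ex:y [ ex:z ex:b ] ] .\n',
        _doc(
            {
                "ex:a": {
                    "ex:p": {
                        "ex:x": _s("1"),
                        "ex:y": {"ex:z": {"rdf:resource": "ex:b"}},
                    }
                }
            }
        ),
    ),
    # --- containers keep their type and ordinal keys -----------------------
    (
        "container_seq_two_literals",
        "turtle",
        _T_PRE + 'ex:a ex:members [ a rdf:Seq ; rdf:_1 "a" ; rdf:_2 "b" ] .\n',
        _doc(
            {
                "ex:a": {
                    "ex:members": {
                        "rdf:type": "rdf:Seq",
                        "rdf:_1": _s("a"),
                        "rdf:_2": _s("b"),
                    }
                }
            }
        ),
    ),
    (
        "container_bag_iri_member_and_empty_alt",
        "turtle",
        _T_PRE
        + "ex:a ex:members [ a rdf:Bag ; rdf:_1 ex:m ] .\n"
        + "ex:b ex:members [ a rdf:Alt ] .\n",
        _doc(
            {
                "ex:a": {
                    "ex:members": {
                        "rdf:type": "rdf:Bag",
                        "rdf:_1": {"rdf:resource": "ex:m"},
                    }
                },
                "ex:b": {"ex:members": {"rdf:type": "rdf:Alt"}},
            }
        ),
    ),
    # --- collections flatten into ordered items ----------------------------
    (
        "collection_two_literals",
        "turtle",
        _T_PRE + 'ex:a ex:list ("x" "y") .\n',
        _doc(
            {
                "ex:a": {
                    "ex:list": {
                        "rdf:type": "rdf:List",
                        "items": [_s("x"), _s("y")],
                    }
                }
            }
        ),
    ),
    (
        "collection_three_iris",
        "turtle",
        _T_PRE + "ex:a ex:list (ex:m1 ex:m2 ex:m3) .\n",
        _doc(
            {
                "ex:a": {
                    "ex:list": {
                        "rdf:type": "rdf:List",
                        "items": [
                            {"rdf:resource": "ex:m1"},
                            {"rdf:resource": "ex:m2"},
                            {"rdf:resource": "ex:m3"},
                        ],
                    }
                }
            }
        ),
    ),
    # --- class hierarchy: plain-string superclass URI ----------------------
    (
        "subclass_single",
        "turtle",
        _T_PRE + "ex:C1 rdfs:subClassOf ex:C2 .\n",
        _doc({"ex:C1": {"rdfs:subClassOf": "ex:C2"}}),
    ),
    (
        "subclass_multiple_merge",
        "turtle",
        _T_PRE + "ex:C1 rdfs:subClassOf ex:C2 , ex:C3 .\n",
        _doc({"ex:C1": {"rdfs:subClassOf": ["ex:C2", "ex:C3"]}}),
    ),
    # --- property hierarchy -------------------------------------------------
    (
        "subproperty_single",
        "turtle",
        _T_PRE + "ex:p1 rdfs:subPropertyOf ex:p2 .\n",
        _doc({"ex:p1": {"rdfs:subPropertyOf": "ex:p2"}}),
    ),
    (
        "subproperty_with_ordinary_props",
        "turtle",
        _T_PRE + 'ex:p1 rdfs:subPropertyOf ex:p2 ; ex:note "n" .\n',
        _doc({"ex:p1": {"ex:note": _s("n"), "rdfs:subPropertyOf": "ex:p2"}}),
    ),
    # --- domain and range go under the property object ----------------------
    (
        "domain_and_range",
        "turtle",
        _T_PRE + "ex:p1 rdfs:domain ex:C1 ; rdfs:range ex:C2 .\n",
        _doc({"ex:p1": {"rdfs:domain": "ex:C1", "rdfs:range": "ex:C2"}}),
    ),
    (
        "full_property_description",
        "turtle",
        _T_PRE
        + "ex:p1 rdfs:subPropertyOf ex:p0 ; rdfs:domain ex:C1 ; rdfs:range ex:C2 .\n",
        _doc(
            {
                "ex:p1": {
                    "rdfs:subPropertyOf": "ex:p0",
                    "rdfs:domain": "ex:C1",
                    "rdfs:range": "ex:C2",
                }
            }
        ),
    ),
    # --- repeated predicates merge into arrays ------------------------------
    (
        "repeat_literals_merge",
        "turtle",
        _T_PRE + 'ex:a ex:p "x" , "y" .\n',
        _doc({"ex:a": {"ex:p": [_s("x"), _s("y")]}}),
    ),
    (
        "repeat_mixed_literal_before_reference",
        "turtle",
        _T_PRE + 'ex:a ex:p "x" , ex:b .\n',
        _doc({"ex:a": {"ex:p": [_s("x"), {"rdf:resource": "ex:b"}]}}),
    ),
    # --- properties without a specific value map to a blank string ----------
    (
        "empty_value_turtle",
        "turtle",
        _T_PRE + 'ex:a ex:p "" .\n',
        _doc({"ex:a": {"ex:p": _s("")}}),
    ),
    (
        "empty_value_rdfxml_element",
        "rdfxml",
        f'<?xml version="1.0"?>\n'
        f'<rdf:RDF xmlns:rdf="{RDF}" xmlns:ex="{EX}">\n'
        f'  <rdf:Description rdf:about="{EX}a"><ex:p></ex:p></rdf:Description>\n'
        f"</rdf:RDF>\n",
        {
            "namespaces": {"ex": EX, "rdf": RDF},
            "resources": {"ex:a": {"ex:p": {"value": "", "datatype": XSD + "string"}}},
        },
    ),
]
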