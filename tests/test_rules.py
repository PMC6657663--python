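"""Unit and property tests for the mapping rules."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rdf2json.errors import ContractError
from rdf2json.fixtures import FixtureSpec, generate_graph
from rdf2json.model import (
    RDF_BAG,
    RDF_FIRST,
    RDF_LANGSTRING,
    RDF_NIL,
    RDF_NS,
    RDF_REST,
    RDF_SEQ,
    RDF_TYPE,
    BlankNodeId,
    Iri,
    LiteralValue,
    RdfGraph,
    SpecialNodeKind,
    Triple,
)
from rdf2json.rules import (
    compact_iri,
    expand_blank,
    inject_schema_relations,
    map_collection,
    map_container,
    map_literal,
    map_namespaces,
    map_reference,
    merge_values,
)

EX = "http://example.org/v#"
XSD = "http://www.w3.org/2001/XMLSchema#"
NS = {"ex": EX, "xsd": XSD, "rdf": RDF_NS}


def g(*triples, ns=NS):
    return RdfGraph(frozenset(triples), dict(ns))


def t(s, p, o):
    return Triple(s, p if isinstance(p, Iri) else Iri(EX + p), o)


class TestNamespacesAndCuries:
    def test_map_namespaces_sorted(self):
        assert map_namespaces({"xsd": XSD, "ex": EX}) == {"ex": EX, "xsd": XSD}

    def test_map_namespaces_empty(self):
        assert map_namespaces({}) == {}

    @pytest.mark.parametrize(
        "iri,ns,expected",
        [
            (EX + "KineticLaw", {"ex": EX}, "ex:KineticLaw"),
            (EX + "a", {}, EX + "a"),
            # longest namespace wins when one extends another
            (
                "http://x/sub/item",
                {"short": "http://x/", "long": "http://x/sub/"},
                "long:item",
            ),
            # slash in the remainder disqualifies the shorter match too
            ("http://x/sub/a/b", {"short": "http://x/", "long": "http://x/sub/"}, "http://x/sub/a/b"),
            # tie on namespace length -> lexicographically smaller prefix
            ("http://x/i", {"b": "http://x/", "a": "http://x/"}, "a:i"),
        ],
    )
    def test_compact_iri(self, iri, ns, expected):
        assert compact_iri(Iri(iri), ns) == expected

    @given(st.text(alphabet="abcXYZ_", min_size=1, max_size=8))
    @settings(max_examples=50, deadline=None)
    def test_compact_iri_expands_back(self, local):
        ns = {"ex": EX}
        result = compact_iri(Iri(EX + local), ns)
        if ":" in result and not result.startswith("http"):
            prefix, got = result.split(":", 1)
            assert ns[prefix] + got == EX + local
        else:
            assert result == EX + local


class TestLiteralAndReference:
    def test_typed_literal(self):
        lit = LiteralValue("42", Iri(XSD + "integer"))
        assert map_literal(lit, NS) == {"value": "42", "datatype": "xsd:integer"}

    def test_language_tagged_literal(self):
        lit = LiteralValue("protein", language="en")
        assert map_literal(lit, NS) == {
            "value": "protein",
            "datatype": "rdf:langString",
            "lang": "en",
        }

    def test_empty_literal(self):
        assert map_literal(LiteralValue(""), NS) == {
            "value": "",
            "datatype": "xsd:string",
        }

    def test_reference(self):
        assert map_reference(Iri(EX + "b"), NS) == {"rdf:resource": "ex:b"}

    def test_reference_nil(self):
        assert map_reference(Iri(RDF_NIL), NS) == {"rdf:resource": "rdf:nil"}

    def test_reference_no_prefix(self):
        assert map_reference(Iri("http://o.org/x"), {}) == {
            "rdf:resource": "http://o.org/x"
        }


class TestExpandBlank:
    def test_single_property(self):
        b = BlankNodeId("b")
        graph = g(t(b, "x", LiteralValue("1", Iri(XSD + "integer"))))
        assert expand_blank(graph, b) == {
            "ex:x": {"value": "1", "datatype": "xsd:integer"}
        }

    def test_empty_description(self):
        assert expand_blank(g(), BlankNodeId("b")) == {}

    def test_two_node_cycle_terminates_with_back_reference(self):
        b1, b2 = BlankNodeId("B1"), BlankNodeId("B2")
        graph = g(t(b1, "next", b2), t(b2, "next", b1))
        assert expand_blank(graph, b1) == {
            "ex:next": {"ex:next": {"rdf:nodeID": "B1"}}
        }

    def test_self_loop(self):
        b = BlankNodeId("b")
        graph = g(t(b, "next", b))
        assert expand_blank(graph, b) == {"ex:next": {"rdf:nodeID": "b"}}

    def test_shared_blank_duplicated_not_backref(self):
        """A diamond (not a cycle) is inlined twice, never cut short."""
        b1, b2 = BlankNodeId("b1"), BlankNodeId("b2")
        top = BlankNodeId("top")
        graph = g(t(top, "l", b1), t(top, "r", b2), t(b1, "v", LiteralValue("x")),
                  t(b2, "w", b1))
        assert expand_blank(graph, top) == {
            "ex:l": {"ex:v": {"value": "x", "datatype": "xsd:string"}},
            "ex:r": {"ex:w": {"ex:v": {"value": "x", "datatype": "xsd:string"}}},
        }

    def test_non_blank_rejected(self):
        with pytest.raises(ContractError):
            expand_blank(g(), Iri(EX + "a"))


class TestContainers:
    def test_seq_two_literals(self):
        b = BlankNodeId("c")
        graph = g(
            t(b, Iri(RDF_TYPE), Iri(RDF_SEQ)),
            t(b, Iri(RDF_NS + "_1"), LiteralValue("a")),
            t(b, Iri(RDF_NS + "_2"), LiteralValue("b")),
        )
        assert map_container(graph, b, SpecialNodeKind.CONTAINER_SEQ, NS) == {
            "rdf:type": "rdf:Seq",
            "rdf:_1": {"value": "a", "datatype": "xsd:string"},
            "rdf:_2": {"value": "b", "datatype": "xsd:string"},
        }

    def test_bag_iri_member(self):
        b = BlankNodeId("c")
        graph = g(
            t(b, Iri(RDF_TYPE), Iri(RDF_BAG)),
            t(b, Iri(RDF_NS + "_1"), Iri(EX + "m")),
        )
        assert map_container(graph, b, SpecialNodeKind.CONTAINER_BAG, NS) == {
            "rdf:type": "rdf:Bag",
            "rdf:_1": {"rdf:resource": "ex:m"},
        }

    def test_empty_alt(self):
        b = BlankNodeId("c")
        graph = g(t(b, Iri(RDF_TYPE), Iri(RDF_NS + "Alt")))
        assert map_container(graph, b, SpecialNodeKind.CONTAINER_ALT, NS) == {
            "rdf:type": "rdf:Alt"
        }

    def test_gap_in_ordinals_mapped_as_is(self, caplog):
        b = BlankNodeId("c")
        graph = g(
            t(b, Iri(RDF_TYPE), Iri(RDF_SEQ)),
            t(b, Iri(RDF_NS + "_1"), LiteralValue("a")),
            t(b, Iri(RDF_NS + "_3"), LiteralValue("c")),
        )
        with caplog.at_level("WARNING"):
            obj = map_container(graph, b, SpecialNodeKind.CONTAINER_SEQ, NS)
        assert list(obj) == ["rdf:type", "rdf:_1", "rdf:_3"]
        assert any("gap" in r.message for r in caplog.records)

    def test_non_ordinal_member_becomes_sibling_key(self):
        b = BlankNodeId("c")
        graph = g(
            t(b, Iri(RDF_TYPE), Iri(RDF_SEQ)),
            t(b, Iri(RDF_NS + "_1"), LiteralValue("a")),
            t(b, "note", LiteralValue("n")),
        )
        obj = map_container(graph, b, SpecialNodeKind.CONTAINER_SEQ, NS)
        assert obj["ex:note"] == {"value": "n", "datatype": "xsd:string"}


class TestCollections:
    def _chain(self, *items):
        cells = [BlankNodeId(f"c{i}") for i in range(len(items))]
        triples = []
        for i, item in enumerate(items):
            triples.append(t(cells[i], Iri(RDF_FIRST), item))
            nxt = cells[i + 1] if i + 1 < len(items) else Iri(RDF_NIL)
            triples.append(t(cells[i], Iri(RDF_REST), nxt))
        return (cells[0] if cells else Iri(RDF_NIL)), g(*triples)

    def test_two_literals_in_order(self):
        head, graph = self._chain(LiteralValue("x"), LiteralValue("y"))
        assert map_collection(graph, head, NS) == {
            "rdf:type": "rdf:List",
            "items": [
                {"value": "x", "datatype": "xsd:string"},
                {"value": "y", "datatype": "xsd:string"},
            ],
        }

    def test_nil_head_is_empty_list(self):
        assert map_collection(g(), Iri(RDF_NIL), NS) == {
            "rdf:type": "rdf:List",
            "items": [],
        }

    def test_three_iris_chain_order(self):
        head, graph = self._chain(Iri(EX + "m1"), Iri(EX + "m3"), Iri(EX + "m2"))
        obj = map_collection(graph, head, NS)
        assert [x["rdf:resource"] for x in obj["items"]] == ["ex:m1", "ex:m3", "ex:m2"]

    def test_unterminated_chain_truncates_with_warning(self, caplog):
        c0 = BlankNodeId("c0")
        graph = g(t(c0, Iri(RDF_FIRST), LiteralValue("x")))
        with caplog.at_level("WARNING"):
            obj = map_collection(graph, c0, NS)
        assert obj["items"] == [{"value": "x", "datatype": "xsd:string"}]
        assert any("not terminated" in r.message for r in caplog.records)

    def test_cyclic_rest_chain_truncates(self, caplog):
        c0, c1 = BlankNodeId("c0"), BlankNodeId("c1")
        graph = g(
            t(c0, Iri(RDF_FIRST), LiteralValue("x")),
            t(c0, Iri(RDF_REST), c1),
            t(c1, Iri(RDF_FIRST), LiteralValue("y")),
            t(c1, Iri(RDF_REST), c0),
        )
        with caplog.at_level("WARNING"):
            obj = map_collection(graph, c0, NS)
        assert len(obj["items"]) == 2


class TestSchemaRelations:
    def test_full_property_description(self):
        p = Iri(EX + "p1")
        graph = g(
            Triple(p, Iri("http://www.w3.org/2000/01/rdf-schema#subPropertyOf"), Iri(EX + "p0")),
            Triple(p, Iri("http://www.w3.org/2000/01/rdf-schema#domain"), Iri(EX + "C1")),
            Triple(p, Iri("http://www.w3.org/2000/01/rdf-schema#range"), Iri(EX + "C2")),
        )
        obj = inject_schema_relations({}, graph, p, NS)
        assert obj == {
            "rdfs:subPropertyOf": "ex:p0",
            "rdfs:domain": "ex:C1",
            "rdfs:range": "ex:C2",
        }

    def test_no_schema_triples_identity(self):
        graph = g(t(Iri(EX + "s"), "p", LiteralValue("v")))
        base = {"ex:p": {"value": "v", "datatype": "xsd:string"}}
        assert inject_schema_relations(dict(base), graph, Iri(EX + "s"), NS) == base

    def test_literal_schema_object_maps_as_literal_with_warning(self, caplog):
        c = Iri(EX + "C1")
        graph = g(
            Triple(c, Iri("http://www.w3.org/2000/01/rdf-schema#subClassOf"), LiteralValue("oops")),
        )
        with caplog.at_level("WARNING"):
            obj = inject_schema_relations({}, graph, c, NS)
        assert obj["rdfs:subClassOf"] == {"value": "oops", "datatype": "xsd:string"}
        assert caplog.records


class TestMergeValues:
    def test_single_not_wrapped(self):
        v = {"value": "x", "datatype": "xsd:string"}
        assert merge_values([v]) is v

    def test_two_become_array(self):
        v1, v2 = {"rdf:resource": "ex:a"}, {"rdf:resource": "ex:b"}
        assert merge_values([v1, v2]) == [v1, v2]

    def test_empty_rejected(self):
        with pytest.raises(ContractError):
            merge_values([])

    @given(st.integers(min_value=1, max_value=6))
    @settings(max_examples=20, deadline=None)
    def test_never_one_element_array_never_drops(self, n):
        values = [{"rdf:resource": f"ex:x{i}"} for i in range(n)]
        merged = merge_values(list(values))
        if n == 1:
            assert merged == values[0]
        else:
            assert merged == values


def _iter_value_objects(value):
    """Yield every value object inside a resource object."""
    stack = [value]
    while stack:
        v = stack.pop()
        if isinstance(v, dict):
            yield v
            stack.extend(v.values())
        elif isinstance(v, list):
            stack.extend(v)


def _shape_of(obj):
    shapes = []
    if "value" in obj:
        shapes.append("literal")
    if "rdf:resource" in obj:
        shapes.append("reference")
    if "rdf:nodeID" in obj:
        shapes.append("backref")
    if obj.get("rdf:type") in ("rdf:Bag", "rdf:Seq", "rdf:Alt"):
        shapes.append("container")
    if obj.get("rdf:type") == "rdf:List" and "items" in obj:
        shapes.append("collection")
    if not shapes:
        shapes.append("nested")
    return shapes


@pytest.mark.parametrize("seed", range(10))
def test_shape_exclusivity_on_generated_graphs(seed):
    """Every emitted value object matches exactly one of the five shapes."""
    from rdf2json.driver import migrate_graph

    fx = generate_graph(FixtureSpec(seed=seed, n_subjects=15))
    doc = migrate_graph(fx.graph)
    for robj in doc["resources"].values():
        for obj in _iter_value_objects(robj):
            assert len(_shape_of(obj)) == 1


@pytest.mark.parametrize("seed", range(10))
def test_container_and_collection_counts_preserved(seed):
    """Member count in equals member count out, for every container/collection."""
    from rdf2json.driver import migrate_graph

    fx = generate_graph(
        FixtureSpec(seed=seed, n_subjects=10, p_literal=0, p_reference=0,
                    p_blank=0, p_container=0.5, p_collection=0.5, p_repeat=0)
    )
    graph = fx.graph
    member_triples = sum(
        1
        for x in graph.triples
        if x.predicate.value.startswith(RDF_NS + "_")
        and x.predicate.value[len(RDF_NS) + 1:].isdigit()
    )
    chain_cells = sum(1 for x in graph.triples if x.predicate.value == RDF_FIRST)
    doc = migrate_graph(graph)
    out_members = out_items = 0
    for robj in doc["resources"].values():
        for obj in _iter_value_objects(robj):
            if _shape_of(obj) == ["container"]:
                out_members += sum(1 for k in obj if k.startswith("rdf:_"))
            if _shape_of(obj) == ["collection"]:
                out_items += len(obj["items"])
    assert out_members == member_triples
    assert out_items == chain_cells
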