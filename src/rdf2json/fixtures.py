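"""Synthetic RDF graph generators.

Real bio-database extracts (protein annotation records, kinetic model
descriptions) are structurally a mix of literal properties, cross-record
IRI references, anonymous nested descriptions, the three RDF containers,
closed collections and RDFS schema triples.  The generators here emit
graphs with a controlled mix of exactly those features, together with a
manifest of how many of each were produced, so tests have both variety and
an independent ground truth.  Everything is driven by a seed and is fully
reproducible.
"""

from __future__ import annotations

import itertools
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List

from .errors import OutputError, ValidationError
from .model import (
    RDF_ALT,
    RDF_BAG,
    RDF_FIRST,
    RDF_LANGSTRING,
    RDF_NIL,
    RDF_NS,
    RDF_PROPERTY,
    RDF_REST,
    RDF_SEQ,
    RDF_TYPE,
    RDFS_CLASS,
    RDFS_DOMAIN,
    RDFS_NS,
    RDFS_RANGE,
    RDFS_SUBCLASSOF,
    RDFS_SUBPROPERTYOF,
    XSD_NS,
    BlankNodeId,
    Iri,
    LiteralValue,
    RdfGraph,
    Triple,
    subjects,
    write_rdfxml,
)

EX_NS = "http://example.org/vocab#"
BIO_NS = "http://example.org/bio#"
SBML_NS = "http://example.org/sbml-rdf#"

BASE_NAMESPACES = {
    "rdf": RDF_NS,
    "rdfs": RDFS_NS,
    "xsd": XSD_NS,
    "ex": EX_NS,
    "bio": BIO_NS,
}

XSD_INTEGER = XSD_NS + "integer"

_CONTAINER_CLASSES = [RDF_BAG, RDF_SEQ, RDF_ALT]
_LANGS = ["en", "de", "fr"]


@dataclass
class FixtureSpec:
    """Parameters controlling one generated graph.

    The ``p_*`` fields are the per-property probabilities of each value
    feature; any leftover probability mass produces an empty-string literal
    (the "property without a specific value" case).  Defaults reflect the
    make-up of typical annotation records: mostly literal fields, some
    cross-references, occasional anonymous nodes, and rare containers and
    collections.
    """

    seed: int = 0
    n_subjects: int = 20
    p_literal: float = 0.5
    p_reference: float = 0.2
    p_blank: float = 0.1
    p_container: float = 0.075
    p_collection: float = 0.075
    p_repeat: float = 0.15
    schema_depth: int = 2
    lang_fraction: float = 0.2

    def validate(self) -> None:
        probs = [
            self.p_literal,
            self.p_reference,
            self.p_blank,
            self.p_container,
            self.p_collection,
        ]
        if any(p < 0 or p > 1 for p in probs + [self.p_repeat, self.lang_fraction]):
            raise ValidationError("probabilities must lie in [0, 1]")
        if sum(probs) > 1 + 1e-9:
            raise ValidationError("feature probabilities must sum to at most 1")
        if self.n_subjects < 0 or self.schema_depth < 0:
            raise ValidationError("counts must be non-negative")


@dataclass
class Fixture:
    """A generated graph plus the generator's per-feature manifest."""

    graph: RdfGraph
    manifest: Dict[str, int] = field(default_factory=dict)


def _blank_manifest() -> Dict[str, int]:
    return {
        "literals": 0,
        "lang_literals": 0,
        "empty_literals": 0,
        "references": 0,
        "blanks": 0,
        "containers": 0,
        "collections": 0,
        "repeats": 0,
        "cycles": 0,
        "schema_class_links": 0,
        "schema_property_links": 0,
        "domain_range_pairs": 0,
        "subjects": 0,
        "triples": 0,
    }


def generate_graph(spec: FixtureSpec) -> Fixture:
    """Generate a reproducible synthetic graph per ``spec``.

    Blank-node values are fresh trees (no sharing, no cycles), so any
    cycle-free round-trip property holds on this output by construction;
    cyclic graphs come from :func:`cycle_graph` instead.
    """
    spec.validate()
    rng = random.Random(spec.seed)
    uid = itertools.count()
    triples: set = set()
    m = _blank_manifest()

    def add(s, p, o) -> None:
        triples.add(Triple(s, Iri(p), o))

    def fresh_literal() -> LiteralValue:
        n = next(uid)
        if rng.random() < spec.lang_fraction:
            m["lang_literals"] += 1
            m["literals"] += 1
            return LiteralValue(f"text{n}", Iri(RDF_LANGSTRING), rng.choice(_LANGS))
        m["literals"] += 1
        if rng.random() < 0.3:
            return LiteralValue(str(n), Iri(XSD_INTEGER))
        return LiteralValue(f"v{n}")

    def make_value(feature: str):
        if feature == "literal":
            return fresh_literal()
        if feature == "reference":
            m["references"] += 1
            return Iri(EX_NS + f"r{next(uid)}")
        if feature == "blank":
            b = BlankNodeId(f"b{next(uid)}")
            for k in range(rng.randint(1, 2)):
                add(b, EX_NS + f"q{k}", fresh_literal())
            m["blanks"] += 1
            return b
        if feature == "container":
            b = BlankNodeId(f"b{next(uid)}")
            add(b, RDF_TYPE, Iri(rng.choice(_CONTAINER_CLASSES)))
            for j in range(1, rng.randint(0, 3) + 1):
                member = (
                    fresh_literal()
                    if rng.random() < 0.7
                    else make_value("reference")
                )
                add(b, RDF_NS + f"_{j}", member)
            m["containers"] += 1
            return b
        if feature == "collection":
            length = rng.randint(1, 3)
            head = BlankNodeId(f"b{next(uid)}")
            cur = head
            for j in range(length):
                item = (
                    fresh_literal()
                    if rng.random() < 0.7
                    else make_value("reference")
                )
                add(cur, RDF_FIRST, item)
                nxt = (
                    Iri(RDF_NIL)
                    if j == length - 1
                    else BlankNodeId(f"b{next(uid)}")
                )
                add(cur, RDF_REST, nxt)
                cur = nxt
            m["collections"] += 1
            return head
        # leftover probability mass: property without a specific value
        m["empty_literals"] += 1
        return LiteralValue("")

    def draw_feature() -> str:
        r = rng.random()
        acc = 0.0
        for name, p in (
            ("literal", spec.p_literal),
            ("reference", spec.p_reference),
            ("blank", spec.p_blank),
            ("container", spec.p_container),
            ("collection", spec.p_collection),
        ):
            acc += p
            if r < acc:
                return name
        return "empty"

    for i in range(1, spec.schema_depth + 1):
        add(Iri(BIO_NS + f"Class{i}"), RDFS_SUBCLASSOF, Iri(BIO_NS + f"Class{i-1}"))
        m["schema_class_links"] += 1
        add(Iri(BIO_NS + f"prop{i}"), RDFS_SUBPROPERTYOF, Iri(BIO_NS + f"prop{i-1}"))
        m["schema_property_links"] += 1
    if spec.schema_depth > 0:
        add(Iri(BIO_NS + "prop1"), RDFS_DOMAIN, Iri(BIO_NS + "Class1"))
        add(Iri(BIO_NS + "prop1"), RDFS_RANGE, Iri(BIO_NS + "Class0"))
        m["domain_range_pairs"] += 1

    for i in range(spec.n_subjects):
        s = Iri(EX_NS + f"s{i}")
        for j in range(rng.randint(1, 3)):
            pred = EX_NS + f"p{j}"
            add(s, pred, make_value(draw_feature()))
            if rng.random() < spec.p_repeat:
                # a second, distinct literal under the same predicate
                add(s, pred, fresh_literal())
                m["repeats"] += 1

    graph = RdfGraph(frozenset(triples), dict(BASE_NAMESPACES))
    m["triples"] = len(graph.triples)
    m["subjects"] = len(subjects(graph))
    return Fixture(graph=graph, manifest=m)


def generate_schema_fixture() -> RdfGraph:
    """A small kinetic-modelling schema: class and property hierarchies.

    Classes ``Element`` > ``SBMLElement`` > ``KineticLaw`` plus
    ``SpeciesReference`` and ``Reaction``; property ``kineticLaw`` is a
    subproperty of ``sbmlElement`` with domain ``Reaction`` and range
    ``KineticLaw``.
    """
    ns = {"rdf": RDF_NS, "rdfs": RDFS_NS, "sbmlRdf": SBML_NS}
    triples = set()

    def add(s, p, o):
        triples.add(Triple(Iri(SBML_NS + s), Iri(p), o))

    for cls in ("Element", "SBMLElement", "SpeciesReference", "KineticLaw", "Reaction"):
        add(cls, RDF_TYPE, Iri(RDFS_CLASS))
    for prop in ("sbmlElement", "kineticLaw"):
        add(prop, RDF_TYPE, Iri(RDF_PROPERTY))
    add("SBMLElement", RDFS_SUBCLASSOF, Iri(SBML_NS + "Element"))
    add("KineticLaw", RDFS_SUBCLASSOF, Iri(SBML_NS + "SBMLElement"))
    add("kineticLaw", RDFS_SUBPROPERTYOF, Iri(SBML_NS + "sbmlElement"))
    add("kineticLaw", RDFS_DOMAIN, Iri(SBML_NS + "Reaction"))
    add("kineticLaw", RDFS_RANGE, Iri(SBML_NS + "KineticLaw"))
    return RdfGraph(frozenset(triples), ns)


def homogeneous_graph(n_subjects: int, seed: int) -> RdfGraph:
    """A graph with a fixed per-subject shape (4 triples each) for scaling runs."""
    triples = set()
    for i in range(n_subjects):
        s = Iri(EX_NS + f"s{i}")
        triples.add(Triple(s, Iri(EX_NS + "p0"), LiteralValue(f"alpha{seed}_{i}")))
        triples.add(Triple(s, Iri(EX_NS + "p1"), LiteralValue(f"beta{seed}_{i}")))
        triples.add(
            Triple(s, Iri(EX_NS + "p2"), LiteralValue(str(i), Iri(XSD_INTEGER)))
        )
        triples.add(Triple(s, Iri(EX_NS + "p3"), Iri(EX_NS + f"s{(i + 1) % max(n_subjects, 1)}")))
    return RdfGraph(frozenset(triples), dict(BASE_NAMESPACES))

#: triples emitted per subject by :func:`homogeneous_graph`
HOMOGENEOUS_SUBJECT_TRIPLES = 4


def scaling_series(
    base_subjects: int, doublings: int, seed: int, out_dir
) -> List[Path]:
    """Write a doubling series of RDF/XML fixtures and return the paths.

    File ``i`` holds ``base_subjects * 2**i`` subjects with an identical
    per-subject triple layout, so document size grows linearly in subject
    count.
    """
    if doublings < 1:
        raise ValidationError("doublings must be >= 1")
    out = Path(out_dir)
    paths: List[Path] = []
    for i in range(doublings):
        n = base_subjects * 2**i
        graph = homogeneous_graph(n, seed)
        p = out / f"scale_{n:08d}.rdf"
        try:
            write_rdfxml(graph, p)
        except OSError as exc:
            raise OutputError(f"cannot write fixture {p}: {exc}") from exc
        paths.append(p)
    return paths


def cycle_graph(length: int) -> RdfGraph:
    """Blank nodes linked in a cycle of ``length`` (1 = self-loop), reachable
    from one IRI subject."""
    if length < 1:
        raise ValidationError("cycle length must be >= 1")
    triples = set()
    blanks = [BlankNodeId(f"c{i}") for i in range(length)]
    triples.add(Triple(Iri(EX_NS + "s"), Iri(EX_NS + "head"), blanks[0]))
    for i, b in enumerate(blanks):
        triples.add(Triple(b, Iri(EX_NS + "next"), blanks[(i + 1) % length]))
        triples.add(Triple(b, Iri(EX_NS + "tag"), LiteralValue(f"cell{i}")))
    return RdfGraph(frozenset(triples), dict(BASE_NAMESPACES))


def deep_chain_graph(depth: int) -> RdfGraph:
    """A non-cyclic chain of ``depth`` nested blank nodes (stress fixture)."""
    if depth < 1:
        raise ValidationError("depth must be >= 1")
    triples = set()
    blanks = [BlankNodeId(f"d{i}") for i in range(depth)]
    triples.add(Triple(Iri(EX_NS + "s"), Iri(EX_NS + "head"), blanks[0]))
    for i in range(depth - 1):
        triples.add(Triple(blanks[i], Iri(EX_NS + "next"), blanks[i + 1]))
    triples.add(Triple(blanks[-1], Iri(EX_NS + "val"), LiteralValue("end")))
    return RdfGraph(frozenset(triples), dict(BASE_NAMESPACES))
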