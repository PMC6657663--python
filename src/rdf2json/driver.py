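"""Migration driver: the two-loop graph -> document algorithm.

The outer loop walks every top-level subject of the graph; the inner loop
walks that subject's predicate groups and maps each group through the
rules in :mod:`rdf2json.rules`.  The result is a root document::

    {"namespaces": {prefix: iri, ...},
     "resources":  {subject-key: resource-object, ...}}

Subject keys are CURIE-compacted IRIs; top-level blank subjects are keyed
``_:label``.  The output is a pure function of the graph, so repeated runs
produce byte-identical files.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

from .errors import OutputError
from .model import BlankNodeId, RdfGraph, load_graph, subjects
from .output import serialize
from .rules import build_resource_object, compact_iri, map_namespaces


def migrate_graph(graph: RdfGraph) -> dict:
    """Map a whole graph to its root JSON document."""
    ns = graph.namespaces
    resources = {}
    for subject in subjects(graph):
        if isinstance(subject, BlankNodeId):
            key = f"_:{subject.label}"
        else:
            key = compact_iri(subject, ns)
        resources[key] = build_resource_object(graph, subject, ns)
    return {"namespaces": map_namespaces(ns), "resources": resources}


def migrate_file(
    input_path,
    syntax: str = "auto",
    output: Optional[str] = None,
    style: str = "pretty",
    mongo_sanitize: bool = False,
) -> Path:
    """Convert one RDF file to JSON and return the path written.

    When ``output`` is omitted the JSON file is written next to the source
    with the extension replaced by ``.json``.
    """
    graph = load_graph(input_path, syntax)
    doc = migrate_graph(graph)
    if mongo_sanitize:
        from .mongo import sanitize_document

        doc = sanitize_document(doc)
    data = serialize(doc, style)
    out = Path(output) if output is not None else Path(input_path).with_suffix(".json")
    try:
        out.write_bytes(data)
    except OSError as exc:
        raise OutputError(f"cannot write {out}: {exc}") from exc
    return out
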