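# rdf2json

Migrate RDF data into JSON documents — and on into MongoDB.

Biomedical databases (protein annotation, computational models of
biological processes, gene–disease networks) widely publish their records
as RDF: graphs of subject–predicate–object triples, with RDFS class and
property hierarchies layered on top. Document stores and modern web APIs,
on the other hand, expect JSON. `rdf2json` performs that migration: it
parses RDF/XML or Turtle into a triple/graph model and applies a fixed set
of mapping rules to produce one JSON object per resource, preserving the
information a record carries while shedding the markup overhead of XML.

## The mapping

For a graph *G* with namespace declarations *N*, the converter emits

```
{"namespaces": {prefix: iri, ...},           # the declared prefixes
 "resources":  {subject: {property: value, ...}, ...}}
```

where each property value is one of five shapes:

| RDF value                    | JSON shape |
|------------------------------|------------|
| literal                      | `{"value": lex, "datatype": dt[, "lang": tag]}` |
| IRI reference                | `{"rdf:resource": "prefix:local"}` |
| blank node                   | its description, expanded recursively in place |
| container (Bag / Seq / Alt)  | `{"rdf:type": "rdf:Seq", "rdf:_1": v1, ...}` |
| collection (`rdf:List`)      | `{"rdf:type": "rdf:List", "items": [v1, ...]}` |

RDFS schema triples get dedicated keys on the resource object:
`rdfs:subClassOf`, `rdfs:subPropertyOf`, `rdfs:domain` and `rdfs:range`
hold the target IRI as a plain string. Repeated properties of one resource
merge into an array; a property without a specific value maps to an empty
string. Blank-node cycles are cut with an explicit
`{"rdf:nodeID": label}` back-reference, so conversion always terminates.
IRIs are abbreviated to CURIEs (`prefix:local`) whenever a declared
namespace matches — the longest match wins.

Every list the converter emits is canonically ordered (keys
lexicographic, repeated values sorted literals < blank nodes < IRIs), so
converting the same file twice gives byte-identical output.

## Worked example

```python
from rdf2json import migrate_graph, serialize
from rdf2json.fixtures import generate_schema_fixture

doc = migrate_graph(generate_schema_fixture())
print(serialize(doc, "pretty").decode())
```

prints (abridged) the JSON objects for a small kinetic-modelling schema:

```json
{
  "namespaces": {
    "rdf": "http://www.w3.org/1999/02/22-rdf-syntax-ns#",
    "rdfs": "http://www.w3.org/2000/01/rdf-schema#",
    "sbmlRdf": "http://example.org/sbml-rdf#"
  },
  "resources": {
    "sbmlRdf:KineticLaw": {
      "rdf:type": {"rdf:resource": "rdfs:Class"},
      "rdfs:subClassOf": "sbmlRdf:SBMLElement"
    },
    "sbmlRdf:kineticLaw": {
      "rdf:type": {"rdf:resource": "rdf:Property"},
      "rdfs:subPropertyOf": "sbmlRdf:sbmlElement",
      "rdfs:domain": "sbmlRdf:Reaction",
      "rdfs:range": "sbmlRdf:KineticLaw"
    }
  }
}
```

`sbmlRdf:KineticLaw` is a class whose superclass is recorded directly on
its object; `sbmlRdf:kineticLaw` is a property that applies to reactions
(`rdfs:domain`) and takes kinetic-law instances as values (`rdfs:range`).

The same pipeline is available from a shell:

```
rdf2json convert model.rdf --style minified --report
rdf2json export-mongo model.json --out model.jsonl
rdf2json import-cmd --db bio --coll models --file model.jsonl
```

`convert` writes `model.json` next to the source and, with `--report`,
prints the byte sizes and the compression rate `1 − json/rdf` on stderr.
`export-mongo` rewrites field names that MongoDB rejects (`.`, NUL, a
leading `$`) using fullwidth Unicode homoglyphs and emits one JSON record
per resource, ready for `mongoimport`. `rdf2json gen` produces synthetic
RDF fixtures with a known feature mix for testing.

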