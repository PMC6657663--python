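# Methods

## Source model

RDF inputs (RDF/XML or Turtle, UTF-8) are parsed with rdflib and converted
to an immutable triple set plus a prefix → namespace map containing exactly
the prefixes the document declares. Three term kinds exist: IRIs, blank
nodes (label scoped to one graph) and literals. Every literal is
normalised to carry an explicit datatype: plain literals become
`xsd:string`, language-tagged literals become `rdf:langString`. Named
graphs, reification and OWL vocabulary are not interpreted; such triples
pass through as ordinary statements.

The graph keeps set semantics, so a triple asserted twice is one triple.
A lazily built subject index makes per-resource lookups O(1); the
migration is therefore linear in the number of triples apart from the
O(n log n) canonical sorts.

## Determinism

Graph stores are unordered, so every emitted ordering is fixed by
convention:

* node order: literals < blank nodes < IRIs; within a class,
  lexicographic by (lexical form, datatype, language), label, or IRI;
* object keys: ordinary property keys lexicographic, then the four schema
  keys in the order subClassOf, subPropertyOf, domain, range; container
  objects list `rdf:type`, then ordinals ascending, then sibling keys;
* repeated values are sorted by node order before merging into an array.

Two conversions of one file are byte-identical, which the suite asserts.

## Mapping decisions

* **CURIEs.** Property keys and IRI-string values are abbreviated when a
  declared namespace prefixes the IRI and the remainder is a plausible
  local name (`[A-Za-z_][A-Za-z0-9_.-]*`). The longest namespace wins;
  length ties go to the lexicographically smaller prefix; otherwise the
  full IRI is kept.
* **Schema relations** are plain IRI strings, not `rdf:resource`
  objects — they name a superclass/superproperty/domain/range rather than
  embed a value — and are only lifted to dedicated keys on *top-level*
  resources. Inside a nested blank-node description the same predicates
  map as ordinary reference-shape properties.
* **`rdf:type`** on an ordinary resource is an ordinary property. On a
  container node the Bag/Seq/Alt type is consumed by the container shape's
  `"rdf:type"` marker string; any additional type triple on a container is
  dropped with a warning, because its key would collide with the marker.
* **Blank nodes** are inlined at every reference site. A blank node shared
  by two parents is therefore duplicated in the output (a storage, not a
  correctness, trade-off); only a true cycle — revisiting a node on the
  same expansion branch — produces a `{"rdf:nodeID": label}`
  back-reference. Blank subjects never referenced as objects stay
  top-level under the key `_:label`.
* **Malformed structures degrade, never abort**: ordinal gaps in a
  container, chains not terminated by `rdf:nil`, cyclic `rdf:rest` links
  and literal-valued schema relations are mapped as far as possible and
  logged as warnings.
* **Empty values**: an empty-content property element parses to the empty
  literal and maps to `{"value": "", "datatype": "xsd:string"}`.
* **merge_values** never wraps a single value and never drops one; it
  preserves the order of the values it is given, and all internal callers
  supply them pre-sorted in canonical node order.

## Implementation notes

Blank-node expansion uses an explicit work stack rather than recursion.
Placeholders are inserted into the parent object in final key order before
children are processed, so traversal order cannot affect output order, and
nesting depth is bounded only by memory (exercised at depth 10 000).

Serialization uses a stack-based encoder that reproduces `json.dumps`
output byte-for-byte (2-space `pretty`, whitespace-free `minified`). The
stdlib encoder was unsuitable for a reason worth recording: its nested
generators forward every chunk through one frame per nesting level, which
is quadratic in depth and also subject to the interpreter recursion limit.
Pretty-printing a chain nested *d* deep is itself Θ(d²) bytes of
indentation, so deep documents should be written minified.

MongoDB sanitization replaces `.` with U+FF0E and a leading `$` with
U+FF04 (fullwidth homoglyphs: readable, reversible in practice) and strips
NUL. The rewrite is idempotent, and a collision between two distinct keys
raises rather than silently merging fields. The import file is JSON Lines,
one resource per line, each record carrying its subject key under `"uri"`.

The compression rate is defined as 1 − (JSON bytes / RDF bytes), measured
on files as stored; sizes are reported both in bytes and in decimal MB
rounded to 2 decimals.

## Synthetic data

`FixtureSpec` drives the generator: per-property probabilities of each
value feature (default 0.50 literal, 0.20 IRI reference, 0.10 nested blank
node, 0.075 container, 0.075 collection, remainder empty-string literal),
a 0.15 chance of a repeated predicate, a 0.2 fraction of language-tagged
literals, and an RDFS class/property hierarchy of depth 2 with one
domain/range pair. These proportions mirror the make-up of annotation
records, which are dominated by literal fields and cross-references, with
containers and collections rare. Each generated graph carries a manifest
of the feature counts actually emitted, verified in tests by independent
structural detection.

Generated blank-node values are fresh trees — no sharing, no cycles — so
on this population the mapping is invertible: an inverse interpreter
(test code) rebuilds a graph from the JSON and checks isomorphism with the
input. Adversarial shapes (cycles of length 1/2/5, a 10 000-deep chain)
are built by dedicated constructors instead. What the generator does *not*
emulate: the vocabulary sizes, text statistics, IRI lengths and degree
distributions of real database extracts. Passing tests demonstrate
structural correctness of the mapping, not the exact compression or
runtime figures any particular real corpus would show; those depend on
serialization conventions and corpus statistics.

## Problem sizes

The test suite and the acceptance script use: 500 (tests) / 200 (script)
random graphs of ≤ 200 triples for oracle equivalence and round-trip
checks; 50 / 30 fixtures of ≥ 100 subjects for the compression property;
a 1k/2k/4k/8k-subject homogeneous series (4 triples per subject) for the
scaling check, asserting each runtime doubling ratio stays below 4; and
100–200 documents for sanitization safety. The scaling assertion is a
soft, order-of-growth check — wall-clock ratios on small inputs are noisy,
which is why the bound is generous and a warm-up conversion precedes
timing.

## Known limitations

* Shared blank nodes are duplicated per reference site; consumers that
  need aliasing preserved must pre-skolemise.
* N-Triples/N-Quads/JSON-LD inputs, SPARQL and OWL reasoning are out of
  scope; `rdfs:subClassOf` closures are not computed, only recorded.
* Datatype values stay strings; no numeric coercion is attempted.
* CURIE compaction is lossy only in pathological cases (a key that is
  itself a declared prefix followed by a colon); the inverse interpreter
  used in testing assumes generated vocabularies, not arbitrary ones.
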