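# Methods

This note documents the design of sparqlpipe: the querying model, the
contracts of each stage, what the synthetic fixtures emulate, the
numerical and lexical edge-case decisions, and known limitations.

## Querying model

The client has two generation modes and one composition mechanism.

**Shortcut mode** builds a SELECT query around a single triple pattern.
Each of subject/predicate/object is either a constant (IRI, prefixed
name, quoted literal, or — in predicate position — a SPARQL 1.1 property
path taken verbatim) or open.  Open positions become the fixed variables
`?s`, `?p`, `?o` and are projected in S,P,O order.  Fixed variable names
are deliberate: they are predictable join targets for pipe composition
and for users inspecting `-q` output.  Two degenerate cases are defined
rather than rejected:

* all three positions fixed → `SELECT (COUNT(*) AS ?n)` over the
  pattern, so the TSV output (0 vs ≥ 1) still signals absence/presence;
  an empty projection would not be grammatical SPARQL.
* no positions fixed → a full `?s ?p ?o` dump (use `-L` to cap it).

Token classification is ordered and total: bare decimal integers are
input-column references (never numeric literals — quote a number
explicitly to pass it as data; this resolves the `-S 1` ambiguity
deterministically), bracketed or `http(s)://` tokens are IRIs,
explicitly quoted tokens are literals, predicate-position tokens
containing a path operator outside an IRI are property paths, and
`label:local` is a prefixed name — with an *undeclared* label being an
error rather than silently a literal, so typos surface at generation
time.  The generated query declares exactly the prefixes its body uses.
No implicit LIMIT is added and DISTINCT is opt-in, mirroring SPARQL's
own defaults; silent truncation or deduplication would corrupt
pipelines.

**Template mode** resolves a named SPARQL text and substitutes
positional parameters.  Placeholders are `$N` with the longest digit run
winning (`$12` is parameter 12), counted and replaced only outside
string literals, IRIREFs and comments.  Parameters are inserted
*verbatim*: templates embed them in the lexical context they need
(`ent:$1`, `db:$1`, or a string position for which the caller passes an
already-quoted literal such as `"^alzheimer"`).  Auto-quoting was
rejected because only the template author knows whether a parameter is a
local name, an IRI, or a literal.  Every instantiated query must pass an
independent SPARQL 1.1 grammar (rdflib's parser) before it is sent;
failures are generation errors that echo the offending text.
Resolution order is: existing local file (local intent is explicit and
wins over a library entry of the same name), local library directories
(`<name>.rq` before `<name>`, later-declared libraries shadowing earlier
ones), prefixed names expanded against a library's base IRI and fetched
over HTTP, then full URIs.  Remote fetches are plain GETs, uncached
unless `--cache-dir` enables content-addressed caching.

**Binding transfer.** A downstream stage reads the upstream TSV, maps
columns to query variables (`-S/-P/-O <column>` in shortcut mode; the
reserved variables `?in1, ?in2, …` in templates, which keep templates
self-describing about their standard-input contract), deduplicates rows
by the bound columns preserving first occurrence, splits them into
chunks of at most `--chunk-size` rows (default 100, chosen to keep
encoded queries within common endpoint URL/POST limits), and prepends a
`VALUES` block to the outermost group pattern of each outgoing query.
VALUES injection — rather than per-row query rewriting or `SERVICE`
clauses — serves both modes with one mechanism, bounds HTTP round
trips, and matches SPARQL 1.1 federation practice.  Deduplication
matches the "list of IDs" reading of a piped column; `VALUES`
duplicates would otherwise multiply join rows.  The contract, enforced
by tests, is that the concatenation of chunk results equals the
brute-force nested-loop join over the distinct inputs, for any chunk
size.

Because TSV erases RDF term types, input tokens are re-classified on the
way back in: bracketed or `http(s)://` tokens become IRIs, `label:local`
with a declared label stays a prefixed name (so abbreviated output from
a previous `-a` stage round-trips), an empty field becomes `UNDEF`, and
anything else a plain literal.  A first input line is treated as a
header only when every field looks like a variable name *and* the
downstream query references at least one of them; `--no-in-header`
forces data.  This heuristic accepts both headered output from a
previous stage and bare `cut -f1` columns; an unreferenced header name
that slips through as data binds nothing and is harmless to the join,
which is why the invariant tests compare multisets against the join
oracle rather than exact streams.

## Protocol and serialization

Queries go out per the SPARQL 1.1 Protocol: GET when the URL-encoded
query is at most 2000 bytes, POST (form-urlencoded) otherwise.  The
Accept header lists SPARQL Results JSON before XML (JSON is universally
supported; XML is the mandated fallback); an endpoint's configured
preference may reorder it.  The default timeout is 60 s with no retry —
pipelines should fail fast and visibly.  In TSV output, plain literals
are emitted bare and typed/language annotations are dropped, because the
stream is meant for line-oriented Unix tools; `--raw-terms` preserves
full lexical forms.  A literal containing a tab or newline is a hard
serialization error, never silent corruption.  The header line is on by
default (a downstream stage auto-detects it) and `--no-header` disables
it; with chunked execution the header is emitted once.

Abbreviation (`-a`) replaces an IRI by `label:remainder` using the
longest declared namespace whose remainder is a conservative PN_LOCAL
(no whitespace, `/`, `#`, quotes or angle brackets — emitting an
unparseable prefixed name would corrupt downstream queries); equal-length
ties go to the later declaration, matching layered-config override
semantics.  Expansion of `label:local` after abbreviation returns the
original IRI whenever abbreviation fired; this round trip is property-
tested.

## Configuration

Line-oriented directives — `PREFIX label: <iri>` (copy-pasteable into
SPARQL), `ENDPOINT nickname url [json,xml,tsv]`, `LIBRARY name root
[label:]` — merged last-writer-wins per key across layers: package
builtins, `~/.sparqlpipe/config`, `./sparqlpipe.config`, then `--config`
files in order.  Unknown directives and malformed lines are rejected
with the file name and line number.  The builtin layer declares common
prefixes, example nicknames for public endpoints (nothing in the package
or tests contacts them), the packaged template library, and the demo
fixture namespace.

## Synthetic fixtures

`sparqlpipe.fixtures` generates seeded graphs that emulate the *shape*
of the target databases, not their content or ontologies: everything
lives under the project-owned namespace `http://example.org/fixture/`.
For a fixed `(kind, n_entities, seed)` the triple set is identical
across runs and platforms (Python's `random.Random(seed)` only).

* `protein_annot(n)` — `n` entries, each with one `rdfs:label`, one
  organism link whose taxon carries a scientific name (5-taxon pool),
  1–3 classification links into a 6-term GO-style pool (each used term
  labelled once), and 0–2 cross-reference nodes tagged with a database
  (PDB/RefSeq/EMBL pool).
* `ortholog_db(n)` — the same accession space partitioned sequentially
  into groups of seeded sizes 3–6 (or caller-given sizes), with
  group→member links.
* `expression_db(n)` — `n` probes, each linked to one labelled disease
  condition (3-condition pool) and one protein entry.

A few anchors are planted deterministically so documented walkthroughs
are stable: entry P02649 ("apolipoprotein E", human, one PDB
cross-reference), entry Q9Y2J0 ("rabphilin-3A", classified with the
synapse term GO_0045202), ortholog member K9Z723 grouped with the two
anchors, and condition EFO_0000249 ("Alzheimer's disease") with two
differentially-expressed anchor probes.  Default sizes in tests and the
acceptance script are 15–50 entities — small enough that brute-force
oracles (full triple scans, nested-loop joins) are trivially computable,
which is the point of the fixtures.

What the fixtures do **not** emulate: real database scale, real
vocabularies and ontology structure, blank nodes, named graphs, language
tags, endpoint quirks (rate limits, server-side result caps, cursoring).
Passing tests therefore demonstrate the correctness of query generation,
binding transfer and protocol handling, not robustness against any
particular public endpoint's behavior.

The loopback endpoint serves the SPARQL Protocol (GET and POST, JSON and
XML results with Accept negotiation, 406 on unsupported types) over
127.0.0.1 and sorts solutions for byte-stable comparisons; it also
serves template files so remote-library resolution is testable offline.
It is shipped as package code — it doubles as a demo server — but is
started only on explicit request.

## Numerical and edge-case choices

* GET/POST switch at 2000 encoded bytes; chunk size default 100; both
  flag-tunable, and results are chunk-size-invariant by contract.
* `$0` is never a placeholder; placeholder indices are 1-based, as are
  input column references.
* Zero input rows with a column binding produce zero outgoing queries
  and empty output (exit 0) without contacting the endpoint.
* `-q` prints the first chunk's query when input is chunked, and never
  executes queries; resolving a *remote* template is the one network
  action `-q` may still perform, since there is nothing to print without
  the template text.
* Errors map to stable exit codes (2 config, 3 generation, 4 resolution,
  5 transport, 6 format); stderr carries one-line diagnostics and never
  interleaves with stdout TSV.

## Limitations

* Shortcut mode covers exactly one triple pattern (plus property paths);
  OPTIONAL/FILTER/GRAPH and aggregation beyond the all-constant COUNT
  belong in templates.
* The whole input table is read before the first outgoing query; there
  is no streaming execution.
* No CONSTRUCT/DESCRIBE output, no UPDATE, no authentication headers,
  and no `SERVICE`-clause rewriting — federation is pipe composition by
  design.
* TSV output drops literal datatypes and language tags unless
  `--raw-terms` is given.
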