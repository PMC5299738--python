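# sparqlpipe

A pipe-composable SPARQL client for the Unix command line, aimed at
bioinformaticians who work with RDF databases (UniProt, ortholog
databases, expression atlases, ontology services) but do not want to
hand-write SPARQL for every lookup.

The `spq` command turns three ideas into shell ergonomics:

1. **Shortcut mode** — because all RDF data is subject–predicate–object
   triples, a very large share of useful queries is "give me the triples
   matching this partially-specified pattern".  `-S`, `-P`, `-O` fix a
   subject, predicate (or property path) and object; unspecified
   positions become projected variables:

   ```
   spq uniprot -S uniprot:P02649 -a
   ```

   generates `SELECT ?p ?o WHERE { uniprot:P02649 ?p ?o . }`, runs it
   against the endpoint nicknamed `uniprot`, and prints TSV with IRIs
   abbreviated (`-a`) through the configured prefix declarations.

2. **Template mode** — complex query shapes are reused, not rewritten.
   A second positional argument names a SPARQL template (a local file, a
   name in a library directory, a full URI, or a prefixed URI such as
   `mbgdl:get_ortholog` resolved against a library published on the
   Web); the remaining arguments replace the positional placeholders
   `$1`, `$2`, … before execution.

3. **Pipe composition** — queries against *different* endpoints combine
   through ordinary Unix pipes.  A downstream stage reads the upstream
   TSV and injects chosen columns into its query as a SPARQL `VALUES`
   block (`-S 1` binds column 1 to the subject; templates can consume
   column N through the reserved variable `?inN`).  Rows are
   deduplicated and chunked (default 100 per outgoing query), and the
   concatenated results are independent of the chunk size — a poor
   man's federated query without writing `SERVICE` clauses.

Everything the CLI does is a thin layer over library functions
(`sparqlpipe.shortcuts`, `templates`, `bindings`, `client`, `config`),
so the same operations are scriptable from Python.

## Worked example

The package ships a seeded fixture generator that emulates toy
protein-annotation, ortholog and expression databases, plus a loopback
SPARQL endpoint, so the full workflow can be demonstrated offline:

```python
from sparqlpipe.fixtures import FixtureSpec, build_fixture, serve_loopback
proteins  = build_fixture(FixtureSpec("protein_annot", 30, seed=7))
orthologs = build_fixture(FixtureSpec("ortholog_db", 18, seed=7))
server = serve_loopback({"/uniprot": proteins, "/mbgd": orthologs})
print(server.url("/uniprot"))   # e.g. http://127.0.0.1:41219/uniprot
```

Inspect the generated query without executing it (`-q`):

```
$ spq http://127.0.0.1:41219/uniprot -S ent:P02649 -q
PREFIX ent: <http://example.org/fixture/entry/>
SELECT ?p ?o
WHERE {
  ent:P02649 ?p ?o .
}
```

Run it with abbreviated output:

```
$ spq http://127.0.0.1:41219/uniprot -S ent:P02649 -a
p	o
fx:classifiedWith	go:GO_0005576
fx:classifiedWith	go:GO_0016020
fx:organism	tax:T9606
fx:xref	xr:P02649_X1
rdfs:label	apolipoprotein E
```

Each row is one matching triple: entry P02649 ("apolipoprotein E") is
classified with two GO-style terms, linked to taxon T9606, carries one
cross-reference, and has a label.

Cross-database pipe: fetch the ortholog group of K9Z723 from the
ortholog endpoint, then look up labels for those entries on the protein
endpoint, binding input column 1 to the subject:

```
$ spq http://127.0.0.1:41219/mbgd get_ortholog K9Z723 \
    | spq http://127.0.0.1:41219/uniprot -S 1 -P rdfs:label -a
s	o
ent:P00001	receptor 971
ent:P00002	lipoprotein 97
ent:P02649	apolipoprotein E
ent:Q9Y2J0	rabphilin-3A
```

Four of the five group members have annotation records; K9Z723 itself
has no label in the protein graph, so it simply contributes no row —
exactly the semantics of the brute-force nested-loop join the tests
compare against.

Configuration (endpoint nicknames such as `uniprot`, prefix
declarations, template library roots) is layered line-oriented text:
package builtins, then `~/.sparqlpipe/config`, `./sparqlpipe.config`,
and repeatable `--config` files, later layers winning per key.  Exit
codes are stable (0 success, 2 configuration, 3 query generation,
4 name resolution, 5 transport, 6 data format) and diagnostics go to
stderr only, so stdout stays a clean TSV stream.

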