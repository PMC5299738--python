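# Keep the entries given on standard input (first input column binds
# ?in1) that are classified with GO term $1 (bare accession, e.g.
# GO_0045202), and report their labels.  Written against the synthetic
# fixture schema shipped with this package.
PREFIX rdfs: <http://www.w3.org/2000/01/rdf-schema#>
PREFIX fx: <http://example.org/fixture/vocab/>
PREFIX go: <http://example.org/fixture/go/>
SELECT ?in1 ?label
WHERE {
  ?in1 fx:classifiedWith go:$1 ;
       rdfs:label ?label .
}
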