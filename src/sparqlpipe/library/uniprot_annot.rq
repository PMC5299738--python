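# Annotation summary for one protein entry: label, organism scientific
# name, and classification terms.  $1 is a bare entry accession, e.g.
# P02649.  Written against the synthetic fixture schema shipped with this
# package (sparqlpipe.fixtures), not a public database schema.
PREFIX rdfs: <http://www.w3.org/2000/01/rdf-schema#>
PREFIX fx: <http://example.org/fixture/vocab/>
PREFIX ent: <http://example.org/fixture/entry/>
SELECT ?label ?organism ?class
WHERE {
  ent:$1 rdfs:label ?label ;
         fx:organism ?taxon ;
         fx:classifiedWith ?class .
  ?taxon fx:scientificName ?organism .
}
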