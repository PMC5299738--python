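# Labelled resources whose label matches a regular expression
# (case-insensitive).  $1 must be a SPARQL string literal, quotes
# included, e.g. "^alzheimer".  Applicable to any endpoint.
PREFIX rdfs: <http://www.w3.org/2000/01/rdf-schema#>
SELECT ?class ?label
WHERE {
  ?class rdfs:label ?label .
  FILTER regex(str(?label), $1, "i")
}
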