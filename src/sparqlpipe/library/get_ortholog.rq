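# Members of the ortholog group containing entry $1 (bare accession,
# e.g. K9Z723).  Written against the synthetic fixture schema shipped
# with this package.
PREFIX fx: <http://example.org/fixture/vocab/>
PREFIX ent: <http://example.org/fixture/entry/>
SELECT ?member
WHERE {
  ?group fx:member ent:$1 .
  ?group fx:member ?member .
}
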