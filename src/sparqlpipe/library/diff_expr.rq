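# Proteins differentially expressed under sample condition $1 (bare
# condition accession, e.g. EFO_0000249), with the reporting probe.
# Written against the synthetic fixture schema shipped with this package.
PREFIX fx: <http://example.org/fixture/vocab/>
PREFIX cond: <http://example.org/fixture/condition/>
SELECT ?protein ?probe
WHERE {
  ?probe fx:diffExprIn cond:$1 .
  ?probe fx:refersTo ?protein .
}
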