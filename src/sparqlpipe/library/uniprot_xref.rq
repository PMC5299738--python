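# Cross-references of the entries given on standard input (first input
# column binds ?in1) to the target database named by $1 (bare name, e.g.
# PDB).  Written against the synthetic fixture schema shipped with this
# package.
PREFIX fx: <http://example.org/fixture/vocab/>
PREFIX db: <http://example.org/fixture/database/>
SELECT ?in1 ?xref
WHERE {
  ?in1 fx:xref ?xref .
  ?xref fx:database db:$1 .
}
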