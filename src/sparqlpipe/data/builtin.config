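# Built-in configuration layer.
#
# Frequently used prefix declarations, example endpoint nicknames for
# public biological SPARQL services, and the remote template library of
# the Microbial Genome Database.  User layers (~/.sparqlpipe/config,
# ./sparqlpipe.config, --config files) override these entries per key.

PREFIX rdf: <http://www.w3.org/1999/02/22-rdf-syntax-ns#>
PREFIX rdfs: <http://www.w3.org/2000/01/rdf-schema#>
PREFIX owl: <http://www.w3.org/2002/07/owl#>
PREFIX xsd: <http://www.w3.org/2001/XMLSchema#>
PREFIX dc: <http://purl.org/dc/elements/1.1/>
PREFIX dcterms: <http://purl.org/dc/terms/>
PREFIX skos: <http://www.w3.org/2004/02/skos/core#>
PREFIX foaf: <http://xmlns.com/foaf/0.1/>
PREFIX obo: <http://purl.obolibrary.org/obo/>
PREFIX up: <http://purl.uniprot.org/core/>
PREFIX uniprot: <http://purl.uniprot.org/uniprot/>
PREFIX taxon: <http://purl.uniprot.org/taxonomy/>
PREFIX efo: <http://www.ebi.ac.uk/efo/>
PREFIX mbgdl: <http://mbgd.genome.ad.jp/sparql/library/>

# Synthetic demo namespace used by the packaged template library and the
# seeded fixture graphs (sparqlpipe.fixtures).
PREFIX fx: <http://example.org/fixture/vocab/>
PREFIX ent: <http://example.org/fixture/entry/>
PREFIX tax: <http://example.org/fixture/taxon/>
PREFIX go: <http://example.org/fixture/go/>
PREFIX grp: <http://example.org/fixture/group/>
PREFIX probe: <http://example.org/fixture/probe/>
PREFIX cond: <http://example.org/fixture/condition/>
PREFIX db: <http://example.org/fixture/database/>
PREFIX xr: <http://example.org/fixture/xref/>

# Example nicknames for public endpoints; nothing in the package or its
# tests contacts them.
ENDPOINT uniprot https://sparql.uniprot.org/sparql
ENDPOINT mbgd http://mbgd.genome.ad.jp/sparql
ENDPOINT atlas https://www.ebi.ac.uk/rdf/services/sparql

LIBRARY mbgd_web http://mbgd.genome.ad.jp/sparql/library/ mbgdl:
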