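# ggprel CLI configuration (picked up from the working directory or via
# --config): ontology IRIs and the relation-label mapping file.
base_iri: http://example.org/ggprel/
ontology_iri: http://example.org/ggprel/ontology
so_import: http://purl.obolibrary.org/obo/so.owl
genia_import: http://www.geniaontology.org/term.owl
imports: true
map: relation_map.yaml
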