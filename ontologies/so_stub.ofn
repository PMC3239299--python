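Prefix(=<http://example.org/ggprel/>)
Prefix(owl:=<http://www.w3.org/2002/07/owl#>)
Prefix(rdf:=<http://www.w3.org/1999/02/22-rdf-syntax-ns#>)
Prefix(rdfs:=<http://www.w3.org/2000/01/rdf-schema#>)
Prefix(xsd:=<http://www.w3.org/2001/XMLSchema#>)
Ontology(<http://example.org/ggprel/so-stub>
Declaration(AnnotationProperty(:patternContract))
Declaration(AnnotationProperty(:sourceLine))
Declaration(Class(:GGP))
Declaration(ObjectProperty(:transcribed-from))
Declaration(ObjectProperty(:translated-from))
)
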