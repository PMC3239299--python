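Prefix(=<http://example.org/ggprel/>)
Prefix(owl:=<http://www.w3.org/2002/07/owl#>)
Prefix(rdf:=<http://www.w3.org/1999/02/22-rdf-syntax-ns#>)
Prefix(rdfs:=<http://www.w3.org/2000/01/rdf-schema#>)
Prefix(xsd:=<http://www.w3.org/2001/XMLSchema#>)
Ontology(<http://example.org/ggprel/genia-term-stub>
Declaration(AnnotationProperty(:patternContract))
Declaration(AnnotationProperty(:sourceLine))
Declaration(Class(:DNA))
Declaration(Class(:DNA_domain_or_region))
Declaration(Class(:DNA_family_or_group))
Declaration(Class(:DNA_molecule))
Declaration(Class(:GGP))
Declaration(Class(:Protein))
Declaration(Class(:Protein_complex))
Declaration(Class(:Protein_domain_or_region))
Declaration(Class(:Protein_family_or_group))
Declaration(Class(:Protein_molecule))
Declaration(Class(:RNA))
Declaration(Class(:RNA_domain_or_region))
Declaration(Class(:RNA_family_or_group))
Declaration(Class(:RNA_molecule))
SubClassOf(:DNA_domain_or_region :DNA)
SubClassOf(:DNA_family_or_group :DNA)
SubClassOf(:DNA_molecule :DNA)
SubClassOf(:Protein_complex :Protein)
SubClassOf(:Protein_domain_or_region :Protein)
SubClassOf(:Protein_family_or_group :Protein)
SubClassOf(:Protein_molecule :Protein)
SubClassOf(:RNA_domain_or_region :RNA)
SubClassOf(:RNA_family_or_group :RNA)
SubClassOf(:RNA_molecule :RNA)
)
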