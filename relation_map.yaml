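Member-Collection:
  type: member
Object-Component:
  type: component
Object-Region:
  type: region
Object-Variant:
  relation: GGP-has-variant
  type: variant
Object-Variant:Experimental-Material:
  relation: GGP-has-experimental-material
  type: variant
Object-Variant:Isoform:
  relation: GGP-has-isoform
  type: variant
Object-Variant:Modified-Protein:
  relation: GGP-has-modified-protein
  type: variant
Object-Variant:Mutant:
  relation: GGP-has-mutant
  type: variant
Object-Variant:Precursor:
  relation: GGP-has-precursor
  type: variant
Object-Variant:Recombinant:
  relation: GGP-has-recombinant
  type: variant
Subclass:
  type: subclass
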