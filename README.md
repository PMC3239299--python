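# ggprel — relation formalization for gene/gene-product annotations

Biomedical corpora annotate relations (*part of*, *member of*, *located
at*, *variant of*, *is a*) between named-entity mentions. When a mention
denotes a **gene/gene-product (GGP)** — a deliberately ambiguous class
unifying a gene's DNA, RNA and protein classes — the generic class-level
reading of such a relation is wrong: asserting

```
CD19 promoter ⊑ ∃part-of.CD19        CD19 ⊑ ∃part-of.CD19/CD21/CD81/Leu-13-complex
```

with transitive parthood derives that a *promoter is part of a protein
complex*, which is false: only the DNA subclass of the CD19 GGP has a
promoter as part, and only the protein subclass sits in the complex.

`ggprel` implements the formal repair, for annotators, corpus maintainers
and ontology engineers:

* a **relation taxonomy** (II- = between individuals, CC- = between
  classes, GGP- = pattern-defined class relations) with per-relation
  axioms: `II-part-of` is reflexive, transitive, antisymmetric;
  `II-oc-part-of` adds strong supplementation; `II-member-of` ⊑
  `II-proper-part-of` is irreflexive, asymmetric, non-transitive;
  `II-has-variant` is reflexive and symmetric; `II-has-mutant`
  irreflexive and symmetric; location propagates along parthood via the
  chains `part ∘ located ⊑ located` and `located ∘ part ⊑ located`;
* the **GGP class construction**: `G_C ≡ C ⊔ ∃transcribed-from.C ⊔
  ∃translated-from.∃transcribed-from.C` for a seed DNA class `C`;
* two **ontology design patterns**:
  * *subclass pattern* — `GGP-subclass-R(G_C, X)` holds when, for at
    least one kind `K ∈ {DNA, RNA, Protein}`, every instance of
    `G_C ⊓ K` has an `II-R` successor in `X` (an axiom disjunction,
    reformulated for OWL with the universal property and `owl:Nothing`);
  * *variant pattern* — `GGP-has-variant(G_C, D)` and its six
    sub-relations: every instance of `D` bears the individual-level
    variance relation to some instance of (a kind-restricted subclass of)
    `G_C`;
* a **converter** from standoff annotation documents (`.txt`/`.ann`
  pairs) to OWL 2 ontologies (functional syntax, Turtle alternate),
  respecting OWL 2 DL's ban on reflexivity/symmetry-style characteristics
  for non-simple properties;
* a **finite-model checker** — deductive closure plus closed-world
  evaluation of every axiom and pattern contract with explicit violation
  witnesses — so annotations can be verified without an external
  reasoner.

## Worked example

Write the bundled fixture documents and verify the classic counterexample
under both readings:

```bash
$ ggprel fixtures --out-dir fixtures
$ ggprel validate fixtures/cd19_complex_faulty.txt --generic-schema; echo "exit $?"
cd19_complex_faulty: subclass [ObjectIntersectionOf(:Protein_complex ObjectSomeValuesFrom(:II-has-part :DNA))] witnesses=CD19_CD21_CD81_Leu-13_complex.1 — CD19_CD21_CD81_Leu-13_complex.1 is in ObjectIntersectionOf(:Protein_complex ObjectSomeValuesFrom(:II-has-part :DNA)) but not in owl:Nothing
exit 1
$ ggprel validate fixtures/cd19_complex_faulty.txt; echo "exit $?"
cd19_complex_faulty: consistent
exit 0
```

Under the generic schema the checker closes the model, derives
`II-part-of(CD19_promoter.1, CD19_CD21_CD81_Leu-13_complex.1)` by
transitivity, and the background constraint *protein complexes have no
DNA parts* is violated with the complex individual as witness (exit 1).
The same document converted through the GGP subclass pattern assigns the
promoter to the DNA subclass and the complex membership to the protein
subclass; no faulty chain exists and the document verifies clean (exit 0).

Conversion produces deterministic OWL; the CD19 promoter document
contains, among others,

```
EquivalentClasses(:G_CD19 ObjectUnionOf(:CD19_gene
    ObjectSomeValuesFrom(:transcribed-from :CD19_gene)
    ObjectSomeValuesFrom(:translated-from ObjectSomeValuesFrom(:transcribed-from :CD19_gene))))
```

— the GGP class construction — plus the pattern contract and its
`owl:Nothing` reformulation for `GGP-subclass-has-part(G_CD19,
CD19_promoter)`.

Other commands: `ggprel convert DIR --out OUT --format ofn|ttl`,
`ggprel taxonomy [--yaml|--ofn]`. Exit codes: 0 consistent/success,
1 violations, 2 input error.

## Library surface

```python
from ggprel import (build_genia_taxonomy, parse_annotation, convert_abstract,
                    verify_annotation, worked_examples, random_corpus)

tax = build_genia_taxonomy()
doc = worked_examples()[0]
axioms, model, report = verify_annotation(doc.parse(), tax)
assert report.ok
```

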