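# Methods

## The problem and the model

Named-entity annotation in molecular-biology text deliberately refuses to
decide whether a name like *CD19* denotes a DNA, RNA or protein class:
the three are *indistinguishable* for the annotation task, and the name
is taken to denote a **gene/gene-product (GGP) class** unifying them.
Relation annotations (component–whole, member–collection,
entity–location, variants, is-a) connect such names to other domain-term
classes. Formalizing those relations naively at the class level — `C ⊑
∃II-R.D` for a class-level statement `CC-R(C, D)` — is unsound precisely
when `C` is a GGP class, because the relation typically holds for one
molecular kind only. The package encodes the repair as two ontology
design patterns over a relation taxonomy, a converter to OWL 2, and a
finite-model checker.

### GGP classes

A GGP class `G_C` is defined from a seed class `C` (assumed to be a
subclass of `DNA`) as the union of `C`, everything transcribed from an
instance of `C`, and everything translated from something transcribed
from an instance of `C`:

```
G_C ≡ C ⊔ ∃transcribed-from.C ⊔ ∃translated-from.∃transcribed-from.C
```

`transcribed-from` / `translated-from` are the Sequence Ontology
derivation primitives between individuals. Mentions grouped by
equivalence links form one GGP class; its DNA-typed member (if any) is
the seed. Groups without a DNA member stay *primitive* subclasses of the
`GGP` class — the converter never invents DNA classes for them, so their
extensions are constrained only from below.

### Relation taxonomy

Relations carry a level prefix: `II-` between individuals, `CC-` between
classes, `GGP-` for pattern-defined class relations whose first argument
is a GGP class. Axioms per relation:

| relation | axioms |
|---|---|
| `II-part-of` / `II-has-part` (inverses) | reflexive, transitive, antisymmetric |
| `II-oc-part-of` (component–object) | + strong supplementation |
| `II-proper-part-of` | irreflexive, asymmetric, transitive |
| `II-member-of` ⊑ `II-proper-part-of` | irreflexive, asymmetric, **non-transitive** |
| `II-region-of` (location) | primitive; chain axioms below |
| `II-has-variant` | reflexive, symmetric, non-transitive |
| `II-has-mutant` | irreflexive, symmetric (hence not transitive) |

`NON_TRANSITIVE` is an explicit flag meaning *transitivity is deliberately
not asserted* (membership does not chain) — never "intransitive for all
triples"; it constrains nothing at check time but is emitted as a
documentation annotation. Membership is recorded as irreflexive even
though the source characterization says "non-reflexive": asymmetry
already entails irreflexivity, so the flag set states the strengthening
explicitly. `II-proper-part-of` is defined as parthood without mutual
parthood (`x < y iff x ≤ y ∧ ¬(y ≤ x)`); on a reflexive-transitive-
antisymmetric parthood this is exactly "part minus identity". Its flag
set (irreflexive, asymmetric, transitive) is the standard strict-order
companion of such a parthood. The definition's right-to-left direction
is not first-order OWL, so it travels as a native pattern contract; the
sound direction is the sub-property axiom `II-proper-part-of ⊑
II-part-of`.

Location interacts with parthood through two property chains:
`II-part-of ∘ II-region-of ⊑ II-region-of` and `II-region-of ∘
II-part-of ⊑ II-region-of`.

Strong supplementation (*if every part of y overlaps x then y is part of
x*) is not expressible in OWL 2 DL; it is carried as a relation flag and
evaluated natively by the checker, quantifying over the individuals
participating in the relation.

Direction convention: `x II-region-of y` reads "x is located at
region/locus y"; `Object-Region` annotations map the located entity to
the first argument. Identifiers are the lowercase hyphenated relation
names; IRIs derive from a configurable prefix.

### The subclass pattern

`GGP-subclass-R(G_C, X)` (R ∈ has-part, part-of, member-of, region-of,
with primitives `II-has-part`, `II-part-of`, `II-member-of`,
`II-region-of`) is the **axiom disjunction** over the kinds `K ∈ {DNA,
RNA, Protein}`:

```
  ⋁_K  [ (G_C ⊓ K) ⊑ ∃II-R.X ]
```

A disjunction of axioms is not OWL syntax. The emitted reformulation
uses the universal (top) object property: `∃top.C` is everything iff `C`
is nonempty, so

```
  ⨅_K ∃top.(G_C ⊓ K ⊓ ¬∃II-R.X)  ⊑  ⊥
```

is violated exactly when *every* kind has a counterexample instance,
i.e. when the disjunction fails. The converter emits both the OWL
reformulation and a machine-readable contract; the checker evaluates the
contract natively (the test suite proves the two coincide on all small
models). Note that a kind with empty `G_C ⊓ K` satisfies its disjunct
vacuously — the pattern is deliberately weak; its strength comes from
the kind-disjointness background.

### The variant pattern

`GGP-has-variant(G_C, D)`: every instance of the variant class `D` bears
the individual-level variance primitive to some instance of `G_C`:

```
  D ⊑ ∃II-S.(G_C ⊓ K?)       S ∈ {variant, isoform, mutant, …}
```

The kind restriction `K` per sub-relation ships as editable
configuration; only the isoform case (protein) is fixed by the source
definitions, the rest follow the same pattern with defaults chosen here:
isoform, mutant, precursor, modified-protein → `Protein`; recombinant →
`DNA`; experimental-material and the generic variant → unrestricted.
When chain relations `T_1 … T_m` are supplied the filler widens to
anything reachable from it through the chain; the chain is ordered by
default, with arbitrary permutations behind a flag
(`permute_chain=True`), since either reading is defensible.

`II-has-experimental-material` is declared but not axiomatized (its
characterization needs an ontology of experiments and is out of scope).
Protein families are plain subclasses of the term-ontology
`Protein_family_or_group` class, not formalized further.

## Conversion

Term mentions denote classes; identifiers are minted deterministically
from NFC-normalized surface strings (whitespace and punctuation to
underscore). Each mention class is subsumed under its GENIA term class;
a 30-line stub hierarchy (domain/region, family/group, complex under
their kinds) ships in-repo so nothing is downloaded. The fixed
background comprises: taxonomy declarations, hierarchy, characteristics
(with documentation annotations for antisymmetry, non-transitivity,
strong supplementation), the location chains, `DisjointClasses(DNA, RNA,
Protein)` (switchable), and the constraint `Protein_complex ⊓
∃II-has-part.DNA ⊑ ⊥` — the domain fact ("protein complexes have no
promoters as part") that makes the counterexample detectable. Each
relation-mention expansion carries its source line as axiom provenance.
Output is canonically ordered, hence byte-deterministic.

A `--generic-schema` mode converts the same documents with the naive
class-level schema on raw mention classes, for demonstrating the faulty
inferences the patterns block.

The GGP side of a relation mention is the argument that belongs to a GGP
group (an equivalence group, or a mention typed with a core kind). For
component annotations with the GGP as whole the expansion is
`GGP-subclass-has-part`; with the GGP as component, `GGP-subclass-part-of`;
if both arguments are GGPs the whole's perspective wins. Is-a
annotations map to a plain `SubClassOf` between the mention classes (the
member class of a GGP group is itself a subclass of `G_C`, so no
information is lost); a reflexive is-a is emitted with a warning
annotation, since co-extensional classes are not supposed to be
annotated.

## Finite-model checking

A model is a finite interpretation: individuals, class extensions,
relation extensions. **Closure** is the least fixpoint of the rule-like
axioms (asserted facts, symmetry, transitivity, sub-properties, property
chains, inverses, memberships forced by `SubClassOf(expr, Named)` and by
equivalences absorbing into named classes). It is idempotent and, for
the axiom shapes the converter emits, monotone; constraint axioms
(right-hand `owl:Nothing`) and complement-bearing encodings are never
used as rules. The implementation applies delta-driven set operations; a
deliberately naive full-pass fixpoint with triple loops ships as the
reference (`ggprel.reference`) and the two are compared on enumerated
and random models in the tests and the acceptance script.

**Checking is closed-world over the fixed domain**: a violation means
"not satisfied in this model", strictly stronger than OWL's open-world
entailment — the deliberate trade that yields decidable, witness-producing
verification without an external reasoner. In particular an unsatisfied
existential obligation is a violation, never repaired with an anonymous
individual: annotation verification wants witnesses, not skolems.
Reflexivity is checked over the relation's declared domain-class
extension, falling back to the relation's participating individuals
(a global reading is behind `reflexivity_global=True`): a global check
would make every sparse model trivially inconsistent.

**Canonical models.** To verify an annotation document end to end the
package builds its intended model by a deterministic chase: one
prototype individual per mention class; for seeded GGP classes the
transcription/translation chain is materialised (reusing member-class
prototypes, minting an RNA representative when no RNA mention exists);
the subclass-pattern disjunction is satisfied for one kind — preferring
the kind the target class belongs to (a promoter is DNA, so the DNA
subclass receives the part), falling back to the first inhabited kind;
plain existential obligations reuse the subject itself when it qualifies
(which is what makes a self-referential mutant annotation surface as an
irreflexivity violation), then the least existing filler member, then a
fresh individual; reflexive relations get loops over their participants.
The chase is bounded and deterministic, so conversion + verification is
reproducible bit for bit.

## Synthetic corpora

The fixture generator emulates the *annotation layer only*: short
synthetic sentences over a fixed pool of real gene symbols, one to three
mentions, one relation (or an equivalence trio) drawn uniformly from the
template grammar. It does not emulate real abstracts' length, mention
density, nested or discontinuous spans, co-reference, or any statistical
distribution of relation types — so passing tests show the formal
machinery is sound on well-formed and deliberately broken annotations,
not that the converter meets a corpus-scale recall target. Corruptions
come from a typed menu with ground-truth labels: a mutant relation whose
arguments denote the same class (→ irreflexivity), a two-cycle of
membership (→ asymmetry/antisymmetry), one surface typed as two disjoint
kinds (→ disjointness), and a dangling argument reference (→ validation
error). Sensitivity (every injected corruption flagged with its expected
category) and specificity (zero violations at corruption rate 0) are
asserted in the tests and measured by the acceptance script.

## OWL serialization

Primary output is OWL 2 functional syntax — line-oriented, canonically
ordered, byte-deterministic — with Turtle (standard OWL-to-RDF mapping
via rdflib) as alternate. A property is **non-simple** when it is
transitive or concludes a property chain, or reaches such a property
upward through sub-property/inverse links; reflexivity, irreflexivity,
symmetry and asymmetry characteristics on non-simple properties are
dropped from OWL output and recorded as annotation comments (so
reflexivity of `II-part-of` is documentation, not an OWL axiom — OWL 2
DL forbids it there). Imports of the Sequence Ontology and the GENIA
term ontology are IRI references only; stub files with the needed
entities ship in `ontologies/`. The bundled parser reads back exactly
the emitted dialect and reports character positions on errors; it is not
a general OWL parser.

## Problem sizes and numerical choices

Small-scope comparison runs exhaustively over all models with ≤ 2
individuals on a 2-class/2-relation vocabulary (4,113 models) and all
models with 3 individuals on a 1-class/1-relation vocabulary (4,096),
plus 1,000 seeded random models of size ≤ 5 — chosen as the largest
spaces a desk-scale exhaustive sweep covers meaningfully (the
3-individual/2-class/2-relation space alone has 2^24 models, with no
additional rule interactions to reveal). The model enumerator guards at
2^22. Synthetic-corpus measurements use 200 clean and 120 fully
corrupted documents. Equivalence groups are merged transitively before
grouping; mention classes colliding on surface strings merge silently
(that collision is also the mutant-self-loop corruption). Ties in the
chase are broken by lexicographic order throughout.

## Known limitations

* Closed-world checking rejects models that open-world OWL reasoning
  would accept (missing existential witnesses); the OWL export exists
  precisely so a standard DL reasoner can be used when open-world
  semantics is wanted.
* The chase builds *one* intended model; a document satisfiable only by
  a model the chase heuristics do not construct would be reported as
  violated. The heuristics cover the shipped annotation patterns.
* Event annotations (binding etc.) and the integration with upper-level
  ontologies are out of scope; `Protein family` has no internal
  mereology.
* The annotation label vocabulary of released corpora is configuration
  (`relation_map.yaml`), not code; the shipped left-hand labels are this
  repository's conventions.
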