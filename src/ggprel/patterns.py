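"""The ontology design patterns and formal definitions, as IR expansions.

The heart of the formalization: relations annotated between an ambiguous
gene/gene-product (GGP) class and another class cannot be defined with the
generic class-level schema ``C SubClassOf (II-R some D)`` — a GGP class
unifies the DNA, RNA and protein classes of a gene, and the relation
typically holds for exactly one of these kinds (a promoter is part of the
gene's DNA, not of its protein).  Two design patterns repair this:

* the **subclass pattern**: at least one kind-restricted subclass of the
  GGP class stands, instance-wise, in the underlying individual-level
  relation to the target class — an axiom *disjunction* over the kinds,
  reformulated for OWL with the universal property and ``owl:Nothing``;
* the **variant pattern**: every instance of the variant class bears the
  individual-level variance relation to some instance of the GGP class
  (possibly restricted to one kind, e.g. isoforms to the protein subclass).

The GGP class itself is defined from a seed DNA class through chains of
transcription and translation between individuals.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from .axioms import (
    TOP_PROPERTY, AnnotationAssertion, Axiom, Complement, Declaration,
    EquivalentClasses, Exists, Intersection, Named, NOTHING, PatternContract,
    SubClassOf, SubPropertyChain, SubPropertyOf, Union)
from .relations import (
    GGP_CLASS, RelationTaxonomy, TRANSCRIBED_FROM, TRANSLATED_FROM)
from .termstub import KIND_CLASSES


class ConfigurationError(ValueError):
    pass


DEFAULT_KINDS: Tuple[str, ...] = KIND_CLASSES

#: Which variant sub-relations restrict the GGP filler to one kind-subclass.
#: Only the isoform case is fixed by definition (protein isoforms); the
#: remaining entries are editable defaults following the same pattern:
#: mutants, precursors and modified proteins are proteins, recombinants are
#: DNA constructs, experimental material is unrestricted.
DEFAULT_KIND_RESTRICTION: Dict[str, Optional[str]] = {
    "GGP-has-variant": None,
    "GGP-has-isoform": "Protein",
    "GGP-has-mutant": "Protein",
    "GGP-has-precursor": "Protein",
    "GGP-has-modified-protein": "Protein",
    "GGP-has-recombinant": "DNA",
    "GGP-has-experimental-material": None,
}


@dataclass(frozen=True)
class GgpClass:
    """A gene/gene-product class grouped from equivalent mentions.

    ``members`` pairs each member class identifier with its GENIA term
    class; ``seed_dna_class`` is the member typed exactly ``DNA`` that
    seeds the transcription/translation construction, if one exists.
    """

    id: str
    seed_dna_class: Optional[str]
    members: Tuple[Tuple[str, str], ...]  # (class id, term class)

    @property
    def member_term_classes(self) -> frozenset:
        return frozenset(tc for _, tc in self.members)

    def member_classes_of_kind(self, kind_of, kind: str) -> List[str]:
        return sorted(c for c, tc in self.members if kind_of(tc) == kind)


@dataclass(frozen=True)
class PatternInstance:
    """One application of a design pattern to a relation mention."""

    ggp_class: str
    relation: str                       # GGP-level relation identifier
    target: str                         # target class identifier
    kinds: Tuple[str, ...] = DEFAULT_KINDS
    chain_relations: Tuple[str, ...] = ()
    source: Optional[str] = None


# ---------------------------------------------------------------------------
# Formula expansions
# ---------------------------------------------------------------------------

def define_ggp_class(g: GgpClass, tax: RelationTaxonomy,
                     kind_of=None) -> List[Axiom]:
    """Define a GGP class from its seed DNA class.

    An individual belongs to ``G_C`` iff it is an instance of the seed
    ``C``, or transcribed from some instance of ``C``, or translated from
    something transcribed from some instance of ``C``::

        EquivalentClasses(G_C,
            C or (transcribed-from some C)
              or (translated-from some (transcribed-from some C)))

    GGP classes without a DNA-typed member stay primitive subclasses of
    ``GGP`` (the conversion never invents DNA classes).
    """
    from .termstub import kind_of as default_kind_of
    kind_of = kind_of or default_kind_of
    for rel in (TRANSCRIBED_FROM, TRANSLATED_FROM):
        if rel not in tax:
            raise ConfigurationError(
                f"taxonomy lacks the imported primitive {rel!r} needed for "
                f"the GGP class construction")
    out: List[Axiom] = [
        Declaration("Class", g.id),
        SubClassOf(Named(g.id), Named(GGP_CLASS)),
    ]
    for member, _tc in g.members:
        if member != g.id:
            out.append(SubClassOf(Named(member), Named(g.id)))
    if g.seed_dna_class is not None:
        seed = g.seed_dna_class
        out.append(EquivalentClasses([
            Named(g.id),
            Union([
                Named(seed),
                Exists(TRANSCRIBED_FROM, Named(seed)),
                Exists(TRANSLATED_FROM, Exists(TRANSCRIBED_FROM, Named(seed))),
            ]),
        ]))
        out.append(PatternContract.create("ggp-equivalence", {
            "anchor": g.id,
            "ggp": g.id,
            "seed": seed,
            "transcribed_from": TRANSCRIBED_FROM,
            "translated_from": TRANSLATED_FROM,
            "rna_members": g.member_classes_of_kind(kind_of, "RNA"),
            "protein_members": g.member_classes_of_kind(kind_of, "Protein"),
        }))
    return out


def convert_subclass_relation(sub: str, sup: str,
                              source: Optional[str] = None) -> List[Axiom]:
    """The is-a relation between denoted classes: every instance of the
    subclass is an instance of the superclass."""
    out: List[Axiom] = [SubClassOf(Named(sub), Named(sup), source=source)]
    if sub == sup:
        out.append(AnnotationAssertion(
            sub, "warning: reflexive is-a annotation — identical "
                 "(co-extensional) classes are not annotated", source=source))
    return out


def expand_subclass_pattern(p: PatternInstance,
                            tax: RelationTaxonomy) -> List[Axiom]:
    """Subclass pattern: the axiom disjunction over the molecular kinds.

    Contract (evaluated natively by the model checker): for at least one
    kind ``K`` among ``p.kinds``, every instance of ``G_C and K`` has an
    ``II-R`` successor in the target class.  A disjunction of axioms is
    not OWL syntax, so the emitted OWL reformulation uses the universal
    (top) property and a single subclass axiom with ``owl:Nothing``::

        (top some (G and K1 and not (II-R some X)))
          and ... and
        (top some (G and Kn and not (II-R some X)))   SubClassOf   Nothing

    ``top some C`` is everything iff ``C`` is nonempty, so the left side
    is nonempty exactly when *every* kind-restricted subclass has a
    counterexample instance — i.e. when the disjunction fails.
    """
    spec = tax.specs.get(p.relation)
    if spec is None or spec.defined_from is None or spec.defined_from not in tax:
        raise ConfigurationError(
            f"{p.relation!r} does not resolve to an II-level primitive")
    if not p.kinds:
        raise ConfigurationError("subclass pattern needs a nonempty kind list")
    prim = spec.defined_from
    g, x = Named(p.ggp_class), Named(p.target)
    contract = PatternContract.create("subclass-pattern", {
        "anchor": p.ggp_class,
        "ggp": p.ggp_class,
        "relation": p.relation,
        "primitive": prim,
        "target": p.target,
        "kinds": list(p.kinds),
    }, source=p.source)
    encoding = SubClassOf(
        Intersection([
            Exists(TOP_PROPERTY,
                   Intersection([g, Named(k),
                                 Complement(Exists(prim, x))]))
            for k in p.kinds
        ]),
        NOTHING,
        source=(p.source or "pattern") + "#encoding")
    return [contract, encoding]


def expand_variant_pattern(p: PatternInstance, tax: RelationTaxonomy,
                           kind_restriction: Optional[Dict[str, Optional[str]]] = None,
                           *, permute_chain: bool = False) -> List[Axiom]:
    """Variant pattern: every instance of the variant class is a variant
    of some instance of the GGP class.

    For kind-restricted sub-relations (isoforms, mutants, precursors,
    modified proteins, recombinants) the filler is the kind-restricted
    subclass ``G_C and K``.  When ``chain_relations`` are given, the
    filler widens to anything reachable from it by the (ordered, or with
    ``permute_chain`` any permutation of the) chain of relations.
    """
    restriction = DEFAULT_KIND_RESTRICTION if kind_restriction is None else kind_restriction
    spec = tax.specs.get(p.relation)
    if spec is None or spec.defined_from is None or spec.defined_from not in tax:
        raise ConfigurationError(
            f"{p.relation!r} has no configured II-level variance primitive")
    if p.relation not in restriction:
        raise ConfigurationError(
            f"{p.relation!r} missing from the kind-restriction table")
    prim = spec.defined_from
    kind = restriction[p.relation]
    filler: object = Named(p.ggp_class)
    if kind is not None:
        filler = Intersection([Named(p.ggp_class), Named(kind)])
    if p.chain_relations:
        def wrap(order: Sequence[str]):
            e = filler
            for rel in reversed(order):
                e = Exists(rel, e)
            return e
        orders = (list(itertools.permutations(p.chain_relations))
                  if permute_chain else [p.chain_relations])
        filler = Union([filler] + [wrap(o) for o in orders])
    contract = PatternContract.create("variant-pattern", {
        "anchor": p.target,
        "ggp": p.ggp_class,
        "relation": p.relation,
        "primitive": prim,
        "target": p.target,
        "kind": kind,
    }, source=p.source)
    return [contract,
            SubClassOf(Named(p.target), Exists(prim, filler), source=p.source)]


def proper_part_axioms() -> List[Axiom]:
    """Proper parthood: part of, excluding mutual parthood.

    ``x II-proper-part-of y  iff  x II-part-of y and not y II-part-of x``.
    The right-to-left direction is not first-order expressible in OWL, so
    the definition is carried as a native pattern contract; the sound
    direction (every proper part is a part) is a sub-property axiom.
    """
    return [
        SubPropertyOf("II-proper-part-of", "II-part-of"),
        PatternContract.create("proper-part-def", {
            "anchor": "II-proper-part-of",
            "relation": "II-proper-part-of",
            "base": "II-part-of",
        }),
    ]


def location_chain_axioms() -> List[Axiom]:
    """Location propagates along parthood, in both compositions: a part of
    something located at z is located at z, and something located inside a
    part of z is located at z."""
    return [
        SubPropertyChain(["II-part-of", "II-region-of"], "II-region-of"),
        SubPropertyChain(["II-region-of", "II-part-of"], "II-region-of"),
    ]
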