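"""The GENIA relation taxonomy: relations, levels, and their axioms.

Relations come in three levels:

* ``II``  — relations between individuals (the primitives: ``II-part-of``,
  ``II-member-of``, ``II-region-of``, ``II-has-variant`` and friends);
* ``CC``  — relations between classes, defined generically as
  ``C SubClassOf (II-R some D)``;
* ``GGP`` — relations whose first argument is an ambiguous gene/gene-product
  class; these are defined through the subclass and variant design patterns
  and each records the II-level primitive its definition uses
  (``defined_from``).

Axiom flags capture the formal properties asserted for each relation.
``NON_TRANSITIVE`` records a deliberate *non-assertion* of transitivity
(membership in a collection does not chain), not intransitivity for all
triples.  ``STRONG_SUPPLEMENTATION`` marks the extensional-mereology
principle assumed for component-object parthood: if every part of *y*
overlaps *x*, then *y* is part of *x*.
"""

from __future__ import annotations

import enum
import itertools
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterator, List, Optional, Tuple

import yaml


class AxiomFlag(enum.Enum):
    REFLEXIVE = "reflexive"
    IRREFLEXIVE = "irreflexive"
    SYMMETRIC = "symmetric"
    ASYMMETRIC = "asymmetric"
    ANTISYMMETRIC = "antisymmetric"
    TRANSITIVE = "transitive"
    NON_TRANSITIVE = "non-transitive"
    STRONG_SUPPLEMENTATION = "strong-supplementation"


F = AxiomFlag


@dataclass(frozen=True)
class RelationSpec:
    """One relation of the taxonomy.

    ``domain_class`` / ``range_class`` are class identifiers or ``None``
    for unrestricted; ``parent`` points to the super-relation;
    ``defined_from`` names the II-level primitive a defined relation's
    pattern expansion uses; ``inverse_of`` links converse primitives
    (``II-has-part`` is the inverse of ``II-part-of``).
    """

    name: str
    level: str  # "II" | "CC" | "GGP"
    flags: FrozenSet[AxiomFlag] = frozenset()
    domain_class: Optional[str] = None
    range_class: Optional[str] = None
    parent: Optional[str] = None
    defined_from: Optional[str] = None
    inverse_of: Optional[str] = None


@dataclass(frozen=True)
class FlagConflict:
    kind: str  # "contradictory-pair" | "forced-empty" | "unsatisfiable"
    flags: Tuple[AxiomFlag, ...]
    message: str


class TaxonomyError(ValueError):
    pass


@dataclass
class RelationTaxonomy:
    specs: Dict[str, RelationSpec] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._validate()

    # -- access ------------------------------------------------------------
    def __getitem__(self, name: str) -> RelationSpec:
        return self.specs[name]

    def __contains__(self, name: str) -> bool:
        return name in self.specs

    def __iter__(self) -> Iterator[RelationSpec]:
        return iter(self.specs.values())

    @property
    def roots(self) -> List[str]:
        return sorted(n for n, s in self.specs.items() if s.parent is None)

    def children(self, name: str) -> List[str]:
        return sorted(n for n, s in self.specs.items() if s.parent == name)

    def ancestors(self, name: str) -> List[str]:
        out: List[str] = []
        cur = self.specs[name].parent
        while cur is not None:
            out.append(cur)
            cur = self.specs[cur].parent
        return out

    def flags_of(self, name: str) -> FrozenSet[AxiomFlag]:
        spec = self.specs.get(name)
        return spec.flags if spec else frozenset()

    # -- validation --------------------------------------------------------
    def _validate(self) -> None:
        for name, spec in self.specs.items():
            if spec.parent is not None and spec.parent not in self.specs:
                raise TaxonomyError(f"{name}: parent {spec.parent!r} not in taxonomy")
            if spec.defined_from is not None:
                tgt = self.specs.get(spec.defined_from)
                if tgt is None or tgt.level != "II":
                    raise TaxonomyError(
                        f"{name}: defined_from {spec.defined_from!r} does not "
                        f"resolve to an II-level relation")
            if spec.level == "GGP" and spec.defined_from is None:
                raise TaxonomyError(f"{name}: GGP-level relation lacks defined_from")
            if spec.inverse_of is not None and spec.inverse_of not in self.specs:
                raise TaxonomyError(f"{name}: inverse {spec.inverse_of!r} not in taxonomy")
        # parent links must form a forest
        for name in self.specs:
            seen = {name}
            cur = self.specs[name].parent
            while cur is not None:
                if cur in seen:
                    raise TaxonomyError(f"cycle in parent links through {name!r}")
                seen.add(cur)
                cur = self.specs[cur].parent

    # -- export ------------------------------------------------------------
    def to_yaml(self) -> str:
        doc = {}
        for name in sorted(self.specs):
            s = self.specs[name]
            entry: dict = {"level": s.level,
                           "flags": sorted(f.value for f in s.flags)}
            if s.parent:
                entry["parent"] = s.parent
            if s.defined_from:
                entry["defined_from"] = s.defined_from
            if s.inverse_of:
                entry["inverse_of"] = s.inverse_of
            if s.domain_class:
                entry["domain"] = s.domain_class
            if s.range_class:
                entry["range"] = s.range_class
            doc[name] = entry
        return yaml.safe_dump(doc, sort_keys=True)

    def tree_str(self) -> str:
        lines: List[str] = []

        def walk(name: str, depth: int) -> None:
            s = self.specs[name]
            flags = ", ".join(sorted(f.value for f in s.flags)) or "-"
            lines.append("  " * depth + f"{name} [{s.level}] ({flags})")
            for child in self.children(name):
                walk(child, depth + 1)

        for root in self.roots:
            walk(root, 0)
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# The shipped taxonomy
# ---------------------------------------------------------------------------

#: Imported Sequence Ontology primitives used by the gene/gene-product
#: class construction (an RNA is transcribed from a DNA template; a protein
#: is translated from an RNA).
TRANSCRIBED_FROM = "transcribed-from"
TRANSLATED_FROM = "translated-from"

GGP_CLASS = "GGP"


def build_genia_taxonomy() -> RelationTaxonomy:
    """The complete shipped relation taxonomy.

    Individual-level mereology: ``II-part-of`` is reflexive, transitive and
    antisymmetric; component-object parthood ``II-oc-part-of`` additionally
    satisfies strong supplementation; ``II-proper-part-of`` is parthood
    minus mutual parthood; ``II-member-of`` (collection membership) is a
    sub-relation of proper parthood, irreflexive, asymmetric, and
    deliberately not transitive.  ``II-region-of`` (location) is primitive.
    Variance: ``II-has-variant`` is reflexive and symmetric but not assumed
    transitive; ``II-has-mutant`` is irreflexive and symmetric (hence not
    transitive).  The GGP-level relations are the pattern-defined class
    relations, each tied to its individual-level primitive.
    """
    specs: List[RelationSpec] = [
        # --- individual-level mereology ---
        RelationSpec("II-part-of", "II",
                     frozenset({F.REFLEXIVE, F.TRANSITIVE, F.ANTISYMMETRIC}),
                     inverse_of="II-has-part"),
        RelationSpec("II-has-part", "II",
                     frozenset({F.REFLEXIVE, F.TRANSITIVE, F.ANTISYMMETRIC}),
                     inverse_of="II-part-of"),
        RelationSpec("II-oc-part-of", "II",
                     frozenset({F.REFLEXIVE, F.TRANSITIVE, F.ANTISYMMETRIC,
                                F.STRONG_SUPPLEMENTATION}),
                     parent="II-part-of"),
        RelationSpec("II-proper-part-of", "II",
                     frozenset({F.IRREFLEXIVE, F.ASYMMETRIC, F.TRANSITIVE}),
                     parent="II-part-of", defined_from="II-part-of"),
        RelationSpec("II-member-of", "II",
                     frozenset({F.IRREFLEXIVE, F.ASYMMETRIC, F.NON_TRANSITIVE}),
                     parent="II-proper-part-of"),
        RelationSpec("II-region-of", "II", frozenset()),
        # --- individual-level variance ---
        RelationSpec("II-has-variant", "II",
                     frozenset({F.REFLEXIVE, F.SYMMETRIC, F.NON_TRANSITIVE})),
        RelationSpec("II-has-modified-protein", "II", frozenset(),
                     parent="II-has-variant"),
        RelationSpec("II-has-isoform", "II", frozenset(), parent="II-has-variant"),
        RelationSpec("II-has-mutant", "II",
                     frozenset({F.IRREFLEXIVE, F.SYMMETRIC, F.NON_TRANSITIVE}),
                     parent="II-has-variant"),
        RelationSpec("II-has-recombinant", "II", frozenset(), parent="II-has-variant"),
        RelationSpec("II-has-precursor", "II", frozenset(), parent="II-has-variant"),
        # declared only; its formal characterization is out of scope
        RelationSpec("II-has-experimental-material", "II", frozenset(),
                     parent="II-has-variant"),
        # --- imported Sequence Ontology primitives (formula backbone) ---
        RelationSpec(TRANSCRIBED_FROM, "II", frozenset(), range_class="DNA"),
        RelationSpec(TRANSLATED_FROM, "II", frozenset(), range_class="RNA"),
        # --- class-level generic parthood ---
        RelationSpec("CC-part-of", "CC", frozenset()),
        RelationSpec("CC-has-part", "CC", frozenset()),
        # --- GGP-level pattern-defined relations ---
        RelationSpec("GGP-subclass-has-part", "GGP", frozenset(),
                     domain_class=GGP_CLASS, defined_from="II-has-part"),
        RelationSpec("GGP-subclass-part-of", "GGP", frozenset(),
                     domain_class=GGP_CLASS, defined_from="II-part-of"),
        RelationSpec("GGP-subclass-member-of", "GGP", frozenset(),
                     domain_class=GGP_CLASS, defined_from="II-member-of"),
        RelationSpec("GGP-subclass-region-of", "GGP", frozenset(),
                     domain_class=GGP_CLASS, defined_from="II-region-of"),
        RelationSpec("GGP-has-variant", "GGP", frozenset(),
                     domain_class=GGP_CLASS, defined_from="II-has-variant"),
        RelationSpec("GGP-has-modified-protein", "GGP", frozenset(),
                     domain_class=GGP_CLASS, parent="GGP-has-variant",
                     defined_from="II-has-modified-protein"),
        RelationSpec("GGP-has-isoform", "GGP", frozenset(),
                     domain_class=GGP_CLASS, parent="GGP-has-variant",
                     defined_from="II-has-isoform"),
        RelationSpec("GGP-has-mutant", "GGP", frozenset(),
                     domain_class=GGP_CLASS, parent="GGP-has-variant",
                     defined_from="II-has-mutant"),
        RelationSpec("GGP-has-recombinant", "GGP", frozenset(),
                     domain_class=GGP_CLASS, parent="GGP-has-variant",
                     defined_from="II-has-recombinant"),
        RelationSpec("GGP-has-precursor", "GGP", frozenset(),
                     domain_class=GGP_CLASS, parent="GGP-has-variant",
                     defined_from="II-has-precursor"),
        RelationSpec("GGP-has-experimental-material", "GGP", frozenset(),
                     domain_class=GGP_CLASS, parent="GGP-has-variant",
                     defined_from="II-has-experimental-material"),
    ]
    return RelationTaxonomy({s.name: s for s in specs})


#: GGP-level relations realising the three kinds of parthood (component,
#: membership, location).
PARTHOOD_GGP_RELATIONS = (
    "GGP-subclass-has-part",  # component (whole side)
    "GGP-subclass-member-of",
    "GGP-subclass-region-of",
)

#: The sub-relations of GGP-has-variant (one per variance relationship
#: distinguished in the annotation).
VARIANT_SUBRELATIONS = (
    "GGP-has-modified-protein",
    "GGP-has-isoform",
    "GGP-has-mutant",
    "GGP-has-recombinant",
    "GGP-has-precursor",
    "GGP-has-experimental-material",
)


# ---------------------------------------------------------------------------
# Flag consistency
# ---------------------------------------------------------------------------

_CONTRADICTORY_PAIRS = (
    (F.REFLEXIVE, F.IRREFLEXIVE),
    (F.SYMMETRIC, F.ASYMMETRIC),
)


def _satisfies(rel: FrozenSet[Tuple[int, int]], flags: FrozenSet[AxiomFlag],
               domain: Tuple[int, ...]) -> bool:
    if F.REFLEXIVE in flags and any((x, x) not in rel for x in domain):
        return False
    if F.IRREFLEXIVE in flags and any((x, x) in rel for x in domain):
        return False
    if F.SYMMETRIC in flags and any((y, x) not in rel for (x, y) in rel):
        return False
    if F.ASYMMETRIC in flags and any((y, x) in rel for (x, y) in rel):
        return False
    if F.ANTISYMMETRIC in flags and any(
            x != y and (y, x) in rel for (x, y) in rel):
        return False
    if F.TRANSITIVE in flags and any(
            (x, z) not in rel for (x, y) in rel for (y2, z) in rel if y == y2):
        return False
    return True


def validate_flags(spec: RelationSpec) -> List[FlagConflict]:
    """Check that a relation's axiom flags are jointly satisfiable.

    Returns an empty list iff some *nonempty* relation on a 2-element
    domain satisfies every flag; conflicts are returned as data, naming the
    offending flag pairs.  A flag set that admits only the empty relation
    (e.g. symmetric + antisymmetric + irreflexive) is reported as
    ``forced-empty``.
    """
    conflicts: List[FlagConflict] = []
    for a, b in _CONTRADICTORY_PAIRS:
        if a in spec.flags and b in spec.flags:
            conflicts.append(FlagConflict(
                "contradictory-pair", (a, b),
                f"{spec.name}: {a.value} and {b.value} cannot both hold on a "
                f"nonempty domain"))
    if conflicts:
        return conflicts

    domain = (0, 1)
    pairs = tuple(itertools.product(domain, domain))
    satisfying = []
    for bits in itertools.product((False, True), repeat=len(pairs)):
        rel = frozenset(p for p, keep in zip(pairs, bits) if keep)
        if _satisfies(rel, spec.flags, domain):
            satisfying.append(rel)
    if not satisfying:
        conflicts.append(FlagConflict(
            "unsatisfiable", tuple(sorted(spec.flags, key=lambda f: f.value)),
            f"{spec.name}: no relation on a 2-element domain satisfies the flags"))
    elif all(not rel for rel in satisfying):
        conflicts.append(FlagConflict(
            "forced-empty", tuple(sorted(spec.flags, key=lambda f: f.value)),
            f"{spec.name}: relation forced empty — only the empty relation "
            f"satisfies the flags on a 2-element domain"))
    return conflicts
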