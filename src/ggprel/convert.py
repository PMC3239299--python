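"""Conversion of annotated abstracts into axiom sets.

Every term mention denotes a class (minted deterministically from the
normalized surface string); equivalence links group mentions into
gene/gene-product (GGP) classes; each relation mention expands through the
design pattern matching its mapped formal relation.  The fixed background
carries the relation characteristics, the location-propagation chains, the
kind disjointness (DNA/RNA/Protein) and the "protein complexes have no DNA
parts" constraint — the background knowledge that lets the checker catch
the classic faulty inference (a promoter derived to be part of a protein
complex) under the generic class-level parthood schema, while the GGP
subclass pattern blocks it.

The annotation label vocabulary is not hard-coded: a YAML mapping takes
annotation labels to conversion rules; the shipped default covers every
relation of the taxonomy (the left-hand label strings are repo
conventions).
"""

from __future__ import annotations

import re
import unicodedata
from typing import Dict, List, Optional, Sequence, Tuple

import yaml

from .axioms import (
    AnnotationAssertion, Axiom, Declaration, DisjointClasses, Exists,
    Intersection, Named, NOTHING, SubClassOf, SubPropertyOf,
    InverseProperties, TransitiveProperty, SymmetricProperty,
    AsymmetricProperty, ReflexiveProperty, IrreflexiveProperty,
    canonical_sort)
from .checker import FiniteModel, ViolationReport, build_canonical_model, check
from .patterns import (
    DEFAULT_KINDS, GgpClass, PatternInstance, convert_subclass_relation,
    define_ggp_class, expand_subclass_pattern, expand_variant_pattern,
    location_chain_axioms)
from .relations import AxiomFlag, RelationTaxonomy, GGP_CLASS
from .standoff import AbstractAnnotation
from .termstub import BUILTIN_CLASSES, KIND_CLASSES, TERM_HIERARCHY, stub_axioms


class MappingError(ValueError):
    def __init__(self, label: str, where: str):
        super().__init__(f"unmapped relation label {label!r} at {where}")
        self.label = label
        self.where = where


# ---------------------------------------------------------------------------
# Relation label mapping
# ---------------------------------------------------------------------------

#: Default annotation-label mapping (label strings are repo conventions;
#: the released corpus labels are configurable through the YAML file).
DEFAULT_RELATION_MAP: Dict[str, Dict[str, str]] = {
    "Object-Component": {"type": "component"},
    "Member-Collection": {"type": "member"},
    "Object-Region": {"type": "region"},
    "Subclass": {"type": "subclass"},
    "Object-Variant": {"type": "variant", "relation": "GGP-has-variant"},
    "Object-Variant:Modified-Protein": {
        "type": "variant", "relation": "GGP-has-modified-protein"},
    "Object-Variant:Isoform": {"type": "variant", "relation": "GGP-has-isoform"},
    "Object-Variant:Mutant": {"type": "variant", "relation": "GGP-has-mutant"},
    "Object-Variant:Recombinant": {
        "type": "variant", "relation": "GGP-has-recombinant"},
    "Object-Variant:Precursor": {"type": "variant", "relation": "GGP-has-precursor"},
    "Object-Variant:Experimental-Material": {
        "type": "variant", "relation": "GGP-has-experimental-material"},
}


def load_relation_map(path: str) -> Dict[str, Dict[str, str]]:
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: relation map must be a mapping")
    return {str(k): dict(v) for k, v in data.items()}


def dump_default_relation_map() -> str:
    return yaml.safe_dump(DEFAULT_RELATION_MAP, sort_keys=True)


# ---------------------------------------------------------------------------
# Class identifier minting
# ---------------------------------------------------------------------------

_WS = re.compile(r"\s+")
_BAD = re.compile(r"[^0-9A-Za-z_\-]")
_SQUEEZE = re.compile(r"__+")


def mint_class_id(surface: str) -> str:
    """Deterministic class identifier from a normalized surface string."""
    s = unicodedata.normalize("NFC", surface).strip()
    s = _WS.sub("_", s)
    s = _BAD.sub("_", s)
    s = _SQUEEZE.sub("_", s).strip("_")
    return s or "unnamed"


def ggp_class_id(member_class_ids: Sequence[str]) -> str:
    rep = min(member_class_ids, key=lambda c: (len(c), c))
    return f"G_{rep}"


# ---------------------------------------------------------------------------
# GGP grouping
# ---------------------------------------------------------------------------

def _is_ggp_mention(term_class: str) -> bool:
    # named-entity GGP mentions carry one of the core molecular kinds;
    # domain/region, family/group and complex terms denote other entities
    return term_class in KIND_CLASSES


def _group_mentions(a: AbstractAnnotation) -> List[List[str]]:
    grouped: Dict[str, int] = {}
    groups: List[List[str]] = []
    for link in a.equivs:
        members = sorted(link.members)
        groups.append(members)
        for tid in members:
            grouped[tid] = len(groups) - 1
    for t in a.terms:
        if t.id not in grouped and _is_ggp_mention(t.term_class):
            groups.append([t.id])
    return groups


def build_ggp_classes(a: AbstractAnnotation,
                      rel_map: Optional[Dict[str, Dict[str, str]]] = None
                      ) -> List[GgpClass]:
    """Group mentions into GGP classes: one per (transitively merged)
    equivalence group, plus one per ungrouped core-kind-typed mention."""
    return _build_ggp_index(a)[0]


def _build_ggp_index(a: AbstractAnnotation
                     ) -> Tuple[List[GgpClass], Dict[str, GgpClass]]:
    by_id = {t.id: t for t in a.terms}
    ggps: List[GgpClass] = []
    index: Dict[str, GgpClass] = {}
    for group in _group_mentions(a):
        members = sorted({(mint_class_id(by_id[tid].surface),
                           by_id[tid].term_class) for tid in group})
        class_ids = [c for c, _ in members]
        dna = sorted(c for c, tc in members if tc == "DNA")
        g = GgpClass(ggp_class_id(class_ids), dna[0] if dna else None,
                     tuple(members))
        ggps.append(g)
        for tid in group:
            index[tid] = g
    ggps.sort(key=lambda g: g.id)
    return ggps, index


# ---------------------------------------------------------------------------
# Background axioms
# ---------------------------------------------------------------------------

_FLAG_AXIOMS = {
    AxiomFlag.TRANSITIVE: TransitiveProperty,
    AxiomFlag.SYMMETRIC: SymmetricProperty,
    AxiomFlag.ASYMMETRIC: AsymmetricProperty,
    AxiomFlag.REFLEXIVE: ReflexiveProperty,
    AxiomFlag.IRREFLEXIVE: IrreflexiveProperty,
}

_FLAG_NOTES = {
    AxiomFlag.ANTISYMMETRIC: "antisymmetric (no OWL 2 characteristic exists)",
    AxiomFlag.NON_TRANSITIVE: "transitivity deliberately not asserted",
    AxiomFlag.STRONG_SUPPLEMENTATION:
        "satisfies strong supplementation (checked natively; not "
        "first-order expressible in OWL 2 DL)",
}


def taxonomy_axioms(tax: RelationTaxonomy) -> List[Axiom]:
    """Declarations, hierarchy and characteristics of the relation taxonomy."""
    out: List[Axiom] = []
    seen_inverse = set()
    for spec in sorted(tax, key=lambda s: s.name):
        out.append(Declaration("ObjectProperty", spec.name))
        if spec.parent:
            out.append(SubPropertyOf(spec.name, spec.parent))
        if spec.inverse_of and frozenset((spec.name, spec.inverse_of)) not in seen_inverse:
            seen_inverse.add(frozenset((spec.name, spec.inverse_of)))
            out.append(InverseProperties(spec.name, spec.inverse_of))
        for flag in sorted(spec.flags, key=lambda f: f.value):
            ctor = _FLAG_AXIOMS.get(flag)
            if ctor is not None:
                out.append(ctor(spec.name))
            else:
                out.append(AnnotationAssertion(spec.name, _FLAG_NOTES[flag]))
    return out


def background_axioms(tax: RelationTaxonomy, *, disjointness: bool = True,
                      complex_constraint: bool = True) -> List[Axiom]:
    out: List[Axiom] = []
    out.extend(stub_axioms())
    out.extend(taxonomy_axioms(tax))
    out.extend(location_chain_axioms())
    if disjointness:
        out.append(DisjointClasses([Named(k) for k in KIND_CLASSES]))
    if complex_constraint:
        # protein complexes have protein parts only; in particular no
        # promoters (DNA) as part
        out.append(SubClassOf(
            Intersection([Named("Protein_complex"),
                          Exists("II-has-part", Named("DNA"))]),
            NOTHING))
    return out


# ---------------------------------------------------------------------------
# Abstract conversion
# ---------------------------------------------------------------------------

def convert_abstract(a: AbstractAnnotation, tax: RelationTaxonomy,
                     rel_map: Optional[Dict[str, Dict[str, str]]] = None, *,
                     generic_schema: bool = False,
                     background: bool = True,
                     disjointness: bool = True,
                     complex_constraint: bool = True,
                     kinds: Sequence[str] = DEFAULT_KINDS) -> List[Axiom]:
    """Translate one annotated abstract into a canonically ordered axiom set.

    With ``generic_schema=True`` the GGP design patterns are bypassed and
    every parthood/membership/location/variant mention uses the generic
    class-level schema ``C SubClassOf (II-R some D)`` on the raw mention
    classes — the inadequate schema the patterns exist to replace; useful
    to demonstrate the faulty inferences it licenses.
    """
    rel_map = DEFAULT_RELATION_MAP if rel_map is None else rel_map
    out: List[Axiom] = []
    if background:
        out.extend(background_axioms(tax, disjointness=disjointness,
                                     complex_constraint=complex_constraint))

    by_id = {t.id: t for t in a.terms}
    cls: Dict[str, str] = {}
    for t in a.terms:
        c = mint_class_id(t.surface)
        cls[t.id] = c
        out.append(Declaration("Class", c))
        known = t.term_class in KIND_CLASSES or t.term_class in TERM_HIERARCHY
        if not known:
            out.append(Declaration("Class", t.term_class))
        out.append(SubClassOf(Named(c), Named(t.term_class)))

    if generic_schema:
        index: Dict[str, GgpClass] = {}
    else:
        ggps, index = _build_ggp_index(a)
        for g in ggps:
            out.extend(define_ggp_class(g, tax))

    def ggp_of(tid: str) -> Optional[str]:
        g = index.get(tid)
        return g.id if g is not None else None

    for r in a.relations:
        entry = rel_map.get(r.label)
        if entry is None:
            raise MappingError(r.label, f"{a.doc_id}:{r.id}")
        src = f"{a.doc_id}:{r.id}"
        kind = entry["type"]
        c1, c2 = cls[r.arg1], cls[r.arg2]
        g1, g2 = ggp_of(r.arg1), ggp_of(r.arg2)

        if kind == "subclass":
            out.extend(convert_subclass_relation(c1, c2, source=src))
        elif kind == "component":
            if not generic_schema and g1 is not None:
                out.extend(expand_subclass_pattern(PatternInstance(
                    g1, "GGP-subclass-has-part", c2, tuple(kinds),
                    source=src), tax))
            elif not generic_schema and g2 is not None:
                out.extend(expand_subclass_pattern(PatternInstance(
                    g2, "GGP-subclass-part-of", c1, tuple(kinds),
                    source=src), tax))
            else:
                out.append(SubClassOf(Named(c2), Exists("II-part-of", Named(c1)),
                                      source=src))
                out.append(AnnotationAssertion(
                    c2, f"generic CC-part-of / CC-has-part schema applied "
                        f"for {r.id}", source=src))
        elif kind == "member":
            if not generic_schema and g1 is not None:
                out.extend(expand_subclass_pattern(PatternInstance(
                    g1, "GGP-subclass-member-of", c2, tuple(kinds),
                    source=src), tax))
            else:
                out.append(SubClassOf(Named(c1), Exists("II-member-of", Named(c2)),
                                      source=src))
        elif kind == "region":
            if not generic_schema and g1 is not None:
                out.extend(expand_subclass_pattern(PatternInstance(
                    g1, "GGP-subclass-region-of", c2, tuple(kinds),
                    source=src), tax))
            else:
                out.append(SubClassOf(Named(c1), Exists("II-region-of", Named(c2)),
                                      source=src))
        elif kind == "variant":
            rel = entry["relation"]
            if generic_schema:
                prim = tax[rel].defined_from
                out.append(SubClassOf(Named(c2), Exists(prim, Named(c1)),
                                      source=src))
            else:
                out.extend(expand_variant_pattern(PatternInstance(
                    g1 or c1, rel, c2, source=src), tax))
        else:
            raise MappingError(r.label, f"{a.doc_id}:{r.id} (bad entry type "
                                        f"{kind!r})")
    return canonical_sort(out)


# ---------------------------------------------------------------------------
# End-to-end verification
# ---------------------------------------------------------------------------

def verify_annotation(a: AbstractAnnotation, tax: RelationTaxonomy,
                      rel_map: Optional[Dict[str, Dict[str, str]]] = None, *,
                      generic_schema: bool = False,
                      disjointness: bool = True,
                      complex_constraint: bool = True
                      ) -> Tuple[List[Axiom], FiniteModel, ViolationReport]:
    """Convert, build the canonical model, close it, and check it."""
    axioms = convert_abstract(a, tax, rel_map, generic_schema=generic_schema,
                              disjointness=disjointness,
                              complex_constraint=complex_constraint)
    model = build_canonical_model(axioms, tax, builtin_classes=BUILTIN_CLASSES)
    report = check(model, axioms, tax)
    return axioms, model, report
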