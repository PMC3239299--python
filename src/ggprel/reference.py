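"""Reference semantics: independent oracles for closure and checking.

Everything here is written as plainly as possible — full-pass fixpoints,
triple loops and direct first-order quantifier evaluation — and stays
independent of the optimized implementation paths in :mod:`ggprel.checker`.
The test suite and the acceptance script compare the two on exhaustively
enumerated and seeded-random small models.
"""

from __future__ import annotations

import itertools
from typing import Dict, List, Sequence, Set, Tuple

from .axioms import (
    TOP_PROPERTY, Axiom, ClassAssertion, Complement, DisjointClasses,
    EquivalentClasses, Exists, Intersection, InverseProperties, Named,
    Nothing, PatternContract, PropertyAssertion, SubClassOf,
    SubPropertyChain, SubPropertyOf, SymmetricProperty, Thing,
    TransitiveProperty, Union)
from .checker import FiniteModel, check, closure
from .relations import AxiomFlag as F
from .relations import RelationSpec, RelationTaxonomy


def fol_eval(m: FiniteModel, e) -> Set[str]:
    """Direct recursive evaluation of a class expression."""
    if isinstance(e, Named):
        return set(m.ext(e.id))
    if isinstance(e, Thing):
        return set(m.individuals)
    if isinstance(e, Nothing):
        return set()
    if isinstance(e, Intersection):
        out = set(m.individuals)
        for p in e.parts:
            out = {x for x in out if x in fol_eval(m, p)}
        return out
    if isinstance(e, Union):
        out = set()
        for p in e.parts:
            out |= fol_eval(m, p)
        return out
    if isinstance(e, Complement):
        return {x for x in m.individuals if x not in fol_eval(m, e.expr)}
    if isinstance(e, Exists):
        filler = fol_eval(m, e.filler)
        if e.relation == TOP_PROPERTY:
            return set(m.individuals) if filler else set()
        return {x for x in m.individuals
                if any((x, y) in m.pairs(e.relation) for y in filler)}
    raise TypeError(e)


def naive_closure(m: FiniteModel, axioms: Sequence[Axiom]) -> FiniteModel:
    """Full-recompute fixpoint: apply every rule as a complete pass until a
    whole round changes nothing."""
    out = m.copy()
    for a in axioms:
        if isinstance(a, ClassAssertion) and isinstance(a.expr, Named):
            out.add_member(a.expr.id, a.individual)
        if isinstance(a, PropertyAssertion):
            out.add_pair(a.relation, a.subject, a.object)
    while True:
        before = out.freeze()
        inds = sorted(out.individuals)
        for a in axioms:
            if isinstance(a, SymmetricProperty):
                for x, y in list(out.pairs(a.relation)):
                    out.add_pair(a.relation, y, x)
            elif isinstance(a, TransitiveProperty):
                for x, y, z in itertools.product(inds, repeat=3):
                    if (x, y) in out.pairs(a.relation) and \
                            (y, z) in out.pairs(a.relation):
                        out.add_pair(a.relation, x, z)
            elif isinstance(a, SubPropertyOf):
                for x, y in list(out.pairs(a.sub)):
                    out.add_pair(a.sup, x, y)
            elif isinstance(a, SubPropertyChain):
                for combo in itertools.product(inds, repeat=len(a.chain) + 1):
                    if all((combo[i], combo[i + 1]) in out.pairs(r)
                           for i, r in enumerate(a.chain)):
                        out.add_pair(a.sup, combo[0], combo[-1])
            elif isinstance(a, InverseProperties):
                for x, y in list(out.pairs(a.first)):
                    out.add_pair(a.second, y, x)
                for x, y in list(out.pairs(a.second)):
                    out.add_pair(a.first, y, x)
            elif isinstance(a, SubClassOf) and isinstance(a.sup, Named):
                for x in fol_eval(out, a.sub):
                    out.add_member(a.sup.id, x)
            elif isinstance(a, EquivalentClasses):
                for tgt in a.exprs:
                    if isinstance(tgt, Named):
                        for other in a.exprs:
                            if other is not tgt:
                                for x in fol_eval(out, other):
                                    out.add_member(tgt.id, x)
        if out.freeze() == before:
            return out


# ---------------------------------------------------------------------------
# Direct first-order satisfaction
# ---------------------------------------------------------------------------

def flag_satisfied(m: FiniteModel, rel: str, flag: F,
                   domain_class=None, reflexivity_global=False) -> bool:
    p = m.pairs(rel)
    if flag is F.REFLEXIVE:
        if reflexivity_global:
            dom = m.individuals
        elif domain_class is not None:
            dom = m.ext(domain_class)
        else:
            dom = m.field_of(rel)
        return all((x, x) in p for x in dom)
    if flag is F.IRREFLEXIVE:
        return all(x != y for x, y in p)
    if flag is F.SYMMETRIC:
        return all((y, x) in p for x, y in p)
    if flag is F.ASYMMETRIC:
        return all((y, x) not in p for x, y in p)
    if flag is F.ANTISYMMETRIC:
        return all(x == y or (y, x) not in p for x, y in p)
    if flag is F.TRANSITIVE:
        return all((x, z) in p
                   for x, y in p for y2, z in p if y == y2)
    if flag is F.STRONG_SUPPLEMENTATION:
        fld = m.field_of(rel)

        def overlaps(a: str, b: str) -> bool:
            return any((w, a) in p and (w, b) in p for w in fld)

        return all((y, x) in p
                   for x in fld for y in fld
                   if all(overlaps(z, x) for z in fld if (z, y) in p))
    if flag is F.NON_TRANSITIVE:
        return True  # the absence of an assertion constrains nothing
    raise ValueError(flag)


def axiom_satisfied(m: FiniteModel, a: Axiom) -> bool:
    """Direct evaluation of one axiom's first-order contract on a model."""
    if isinstance(a, SubClassOf):
        return fol_eval(m, a.sub) <= fol_eval(m, a.sup)
    if isinstance(a, DisjointClasses):
        return all(not (fol_eval(m, e1) & fol_eval(m, e2))
                   for e1, e2 in itertools.combinations(a.exprs, 2))
    if isinstance(a, EquivalentClasses):
        exts = [fol_eval(m, e) for e in a.exprs]
        return all(x == exts[0] for x in exts[1:])
    if isinstance(a, PatternContract):
        pl = a.payload
        if a.kind == "subclass-pattern":
            return subclass_pattern_holds(
                m, pl["ggp"], pl["primitive"], pl["target"], pl["kinds"])
        if a.kind == "proper-part-def":
            strict = {(x, y) for x, y in m.pairs(pl["base"])
                      if (y, x) not in m.pairs(pl["base"])}
            return m.pairs(pl["relation"]) == strict
        if a.kind == "ggp-equivalence":
            return True  # carried by the companion EquivalentClasses axiom
    raise TypeError(a)


def subclass_pattern_holds(m: FiniteModel, ggp: str, prim: str, target: str,
                           kinds) -> bool:
    """Brute-force the axiom disjunction over the kinds."""
    return any(
        all(any((x, y) in m.pairs(prim) for y in m.ext(target))
            for x in m.ext(ggp) & m.ext(kind))
        for kind in kinds)


def ggp_extension(m: FiniteModel, seed: str, tf: str, tlf: str) -> Set[str]:
    """Three-disjunct first-order evaluation of the GGP class construction."""
    return {x for x in m.individuals
            if x in m.ext(seed)
            or any((x, d) in m.pairs(tf) for d in m.ext(seed))
            or any((x, r) in m.pairs(tlf) and
                   any((r, d) in m.pairs(tf) for d in m.ext(seed))
                   for r in m.individuals)}


def enumerate_binary_relations(n: int):
    """All binary relations on an n-element domain, as frozensets."""
    dom = tuple(range(n))
    pairs = tuple(itertools.product(dom, dom))
    for bits in itertools.product((False, True), repeat=len(pairs)):
        yield frozenset(p for p, keep in zip(pairs, bits) if keep)


# ---------------------------------------------------------------------------
# Small-scope comparison harness
# ---------------------------------------------------------------------------

def smallscope_suite(classes: Sequence[str], relations: Sequence[str]
                     ) -> Tuple[List[Axiom], RelationTaxonomy]:
    """A fixed axiom suite exercising every rule and check on a small
    vocabulary: characteristics, a sub-property link, a property chain,
    disjointness, an existential obligation, a defined-class equivalence,
    the subclass-pattern disjunction and the proper-parthood definition."""
    c = list(classes)
    r = list(relations)
    axioms: List[Axiom] = [TransitiveProperty(r[0])]
    flags0 = {F.REFLEXIVE, F.TRANSITIVE, F.ANTISYMMETRIC,
              F.STRONG_SUPPLEMENTATION}
    specs = {r[0]: RelationSpec(r[0], "II", frozenset(flags0))}
    if len(r) > 1:
        axioms += [SymmetricProperty(r[1]),
                   SubPropertyOf(r[1], r[0]),
                   SubPropertyChain([r[0], r[1]], r[1])]
        specs[r[1]] = RelationSpec(
            r[1], "II", frozenset({F.SYMMETRIC, F.NON_TRANSITIVE}),
            parent=r[0])
    axioms.append(SubClassOf(Named(c[0]), Exists(r[0], Named(c[-1]))))
    axioms.append(PatternContract.create("subclass-pattern", {
        "anchor": c[0], "ggp": c[0], "relation": "pattern-R",
        "primitive": r[0], "target": c[-1], "kinds": list(c)}))
    axioms.append(PatternContract.create("proper-part-def", {
        "anchor": r[-1], "relation": r[-1], "base": r[0]}))
    if len(c) > 1:
        axioms.append(DisjointClasses([Named(c[0]), Named(c[1])]))
        axioms.append(EquivalentClasses([
            Named(c[1]),
            Union([Named(c[0]), Exists(r[-1], Named(c[0]))])]))
    return axioms, RelationTaxonomy(specs)


def compare_on_model(m: FiniteModel, axioms: Sequence[Axiom],
                     tax: RelationTaxonomy) -> List[str]:
    """Compare implementation and reference on one model.

    Returns mismatch descriptions (empty = full agreement): the optimized
    closure must equal the naive full-pass fixpoint, and for every flag and
    axiom the checker's verdict must equal direct first-order evaluation on
    the closed model.
    """
    mismatches: List[str] = []
    closed = closure(m, axioms)
    if closed != naive_closure(m, axioms):
        mismatches.append("closure != naive fixpoint")
        return mismatches
    report = check(closed, axioms, tax, close=False)
    kinds_by_rel: Dict[Tuple[str, str], bool] = {}
    for e in report.entries:
        kinds_by_rel[(e.kind, e.subject)] = True

    flag_kind = {F.REFLEXIVE: "reflexivity", F.IRREFLEXIVE: "irreflexivity",
                 F.SYMMETRIC: "symmetry", F.ASYMMETRIC: "asymmetry",
                 F.ANTISYMMETRIC: "antisymmetry", F.TRANSITIVE: "transitivity",
                 F.STRONG_SUPPLEMENTATION: "strong-supplementation"}
    for spec in tax:
        for flag in spec.flags:
            if flag is F.NON_TRANSITIVE:
                continue
            ok = flag_satisfied(closed, spec.name, flag, spec.domain_class)
            reported = kinds_by_rel.get((flag_kind[flag], spec.name), False)
            if ok == reported:
                mismatches.append(
                    f"flag {flag.value} on {spec.name}: oracle says "
                    f"{'satisfied' if ok else 'violated'}, checker "
                    f"{'agrees not' if reported else 'found nothing'}")

    from .axioms import render_expr
    for a in axioms:
        if isinstance(a, SubClassOf):
            ok = axiom_satisfied(closed, a)
            reported = kinds_by_rel.get(("subclass", render_expr(a.sub)), False)
        elif isinstance(a, DisjointClasses):
            ok = axiom_satisfied(closed, a)
            reported = any(k == "disjointness" for k, _ in kinds_by_rel)
        elif isinstance(a, EquivalentClasses):
            ok = axiom_satisfied(closed, a)
            reported = any(k == "equivalence" for k, _ in kinds_by_rel)
        elif isinstance(a, PatternContract) and a.kind == "subclass-pattern":
            ok = axiom_satisfied(closed, a)
            reported = any(k == "pattern-disjunction" for k, _ in kinds_by_rel)
        elif isinstance(a, PatternContract) and a.kind == "proper-part-def":
            ok = axiom_satisfied(closed, a)
            reported = any(k == "proper-part-definition" for k, _ in kinds_by_rel)
        else:
            continue
        if ok == reported:
            mismatches.append(f"axiom {type(a).__name__}: oracle "
                              f"{'satisfied' if ok else 'violated'}, checker "
                              f"disagrees")
    return mismatches
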