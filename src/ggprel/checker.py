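"""Finite-model semantics for the axiom IR.

A :class:`FiniteModel` is a finite interpretation: a set of individuals,
class extensions, and relation extensions.  :func:`closure` computes the
deductive closure of a model under the rule-like axioms (symmetry,
transitivity, sub-properties, property chains, inverse synchronisation,
forced subclass memberships and asserted facts).  :func:`check` evaluates
every axiom and every relation flag on the closed model and returns a
:class:`ViolationReport` with explicit witnesses.

Checking is closed-world over a fixed domain: a violation means "not
satisfied in THIS finite model", which is deliberately stronger than
open-world OWL entailment.  In particular an unsatisfied existential
obligation (``A SubClassOf (r some B)`` with an instance of ``A`` lacking
a successor) is reported as a violation rather than repaired with an
anonymous individual — annotation verification wants witnesses, not
skolems.  :func:`build_canonical_model` constructs, by a deterministic
chase, a smallest "intended" model of a converted abstract so that
annotation sets can be verified end to end.
"""

from __future__ import annotations

import itertools
import json
import random
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, Iterator, List, Optional, Sequence, Set, Tuple

from .axioms import (
    TOP_PROPERTY, Axiom, ClassAssertion, ClassExpr, Complement, Declaration,
    DisjointClasses, EquivalentClasses, Exists, Intersection,
    InverseProperties, IrreflexiveProperty, Named, Nothing, PatternContract,
    PropertyAssertion, ReflexiveProperty, SubClassOf, SubPropertyChain,
    SubPropertyOf, SymmetricProperty, AsymmetricProperty, Thing,
    TransitiveProperty, Union, contains_nothing, named_atoms, render_expr)
from .relations import AxiomFlag, RelationTaxonomy


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------

Pair = Tuple[str, str]


@dataclass
class FiniteModel:
    individuals: Set[str] = field(default_factory=set)
    class_ext: Dict[str, Set[str]] = field(default_factory=dict)
    rel_ext: Dict[str, Set[Pair]] = field(default_factory=dict)

    def ext(self, cls: str) -> Set[str]:
        return self.class_ext.get(cls, set())

    def pairs(self, rel: str) -> Set[Pair]:
        return self.rel_ext.get(rel, set())

    def add_member(self, cls: str, x: str) -> None:
        self.individuals.add(x)
        self.class_ext.setdefault(cls, set()).add(x)

    def add_pair(self, rel: str, x: str, y: str) -> None:
        self.individuals.update((x, y))
        self.rel_ext.setdefault(rel, set()).add((x, y))

    def field_of(self, rel: str) -> Set[str]:
        out: Set[str] = set()
        for x, y in self.pairs(rel):
            out.add(x)
            out.add(y)
        return out

    def copy(self) -> "FiniteModel":
        return FiniteModel(
            set(self.individuals),
            {c: set(v) for c, v in self.class_ext.items()},
            {r: set(v) for r, v in self.rel_ext.items()})

    def freeze(self):
        return (frozenset(self.individuals),
                frozenset((c, frozenset(v)) for c, v in self.class_ext.items() if v),
                frozenset((r, frozenset(v)) for r, v in self.rel_ext.items() if v))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FiniteModel):
            return NotImplemented
        return self.freeze() == other.freeze()

    def issubmodel(self, other: "FiniteModel") -> bool:
        return (self.individuals <= other.individuals
                and all(v <= other.ext(c) for c, v in self.class_ext.items())
                and all(v <= other.pairs(r) for r, v in self.rel_ext.items()))


def eval_expr(m: FiniteModel, e: ClassExpr) -> FrozenSet[str]:
    """Extension of a class expression in *m* (closed-world)."""
    if isinstance(e, Named):
        return frozenset(m.ext(e.id))
    if isinstance(e, Thing):
        return frozenset(m.individuals)
    if isinstance(e, Nothing):
        return frozenset()
    if isinstance(e, Intersection):
        out = frozenset(m.individuals)
        for p in e.parts:
            out &= eval_expr(m, p)
        return out
    if isinstance(e, Union):
        out: FrozenSet[str] = frozenset()
        for p in e.parts:
            out |= eval_expr(m, p)
        return out
    if isinstance(e, Complement):
        return frozenset(m.individuals) - eval_expr(m, e.expr)
    if isinstance(e, Exists):
        filler = eval_expr(m, e.filler)
        if e.relation == TOP_PROPERTY:
            # the universal property relates every pair of individuals
            return frozenset(m.individuals) if filler else frozenset()
        rel = m.pairs(e.relation)
        return frozenset(x for x, y in rel if y in filler)
    raise TypeError(f"not a class expression: {e!r}")


# ---------------------------------------------------------------------------
# Deductive closure
# ---------------------------------------------------------------------------

def _is_forced_subclass(a: SubClassOf) -> bool:
    """Rule-like subclass axioms whose right side forces memberships."""
    return isinstance(a.sup, Named)


def closure(m: FiniteModel, axioms: Sequence[Axiom]) -> FiniteModel:
    """Least fixpoint of the rule-like axioms over *m*.

    Rules: asserted class/property facts; symmetry and transitivity of
    flagged relations (as characteristic axioms); sub-property and inverse
    propagation; property-chain firing; memberships forced by
    ``SubClassOf(expr, Named)`` and by ``EquivalentClasses`` (every named
    class absorbs the evaluated extension of its equivalents).  Additions
    only, never retractions; idempotent and, for the axiom shapes the
    converter emits, monotone in the input extensions.
    """
    out = m.copy()

    sym = [a.relation for a in axioms if isinstance(a, SymmetricProperty)]
    trans = [a.relation for a in axioms if isinstance(a, TransitiveProperty)]
    subprops = [(a.sub, a.sup) for a in axioms if isinstance(a, SubPropertyOf)]
    chains = [(a.chain, a.sup) for a in axioms if isinstance(a, SubPropertyChain)]
    inverses = [(a.first, a.second) for a in axioms if isinstance(a, InverseProperties)]
    forced = [a for a in axioms if isinstance(a, SubClassOf) and _is_forced_subclass(a)]
    equivs = [a for a in axioms if isinstance(a, EquivalentClasses)]

    for a in axioms:
        if isinstance(a, ClassAssertion) and isinstance(a.expr, Named):
            out.add_member(a.expr.id, a.individual)
        elif isinstance(a, PropertyAssertion):
            out.add_pair(a.relation, a.subject, a.object)

    changed = True
    while changed:
        changed = False

        def add_pairs(rel: str, new: Iterable[Pair]) -> None:
            nonlocal changed
            cur = out.rel_ext.setdefault(rel, set())
            extra = set(new) - cur
            if extra:
                cur |= extra
                changed = True

        for r in sym:
            add_pairs(r, {(y, x) for (x, y) in out.pairs(r)})
        for r in trans:
            p = out.pairs(r)
            succ: Dict[str, Set[str]] = {}
            for x, y in p:
                succ.setdefault(x, set()).add(y)
            add_pairs(r, {(x, z) for (x, y) in p for z in succ.get(y, ())})
        for sub, sup in subprops:
            add_pairs(sup, out.pairs(sub))
        for chain, sup in chains:
            pairs = out.pairs(chain[0])
            for rel in chain[1:]:
                step = out.pairs(rel)
                succ = {}
                for x, y in step:
                    succ.setdefault(x, set()).add(y)
                pairs = {(x, z) for (x, y) in pairs for z in succ.get(y, ())}
            add_pairs(sup, pairs)
        for a, b in inverses:
            add_pairs(b, {(y, x) for (x, y) in out.pairs(a)})
            add_pairs(a, {(y, x) for (x, y) in out.pairs(b)})

        for ax in forced:
            members = eval_expr(out, ax.sub)
            cur = out.class_ext.setdefault(ax.sup.id, set())  # type: ignore[union-attr]
            if not members <= cur:
                cur |= members
                changed = True
        for ax in equivs:
            for tgt in ax.exprs:
                if not isinstance(tgt, Named):
                    continue
                cur = out.class_ext.setdefault(tgt.id, set())
                for other in ax.exprs:
                    if other is tgt:
                        continue
                    members = eval_expr(out, other)
                    if not members <= cur:
                        cur |= members
                        changed = True
    return out


# ---------------------------------------------------------------------------
# Violations
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ViolationEntry:
    kind: str                 # e.g. "irreflexivity", "subclass", "pattern-disjunction"
    subject: str              # relation / class / contract identifier
    witnesses: Tuple[str, ...]  # witness individuals ("*" marks a universal claim)
    message: str

    def to_dict(self) -> dict:
        return {"kind": self.kind, "subject": self.subject,
                "witnesses": list(self.witnesses), "message": self.message}


@dataclass
class ViolationReport:
    entries: List[ViolationEntry] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.entries

    def kinds(self) -> Set[str]:
        return {e.kind for e in self.entries}

    def by_kind(self, kind: str) -> List[ViolationEntry]:
        return [e for e in self.entries if e.kind == kind]

    def to_json(self) -> str:
        return json.dumps([e.to_dict() for e in self.entries], indent=2)

    def __len__(self) -> int:
        return len(self.entries)


def _flag_violations(m: FiniteModel, rel: str, flags: FrozenSet[AxiomFlag],
                     domain_class: Optional[str],
                     reflexivity_global: bool) -> Iterator[ViolationEntry]:
    p = m.pairs(rel)
    F = AxiomFlag
    if F.REFLEXIVE in flags:
        if reflexivity_global:
            dom = set(m.individuals)
        elif domain_class is not None:
            dom = set(m.ext(domain_class))
        else:
            dom = m.field_of(rel)
        for x in sorted(dom):
            if (x, x) not in p:
                yield ViolationEntry("reflexivity", rel, (x,),
                                     f"{rel} is reflexive but misses ({x},{x})")
    if F.IRREFLEXIVE in flags:
        for x, y in sorted(p):
            if x == y:
                yield ViolationEntry("irreflexivity", rel, (x,),
                                     f"{rel} is irreflexive but contains ({x},{x})")
    if F.SYMMETRIC in flags:
        for x, y in sorted(p):
            if (y, x) not in p:
                yield ViolationEntry("symmetry", rel, (x, y),
                                     f"{rel} is symmetric but misses ({y},{x})")
    if F.ASYMMETRIC in flags:
        for x, y in sorted(p):
            if (y, x) in p and (x, y) <= (y, x):
                yield ViolationEntry("asymmetry", rel, (x, y),
                                     f"{rel} is asymmetric but contains both "
                                     f"({x},{y}) and ({y},{x})")
    if F.ANTISYMMETRIC in flags:
        for x, y in sorted(p):
            if x != y and (y, x) in p and x < y:
                yield ViolationEntry("antisymmetry", rel, (x, y),
                                     f"{rel} is antisymmetric but contains both "
                                     f"({x},{y}) and ({y},{x}) with {x} != {y}")
    if F.TRANSITIVE in flags:
        succ: Dict[str, Set[str]] = {}
        for x, y in p:
            succ.setdefault(x, set()).add(y)
        for x, y in sorted(p):
            for z in sorted(succ.get(y, ())):
                if (x, z) not in p:
                    yield ViolationEntry("transitivity", rel, (x, y, z),
                                         f"{rel} is transitive but misses ({x},{z})")
    if F.STRONG_SUPPLEMENTATION in flags:
        fld = sorted(m.field_of(rel))
        parts: Dict[str, Set[str]] = {y: set() for y in fld}
        for x, y in p:
            parts.setdefault(y, set()).add(x)
        for x in fld:
            for y in fld:
                if (y, x) in p:
                    continue
                def overlaps(z: str, w: str) -> bool:
                    return any((v, z) in p and (v, w) in p for v in fld)
                if all(overlaps(z, x) for z in parts.get(y, ())):
                    yield ViolationEntry(
                        "strong-supplementation", rel, (x, y),
                        f"every part of {y} overlaps {x} but ({y},{x}) not in {rel}")


def _contract_violations(m: FiniteModel, c: PatternContract) -> Iterator[ViolationEntry]:
    pl = c.payload
    if c.kind == "subclass-pattern":
        ggp, prim, target = pl["ggp"], pl["primitive"], pl["target"]
        kinds = pl["kinds"]
        tgt_ext = m.ext(target)
        rel = m.pairs(prim)
        witnesses: List[str] = []
        for k in kinds:
            sub = m.ext(ggp) & m.ext(k)
            bad = sorted(x for x in sub
                         if not any((x, y) in rel for y in tgt_ext))
            if not bad:
                return  # this disjunct is satisfied
            witnesses.append(bad[0])
        yield ViolationEntry(
            "pattern-disjunction", f"{pl['relation']}({ggp},{target})",
            tuple(witnesses) or ("*",),
            f"no kind-restricted subclass of {ggp} has all instances with an "
            f"{prim} successor in {target} (kinds tried: {', '.join(kinds)})")
    elif c.kind == "proper-part-def":
        rel, base = pl["relation"], pl["base"]
        have = m.pairs(rel)
        want = {(x, y) for (x, y) in m.pairs(base) if (y, x) not in m.pairs(base)}
        for x, y in sorted(have - want):
            yield ViolationEntry(
                "proper-part-definition", rel, (x, y),
                f"({x},{y}) in {rel} but not a strict (non-mutual) {base} pair")
        for x, y in sorted(want - have):
            yield ViolationEntry(
                "proper-part-definition", rel, (x, y),
                f"({x},{y}) is a strict {base} pair but missing from {rel}")
    elif c.kind in ("ggp-equivalence", "variant-pattern"):
        # verified through the companion EquivalentClasses / SubClassOf axiom
        return
    else:
        raise ValueError(f"unknown pattern contract kind {c.kind!r}")


def check(m: FiniteModel, axioms: Sequence[Axiom],
          tax: Optional[RelationTaxonomy] = None, *,
          close: bool = True,
          reflexivity_global: bool = False) -> ViolationReport:
    """Evaluate axioms and relation flags on *m*; empty report = consistent.

    Reflexivity is, by default, checked over the relation's declared domain
    class extension (falling back to the individuals participating in the
    relation) rather than over all individuals; ``reflexivity_global``
    switches to the strict-global reading.
    """
    if close:
        m = closure(m, axioms)

    entries: Dict[Tuple, ViolationEntry] = {}

    def put(v: ViolationEntry) -> None:
        entries.setdefault((v.kind, v.subject, v.witnesses), v)

    # relation flags (from the taxonomy, plus standalone characteristic axioms)
    checked_flags: Set[Tuple[str, AxiomFlag]] = set()
    if tax is not None:
        for spec in tax:
            if not spec.flags:
                continue
            for v in _flag_violations(m, spec.name, spec.flags,
                                      spec.domain_class, reflexivity_global):
                put(v)
            checked_flags.update((spec.name, f) for f in spec.flags)
    flag_axiom_map = {
        ReflexiveProperty: AxiomFlag.REFLEXIVE,
        IrreflexiveProperty: AxiomFlag.IRREFLEXIVE,
        SymmetricProperty: AxiomFlag.SYMMETRIC,
        AsymmetricProperty: AxiomFlag.ASYMMETRIC,
    }
    for a in axioms:
        flag = flag_axiom_map.get(type(a))
        if flag is not None and (a.relation, flag) not in checked_flags:
            for v in _flag_violations(m, a.relation, frozenset({flag}), None,
                                      reflexivity_global):
                put(v)
            checked_flags.add((a.relation, flag))

    for a in axioms:
        if isinstance(a, DisjointClasses):
            for e1, e2 in itertools.combinations(a.exprs, 2):
                common = eval_expr(m, e1) & eval_expr(m, e2)
                for x in sorted(common):
                    put(ViolationEntry(
                        "disjointness", f"{render_expr(e1)}|{render_expr(e2)}",
                        (x,), f"{x} is an instance of both {render_expr(e1)} "
                              f"and {render_expr(e2)}"))
        elif isinstance(a, SubClassOf):
            if a.source and a.source.endswith("#encoding"):
                continue  # covered by the native pattern contract
            missing = eval_expr(m, a.sub) - eval_expr(m, a.sup)
            for x in sorted(missing):
                put(ViolationEntry(
                    "subclass", render_expr(a.sub), (x,),
                    f"{x} is in {render_expr(a.sub)} but not in "
                    f"{render_expr(a.sup)}"))
        elif isinstance(a, EquivalentClasses):
            exts = [eval_expr(m, e) for e in a.exprs]
            for (e1, x1), (e2, x2) in itertools.combinations(zip(a.exprs, exts), 2):
                for x in sorted(x1 ^ x2):
                    put(ViolationEntry(
                        "equivalence", render_expr(e1), (x,),
                        f"{x} distinguishes the declared-equivalent classes "
                        f"{render_expr(e1)} and {render_expr(e2)}"))
        elif isinstance(a, PatternContract):
            for v in _contract_violations(m, a):
                put(v)
        elif isinstance(a, ClassAssertion):
            if a.individual not in eval_expr(m, a.expr):
                put(ViolationEntry("assertion", render_expr(a.expr),
                                   (a.individual,),
                                   f"asserted {a.individual} not in "
                                   f"{render_expr(a.expr)}"))
        elif isinstance(a, PropertyAssertion):
            if (a.subject, a.object) not in m.pairs(a.relation):
                put(ViolationEntry("assertion", a.relation,
                                   (a.subject, a.object),
                                   f"asserted {a.relation}({a.subject},"
                                   f"{a.object}) missing"))
    return ViolationReport(sorted(entries.values(),
                                  key=lambda v: (v.kind, v.subject, v.witnesses)))


# ---------------------------------------------------------------------------
# Model enumeration (small-scope oracle support)
# ---------------------------------------------------------------------------

MAX_ENUMERATION_BITS = 22


def enumerate_models(classes: Sequence[str], relations: Sequence[str],
                     n_individuals: int) -> Iterator[FiniteModel]:
    """Exhaustively yield all models with exactly ``n_individuals``
    individuals over the given class and relation vocabulary.

    The number of models is ``2**(n*c) * 2**(n*n*r)``; a guard raises when
    the exponent exceeds ``MAX_ENUMERATION_BITS``.
    """
    n = n_individuals
    bits = n * len(classes) + n * n * len(relations)
    if bits > MAX_ENUMERATION_BITS:
        raise ValueError(
            f"enumeration of 2**{bits} models exceeds the configured bound "
            f"(2**{MAX_ENUMERATION_BITS})")
    inds = tuple(f"x{i}" for i in range(n))
    pairs = tuple(itertools.product(inds, inds))
    for mask in range(2 ** bits):
        m = FiniteModel(set(inds))
        pos = 0
        for c in classes:
            ext = {inds[i] for i in range(n) if mask >> (pos + i) & 1}
            pos += n
            if ext:
                m.class_ext[c] = ext
        for r in relations:
            rel = {pairs[i] for i in range(n * n) if mask >> (pos + i) & 1}
            pos += n * n
            if rel:
                m.rel_ext[r] = rel
        yield m


def random_models(classes: Sequence[str], relations: Sequence[str],
                  max_n: int, count: int, seed: int,
                  density: float = 0.35) -> Iterator[FiniteModel]:
    """Seeded random models of size 1..max_n (reproducible per seed)."""
    rng = random.Random(seed)
    for _ in range(count):
        n = rng.randint(1, max_n)
        inds = [f"x{i}" for i in range(n)]
        m = FiniteModel(set(inds))
        for c in classes:
            ext = {x for x in inds if rng.random() < 0.5}
            if ext:
                m.class_ext[c] = ext
        for r in relations:
            rel = {(x, y) for x in inds for y in inds if rng.random() < density}
            if rel:
                m.rel_ext[r] = rel
        yield m


# ---------------------------------------------------------------------------
# Canonical ("intended") model construction
# ---------------------------------------------------------------------------

def proto(cls: str) -> str:
    """Deterministic prototype-individual name for a class."""
    return f"{cls}.1"


def build_canonical_model(axioms: Sequence[Axiom],
                          tax: Optional[RelationTaxonomy] = None, *,
                          builtin_classes: Iterable[str] = (),
                          kinds_order: Sequence[str] = ("DNA", "RNA", "Protein"),
                          max_rounds: int = 40) -> FiniteModel:
    """Deterministic chase: the smallest intended model of an axiom set.

    One prototype individual is created per declared (non-builtin) class;
    seeded gene/gene-product classes get their transcription/translation
    chain materialised; existential obligations are satisfied by reusing an
    eligible individual (the subject itself if it qualifies, then the least
    existing member of the filler) before minting a fresh one; reflexive
    relations get their loops over participating individuals.  Constraint
    axioms (right side ``owl:Nothing``) and the OWL reformulations of
    pattern contracts are never chased — they are what :func:`check`
    verifies afterwards.
    """
    builtin = set(builtin_classes)
    m = FiniteModel()
    for a in axioms:
        if isinstance(a, Declaration) and a.kind == "Class" and a.entity not in builtin:
            m.add_member(a.entity, proto(a.entity))

    contracts = [a for a in axioms if isinstance(a, PatternContract)]
    existentials = [a for a in axioms if isinstance(a, SubClassOf)
                    and isinstance(a.sup, Exists)
                    and not (a.source and a.source.endswith("#encoding"))
                    and not contains_nothing(a.sup)]

    fresh_counter: Dict[Tuple[str, str], str] = {}

    def fresh(key: Tuple[str, str], classes: Iterable[str]) -> str:
        if key not in fresh_counter:
            name = f"{key[1]}~{key[0]}"
            fresh_counter[key] = name
            for c in classes:
                m.add_member(c, name)
            m.individuals.add(name)
        return fresh_counter[key]

    for _ in range(max_rounds):
        m = closure(m, axioms)
        changed = False

        # formula-backbone materialisation for seeded GGP classes
        for c in contracts:
            if c.kind != "ggp-equivalence":
                continue
            pl = c.payload
            ggp, seed = pl["ggp"], pl["seed"]
            tf, tlf = pl["transcribed_from"], pl["translated_from"]
            if not m.ext(seed):
                m.add_member(seed, proto(seed))
                changed = True
            d = min(sorted(m.ext(seed)))
            union = (m.ext(seed)
                     | {x for x, y in m.pairs(tf) if y in m.ext(seed)}
                     | {x for x, y in m.pairs(tlf)
                        if any((y, z) in m.pairs(tf) for z in m.ext(seed))})
            def rna_rep() -> str:
                rna = [x for x, y in m.pairs(tf) if y in m.ext(seed)]
                if rna:
                    return min(rna)
                r = fresh(("rna", ggp), ["RNA"])
                m.add_pair(tf, r, d)
                return r
            for x in sorted(m.ext(ggp) - union):
                if x in m.ext("RNA"):
                    m.add_pair(tf, x, d)
                elif x in m.ext("Protein"):
                    m.add_pair(tlf, x, rna_rep())
                else:
                    m.add_member(seed, x)
                changed = True

        # the subclass-pattern axiom disjunction: satisfy one kind-restricted
        # disjunct (preferring the kind the target class belongs to)
        for c in contracts:
            if c.kind != "subclass-pattern":
                continue
            pl = c.payload
            ggp, prim, target = pl["ggp"], pl["primitive"], pl["target"]
            kinds = list(pl["kinds"])
            tgt = m.ext(target)
            preferred = [k for k in kinds if tgt & m.ext(k)]
            ordered = preferred + [k for k in kinds if k not in preferred]
            chosen = next((k for k in ordered if m.ext(ggp) & m.ext(k)), None)
            if chosen is None:
                continue
            if not tgt:
                m.add_member(target, proto(target))
                tgt = m.ext(target)
                changed = True
            t = min(sorted(tgt))
            for x in sorted(m.ext(ggp) & m.ext(chosen)):
                if not any((x, y) in m.pairs(prim) for y in tgt):
                    m.add_pair(prim, x, x if x in tgt else t)
                    changed = True

        # plain existential obligations
        for a in existentials:
            assert isinstance(a.sup, Exists)
            rel, filler = a.sup.relation, a.sup.filler
            fext = eval_expr(m, filler)
            for x in sorted(eval_expr(m, a.sub)):
                if any((x, y) in m.pairs(rel) for y in fext):
                    continue
                if x in fext:
                    t = x
                elif fext:
                    t = min(sorted(fext))
                else:
                    t = fresh((rel, render_expr(filler)), named_atoms(filler))
                    fext = eval_expr(m, filler)
                m.add_pair(rel, x, t)
                changed = True

        # reflexive loops for flagged relations, over their participants
        if tax is not None:
            for spec in tax:
                if AxiomFlag.REFLEXIVE in spec.flags:
                    for x in sorted(m.field_of(spec.name)):
                        if (x, x) not in m.pairs(spec.name):
                            m.add_pair(spec.name, x, x)
                            changed = True

        if not changed:
            break
    return closure(m, axioms)
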