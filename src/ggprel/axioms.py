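"""Internal representation of OWL 2 axioms and class expressions.

The converter and the pattern expansions produce lists of :class:`Axiom`
values; the OWL writer serializes them and the finite-model checker
evaluates them.  Class expressions form a small OWL 2 fragment: named
classes, intersection, union, complement, existential restriction and the
two constants ``owl:Thing`` / ``owl:Nothing``.

Axioms carry an optional ``source`` string (provenance: the standoff
relation line an axiom came from, or a marker such as ``...#encoding`` for
the OWL reformulation of a pattern whose native contract is carried
separately).  ``source`` never participates in equality or hashing, so
round-trip comparisons ignore it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Optional, Tuple, Union as TUnion

# The universal (top) object property; used by the OWL reformulation of the
# subclass-pattern axiom disjunction.
TOP_PROPERTY = "owl:topObjectProperty"


# ---------------------------------------------------------------------------
# Class expressions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Named:
    id: str


@dataclass(frozen=True)
class Intersection:
    parts: Tuple["ClassExpr", ...]

    def __init__(self, parts: Iterable["ClassExpr"]):
        object.__setattr__(self, "parts", tuple(parts))


@dataclass(frozen=True)
class Union:
    parts: Tuple["ClassExpr", ...]

    def __init__(self, parts: Iterable["ClassExpr"]):
        object.__setattr__(self, "parts", tuple(parts))


@dataclass(frozen=True)
class Complement:
    expr: "ClassExpr"


@dataclass(frozen=True)
class Exists:
    """Existential restriction ``ObjectSomeValuesFrom(relation, filler)``."""

    relation: str
    filler: "ClassExpr"


@dataclass(frozen=True)
class Nothing:
    pass


@dataclass(frozen=True)
class Thing:
    pass


ClassExpr = TUnion[Named, Intersection, Union, Complement, Exists, Nothing, Thing]

NOTHING = Nothing()
THING = Thing()


def contains_nothing(expr: ClassExpr) -> bool:
    """True when ``Nothing`` occurs anywhere in *expr*."""
    if isinstance(expr, Nothing):
        return True
    if isinstance(expr, (Intersection, Union)):
        return any(contains_nothing(p) for p in expr.parts)
    if isinstance(expr, Complement):
        return contains_nothing(expr.expr)
    if isinstance(expr, Exists):
        return contains_nothing(expr.filler)
    return False


def named_atoms(expr: ClassExpr) -> Tuple[str, ...]:
    """Named classes a fresh individual must join to inhabit *expr*.

    Only defined for the filler shapes the converter emits (named classes
    and intersections of named classes)."""
    if isinstance(expr, Named):
        return (expr.id,)
    if isinstance(expr, Intersection):
        out: list[str] = []
        for p in expr.parts:
            out.extend(named_atoms(p))
        return tuple(out)
    raise ValueError(f"cannot instantiate a fresh individual for {expr!r}")


# ---------------------------------------------------------------------------
# Axioms
# ---------------------------------------------------------------------------

def _src() -> Optional[str]:
    return None


@dataclass(frozen=True)
class Declaration:
    kind: str  # "Class" | "ObjectProperty" | "AnnotationProperty"
    entity: str
    source: Optional[str] = field(default=None, compare=False)


@dataclass(frozen=True)
class SubClassOf:
    sub: ClassExpr
    sup: ClassExpr
    source: Optional[str] = field(default=None, compare=False)


@dataclass(frozen=True)
class EquivalentClasses:
    exprs: Tuple[ClassExpr, ...]
    source: Optional[str] = field(default=None, compare=False)

    def __init__(self, exprs: Iterable[ClassExpr], source: Optional[str] = None):
        object.__setattr__(self, "exprs", tuple(exprs))
        object.__setattr__(self, "source", source)


@dataclass(frozen=True)
class DisjointClasses:
    exprs: Tuple[ClassExpr, ...]
    source: Optional[str] = field(default=None, compare=False)

    def __init__(self, exprs: Iterable[ClassExpr], source: Optional[str] = None):
        object.__setattr__(self, "exprs", tuple(exprs))
        object.__setattr__(self, "source", source)


@dataclass(frozen=True)
class SubPropertyOf:
    sub: str
    sup: str
    source: Optional[str] = field(default=None, compare=False)


@dataclass(frozen=True)
class SubPropertyChain:
    chain: Tuple[str, ...]
    sup: str
    source: Optional[str] = field(default=None, compare=False)

    def __init__(self, chain: Iterable[str], sup: str, source: Optional[str] = None):
        chain = tuple(chain)
        if len(chain) < 2:
            raise ValueError("property chains need length >= 2")
        object.__setattr__(self, "chain", chain)
        object.__setattr__(self, "sup", sup)
        object.__setattr__(self, "source", source)


@dataclass(frozen=True)
class InverseProperties:
    first: str
    second: str
    source: Optional[str] = field(default=None, compare=False)


@dataclass(frozen=True)
class TransitiveProperty:
    relation: str
    source: Optional[str] = field(default=None, compare=False)


@dataclass(frozen=True)
class SymmetricProperty:
    relation: str
    source: Optional[str] = field(default=None, compare=False)


@dataclass(frozen=True)
class AsymmetricProperty:
    relation: str
    source: Optional[str] = field(default=None, compare=False)


@dataclass(frozen=True)
class ReflexiveProperty:
    relation: str
    source: Optional[str] = field(default=None, compare=False)


@dataclass(frozen=True)
class IrreflexiveProperty:
    relation: str
    source: Optional[str] = field(default=None, compare=False)


@dataclass(frozen=True)
class ClassAssertion:
    expr: ClassExpr
    individual: str
    source: Optional[str] = field(default=None, compare=False)


@dataclass(frozen=True)
class PropertyAssertion:
    relation: str
    subject: str
    object: str
    source: Optional[str] = field(default=None, compare=False)


@dataclass(frozen=True)
class AnnotationAssertion:
    """A free-text annotation attached to an entity (rdfs:comment style)."""

    subject: str
    text: str
    property: str = "rdfs:comment"
    source: Optional[str] = field(default=None, compare=False)


@dataclass(frozen=True)
class PatternContract:
    """Machine-readable record of a design-pattern instantiation.

    Some pattern semantics (the axiom disjunction of the subclass pattern,
    the proper-parthood definition, the transcription/translation chain
    seeding a gene/gene-product class) either are not first-order OWL
    axioms or are easier to verify natively.  The contract stores the
    pattern kind and a canonical-JSON payload; the model checker evaluates
    it directly and the OWL writer serializes it as an annotation.
    """

    kind: str
    payload_json: str
    source: Optional[str] = field(default=None, compare=False)

    @classmethod
    def create(cls, kind: str, payload: dict, source: Optional[str] = None) -> "PatternContract":
        return cls(kind, json.dumps(payload, sort_keys=True, separators=(",", ":")), source)

    @property
    def payload(self) -> dict:
        return json.loads(self.payload_json)


Axiom = TUnion[
    Declaration, SubClassOf, EquivalentClasses, DisjointClasses,
    SubPropertyOf, SubPropertyChain, InverseProperties,
    TransitiveProperty, SymmetricProperty, AsymmetricProperty,
    ReflexiveProperty, IrreflexiveProperty,
    ClassAssertion, PropertyAssertion, AnnotationAssertion, PatternContract,
]


# ---------------------------------------------------------------------------
# Rendering (canonical text form; also the canonical sort key)
# ---------------------------------------------------------------------------

def render_expr(e: ClassExpr) -> str:
    if isinstance(e, Named):
        return f":{e.id}"
    if isinstance(e, Intersection):
        return "ObjectIntersectionOf(" + " ".join(render_expr(p) for p in e.parts) + ")"
    if isinstance(e, Union):
        return "ObjectUnionOf(" + " ".join(render_expr(p) for p in e.parts) + ")"
    if isinstance(e, Complement):
        return f"ObjectComplementOf({render_expr(e.expr)})"
    if isinstance(e, Exists):
        return f"ObjectSomeValuesFrom({_prop(e.relation)} {render_expr(e.filler)})"
    if isinstance(e, Nothing):
        return "owl:Nothing"
    if isinstance(e, Thing):
        return "owl:Thing"
    raise TypeError(f"not a class expression: {e!r}")


def _prop(p: str) -> str:
    return p if ":" in p else f":{p}"


def _quote(s: str) -> str:
    return '"' + s.replace("\\", "\\\\").replace('"', '\\"') + '"'


def render_axiom(a: Axiom) -> str:
    """Canonical single-line OWL functional-syntax rendering (no annotations)."""
    if isinstance(a, Declaration):
        return f"Declaration({a.kind}({_prop(a.entity) if a.kind != 'Class' else ':' + a.entity}))"
    if isinstance(a, SubClassOf):
        return f"SubClassOf({render_expr(a.sub)} {render_expr(a.sup)})"
    if isinstance(a, EquivalentClasses):
        return "EquivalentClasses(" + " ".join(render_expr(e) for e in a.exprs) + ")"
    if isinstance(a, DisjointClasses):
        return "DisjointClasses(" + " ".join(render_expr(e) for e in a.exprs) + ")"
    if isinstance(a, SubPropertyOf):
        return f"SubObjectPropertyOf({_prop(a.sub)} {_prop(a.sup)})"
    if isinstance(a, SubPropertyChain):
        inner = " ".join(_prop(p) for p in a.chain)
        return f"SubObjectPropertyOf(ObjectPropertyChain({inner}) {_prop(a.sup)})"
    if isinstance(a, InverseProperties):
        return f"InverseObjectProperties({_prop(a.first)} {_prop(a.second)})"
    if isinstance(a, TransitiveProperty):
        return f"TransitiveObjectProperty({_prop(a.relation)})"
    if isinstance(a, SymmetricProperty):
        return f"SymmetricObjectProperty({_prop(a.relation)})"
    if isinstance(a, AsymmetricProperty):
        return f"AsymmetricObjectProperty({_prop(a.relation)})"
    if isinstance(a, ReflexiveProperty):
        return f"ReflexiveObjectProperty({_prop(a.relation)})"
    if isinstance(a, IrreflexiveProperty):
        return f"IrreflexiveObjectProperty({_prop(a.relation)})"
    if isinstance(a, ClassAssertion):
        return f"ClassAssertion({render_expr(a.expr)} :{a.individual})"
    if isinstance(a, PropertyAssertion):
        return f"ObjectPropertyAssertion({_prop(a.relation)} :{a.subject} :{a.object})"
    if isinstance(a, AnnotationAssertion):
        return f"AnnotationAssertion({_prop(a.property)} {_prop(a.subject)} {_quote(a.text)})"
    if isinstance(a, PatternContract):
        return (f"AnnotationAssertion(:patternContract :{json.loads(a.payload_json).get('anchor', 'pattern')}"
                f" {_quote(a.kind + '|' + a.payload_json)})")
    raise TypeError(f"not an axiom: {a!r}")


_TYPE_RANK = {
    Declaration: 0, SubPropertyOf: 1, SubPropertyChain: 2, InverseProperties: 3,
    TransitiveProperty: 4, SymmetricProperty: 4, AsymmetricProperty: 4,
    ReflexiveProperty: 4, IrreflexiveProperty: 4,
    SubClassOf: 5, EquivalentClasses: 5, DisjointClasses: 5,
    ClassAssertion: 6, PropertyAssertion: 6,
    PatternContract: 7, AnnotationAssertion: 8,
}


def canonical_sort(axioms: Iterable[Axiom]) -> list:
    """Deterministic ordering: declarations, property axioms, class axioms,
    assertions, contracts, annotations; alphabetical within each group.
    Duplicates are removed (first occurrence's provenance wins)."""
    seen = {}
    for a in axioms:
        key = (_TYPE_RANK[type(a)], render_axiom(a))
        if key not in seen:
            seen[key] = a
    return [seen[k] for k in sorted(seen)]
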