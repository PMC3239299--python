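"""OWL 2 serialization: functional syntax (primary) and Turtle (secondary).

The functional-syntax writer is byte-deterministic (canonically ordered,
line-oriented) and respects the OWL 2 DL restriction on non-simple object
properties: a property that is declared transitive, occurs as the
conclusion of a property chain, or has a sub-property (direct, indirect or
inverse) with either trait is *non-simple* and may not carry a
reflexivity, irreflexivity, symmetry or asymmetry characteristic.  Such
characteristics are dropped from the OWL output and recorded as annotation
comments instead, so no information is silently lost.

:func:`parse_ontology` reads back exactly the dialect the writer emits
(not a general OWL parser); write -> parse is the identity on the IR
modulo the dropped characteristics and canonical ordering.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

from .axioms import (
    AnnotationAssertion, AsymmetricProperty, Axiom, ClassAssertion, ClassExpr,
    Complement, Declaration, DisjointClasses, EquivalentClasses, Exists,
    Intersection, InverseProperties, IrreflexiveProperty, Named, Nothing,
    NOTHING, PatternContract, PropertyAssertion, ReflexiveProperty,
    SubClassOf, SubPropertyChain, SubPropertyOf, SymmetricProperty, Thing,
    THING, TransitiveProperty, Union, canonical_sort, render_axiom)


@dataclass(frozen=True)
class OntologyConfig:
    """IRIs for the emitted ontology and its imports."""

    base_iri: str = "http://example.org/ggprel/"
    ontology_iri: str = "http://example.org/ggprel/ontology"
    so_import: str = "http://purl.obolibrary.org/obo/so.owl"
    genia_import: str = "http://www.geniaontology.org/term.owl"
    imports: bool = True


class OwlSyntaxError(ValueError):
    def __init__(self, pos: int, message: str):
        super().__init__(f"character {pos}: {message}")
        self.pos = pos


class OwlDialectError(ValueError):
    """A construct outside the dialect this tool emits."""


# ---------------------------------------------------------------------------
# Non-simple property computation
# ---------------------------------------------------------------------------

def non_simple_properties(axioms: Sequence[Axiom]) -> Set[str]:
    """Properties barred from reflexivity/symmetry-style characteristics.

    A property is non-simple when it is transitive, concludes a property
    chain, or is reachable (upward through sub-property links or across
    inverse links) from such a property.
    """
    seeds: Set[str] = set()
    up: Dict[str, Set[str]] = {}      # property -> its super-properties
    inv: Dict[str, Set[str]] = {}
    for a in axioms:
        if isinstance(a, TransitiveProperty):
            seeds.add(a.relation)
        elif isinstance(a, SubPropertyChain):
            seeds.add(a.sup)
        elif isinstance(a, SubPropertyOf):
            up.setdefault(a.sub, set()).add(a.sup)
        elif isinstance(a, InverseProperties):
            inv.setdefault(a.first, set()).add(a.second)
            inv.setdefault(a.second, set()).add(a.first)
    out = set(seeds)
    frontier = list(seeds)
    while frontier:
        p = frontier.pop()
        for q in up.get(p, set()) | inv.get(p, set()):
            if q not in out:
                out.add(q)
                frontier.append(q)
    return out


_RESTRICTED = (ReflexiveProperty, IrreflexiveProperty,
               SymmetricProperty, AsymmetricProperty)

_CHAR_NAME = {
    ReflexiveProperty: "reflexivity",
    IrreflexiveProperty: "irreflexivity",
    SymmetricProperty: "symmetry",
    AsymmetricProperty: "asymmetry",
}


def lint_simple_property_characteristics(axioms: Sequence[Axiom]) -> List[str]:
    """Names of restricted characteristics asserted on non-simple
    properties (empty list = document is OWL 2 DL clean)."""
    bad = non_simple_properties(axioms)
    return [f"{_CHAR_NAME[type(a)]} on non-simple property {a.relation}"
            for a in axioms
            if isinstance(a, _RESTRICTED) and a.relation in bad]


# ---------------------------------------------------------------------------
# Functional-syntax writer
# ---------------------------------------------------------------------------

_HEADER_PREFIXES = (
    ("", "{base}"),
    ("owl:", "http://www.w3.org/2002/07/owl#"),
    ("rdf:", "http://www.w3.org/1999/02/22-rdf-syntax-ns#"),
    ("rdfs:", "http://www.w3.org/2000/01/rdf-schema#"),
    ("xsd:", "http://www.w3.org/2001/XMLSchema#"),
)

OMISSION_NOTE = "omitted {char} characteristic: non-simple property in OWL 2 DL"


def write_ontology(axioms: Sequence[Axiom],
                   cfg: OntologyConfig = OntologyConfig()) -> str:
    """Serialize an axiom list to OWL 2 functional syntax.

    Restricted characteristics on non-simple properties are replaced by an
    annotation comment built from :data:`OMISSION_NOTE`; pattern contracts
    are carried as ``:patternContract`` annotations so the document
    round-trips through :func:`parse_ontology`.
    """
    bad = non_simple_properties(axioms)
    emitted: List[Axiom] = [Declaration("Class", "GGP"),
                            Declaration("AnnotationProperty", "patternContract"),
                            Declaration("AnnotationProperty", "sourceLine")]
    for a in axioms:
        if isinstance(a, _RESTRICTED) and a.relation in bad:
            emitted.append(AnnotationAssertion(
                a.relation,
                OMISSION_NOTE.format(char=_CHAR_NAME[type(a)])))
        else:
            emitted.append(a)
    lines: List[str] = []
    for pfx, iri in _HEADER_PREFIXES:
        lines.append(f"Prefix({pfx}=<{iri.format(base=cfg.base_iri)}>)")
    lines.append(f"Ontology(<{cfg.ontology_iri}>")
    if cfg.imports:
        lines.append(f"Import(<{cfg.so_import}>)")
        lines.append(f"Import(<{cfg.genia_import}>)")
    for a in canonical_sort(emitted):
        text = render_axiom(a)
        if a.source is not None and not isinstance(a, (AnnotationAssertion,
                                                       PatternContract)):
            # axiom annotation carrying provenance (the source R-line)
            head, _, rest = text.partition("(")
            text = f'{head}(Annotation(:sourceLine "{a.source}") {rest}'
        lines.append(text)
    lines.append(")")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Functional-syntax parser (emitted dialect only)
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(r"""
    (?P<ws>\s+)
  | (?P<string>"(?:[^"\\]|\\.)*")
  | (?P<iri><[^>]*>)
  | (?P<punct>[()=])
  | (?P<name>[^\s()="<>]+)
""", re.VERBOSE)


def _tokenize(text: str) -> List[Tuple[str, str, int]]:
    tokens: List[Tuple[str, str, int]] = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            raise OwlSyntaxError(pos, f"unexpected character {text[pos]!r}")
        if m.lastgroup != "ws":
            tokens.append((m.lastgroup, m.group(), pos))
        pos = m.end()
    return tokens


class _Parser:
    def __init__(self, text: str):
        self.tokens = _tokenize(text)
        self.i = 0

    def peek(self) -> Optional[Tuple[str, str, int]]:
        return self.tokens[self.i] if self.i < len(self.tokens) else None

    def next(self) -> Tuple[str, str, int]:
        tok = self.peek()
        if tok is None:
            last = self.tokens[-1][2] if self.tokens else 0
            raise OwlSyntaxError(last, "unexpected end of document")
        self.i += 1
        return tok

    def expect(self, value: str) -> None:
        kind, tok, pos = self.next()
        if tok != value:
            raise OwlSyntaxError(pos, f"expected {value!r}, found {tok!r}")

    def local(self) -> str:
        kind, tok, pos = self.next()
        if kind != "name" or not tok.startswith(":"):
            raise OwlSyntaxError(pos, f"expected a :local name, found {tok!r}")
        return tok[1:]

    def prop(self) -> str:
        kind, tok, pos = self.next()
        if kind != "name":
            raise OwlSyntaxError(pos, f"expected a property, found {tok!r}")
        return tok[1:] if tok.startswith(":") else tok

    def string(self) -> str:
        kind, tok, pos = self.next()
        if kind != "string":
            raise OwlSyntaxError(pos, f"expected a string, found {tok!r}")
        return tok[1:-1].replace('\\"', '"').replace("\\\\", "\\")

    # -- class expressions --------------------------------------------------
    def class_expr(self) -> ClassExpr:
        kind, tok, pos = self.next()
        if kind == "name" and tok == "owl:Thing":
            return THING
        if kind == "name" and tok == "owl:Nothing":
            return NOTHING
        if kind == "name" and tok.startswith(":"):
            return Named(tok[1:])
        if kind == "name" and tok == "ObjectIntersectionOf":
            return Intersection(self._expr_list())
        if kind == "name" and tok == "ObjectUnionOf":
            return Union(self._expr_list())
        if kind == "name" and tok == "ObjectComplementOf":
            self.expect("(")
            e = self.class_expr()
            self.expect(")")
            return Complement(e)
        if kind == "name" and tok == "ObjectSomeValuesFrom":
            self.expect("(")
            rel = self.prop()
            filler = self.class_expr()
            self.expect(")")
            return Exists(rel, filler)
        raise OwlDialectError(f"character {pos}: unsupported class "
                              f"expression starting with {tok!r}")

    def _expr_list(self) -> List[ClassExpr]:
        self.expect("(")
        out = []
        while self.peek() and self.peek()[1] != ")":
            out.append(self.class_expr())
        self.expect(")")
        return out

    # -- axioms -------------------------------------------------------------
    def maybe_annotation(self) -> Optional[str]:
        tok = self.peek()
        if tok and tok[1] == "Annotation":
            self.next()
            self.expect("(")
            prop = self.prop()
            value = self.string()
            self.expect(")")
            if prop == "sourceLine":
                return value
            return None
        return None

    def axiom(self, head: str, pos: int) -> Optional[Axiom]:
        self.expect("(")
        source = self.maybe_annotation()
        a: Optional[Axiom]
        if head == "Declaration":
            kind, tok, p2 = self.next()
            if tok not in ("Class", "ObjectProperty", "AnnotationProperty",
                           "NamedIndividual"):
                raise OwlDialectError(f"character {p2}: unsupported "
                                      f"declaration {tok!r}")
            self.expect("(")
            entity = self.prop()
            self.expect(")")
            a = Declaration(tok, entity)
        elif head == "SubClassOf":
            a = SubClassOf(self.class_expr(), self.class_expr(), source=source)
        elif head == "EquivalentClasses":
            a = EquivalentClasses(self._axiom_expr_list(), source=source)
        elif head == "DisjointClasses":
            a = DisjointClasses(self._axiom_expr_list(), source=source)
        elif head == "SubObjectPropertyOf":
            tok = self.peek()
            if tok and tok[1] == "ObjectPropertyChain":
                self.next()
                self.expect("(")
                chain = []
                while self.peek() and self.peek()[1] != ")":
                    chain.append(self.prop())
                self.expect(")")
                a = SubPropertyChain(chain, self.prop(), source=source)
            else:
                a = SubPropertyOf(self.prop(), self.prop(), source=source)
        elif head == "InverseObjectProperties":
            a = InverseProperties(self.prop(), self.prop(), source=source)
        elif head == "TransitiveObjectProperty":
            a = TransitiveProperty(self.prop(), source=source)
        elif head == "SymmetricObjectProperty":
            a = SymmetricProperty(self.prop(), source=source)
        elif head == "AsymmetricObjectProperty":
            a = AsymmetricProperty(self.prop(), source=source)
        elif head == "ReflexiveObjectProperty":
            a = ReflexiveProperty(self.prop(), source=source)
        elif head == "IrreflexiveObjectProperty":
            a = IrreflexiveProperty(self.prop(), source=source)
        elif head == "ClassAssertion":
            a = ClassAssertion(self.class_expr(), self.local(), source=source)
        elif head == "ObjectPropertyAssertion":
            a = PropertyAssertion(self.prop(), self.local(), self.local(),
                                  source=source)
        elif head == "AnnotationAssertion":
            prop = self.prop()
            subject = self.prop()
            value = self.string()
            if prop == "patternContract":
                kind_str, _, payload = value.partition("|")
                a = PatternContract(kind_str, payload, source=source)
            else:
                a = AnnotationAssertion(subject, value, property=prop,
                                        source=source)
        else:
            raise OwlDialectError(f"character {pos}: unsupported axiom "
                                  f"{head!r}")
        self.expect(")")
        return a

    def _axiom_expr_list(self) -> List[ClassExpr]:
        out = []
        while self.peek() and self.peek()[1] != ")":
            out.append(self.class_expr())
        return out


def parse_ontology(text: str) -> List[Axiom]:
    """Parse a document produced by :func:`write_ontology` back into IR.

    Raises :class:`OwlSyntaxError` (with character position) on malformed
    input and :class:`OwlDialectError` on OWL constructs outside the
    emitted dialect.
    """
    p = _Parser(text)
    axioms: List[Axiom] = []
    while True:
        tok = p.peek()
        if tok is None:
            break
        kind, value, pos = tok
        if value == "Prefix":
            p.next()
            p.expect("(")
            p.next()  # prefix name or '=' for default prefix
            while p.peek() and p.peek()[1] != ")":
                p.next()
            p.expect(")")
        elif value == "Ontology":
            p.next()
            p.expect("(")
            if p.peek() and p.peek()[0] == "iri":
                p.next()
        elif value == "Import":
            p.next()
            p.expect("(")
            p.next()
            p.expect(")")
        elif value == ")":
            p.next()
        else:
            p.next()
            axioms.append(p.axiom(value, pos))
    return axioms


def expected_roundtrip(axioms: Sequence[Axiom]) -> List[Axiom]:
    """The IR that ``parse_ontology(write_ontology(S))`` yields for ``S``:
    canonical order, the writer's header declarations added, restricted
    characteristics on non-simple properties replaced by their omission
    comments."""
    bad = non_simple_properties(axioms)
    out: List[Axiom] = [Declaration("Class", "GGP"),
                        Declaration("AnnotationProperty", "patternContract"),
                        Declaration("AnnotationProperty", "sourceLine")]
    for a in axioms:
        if isinstance(a, _RESTRICTED) and a.relation in bad:
            out.append(AnnotationAssertion(
                a.relation, OMISSION_NOTE.format(char=_CHAR_NAME[type(a)])))
        else:
            out.append(a)
    return canonical_sort(out)


# ---------------------------------------------------------------------------
# Turtle writer (secondary serialization, via rdflib)
# ---------------------------------------------------------------------------

def write_turtle(axioms: Sequence[Axiom],
                 cfg: OntologyConfig = OntologyConfig()) -> str:
    """Serialize to Turtle using the standard OWL-to-RDF mapping."""
    from rdflib import BNode, Graph, Literal, Namespace, RDF, RDFS, URIRef
    from rdflib.collection import Collection
    from rdflib.namespace import OWL

    base = Namespace(cfg.base_iri)
    g = Graph()
    g.bind("", base)
    g.bind("owl", OWL)
    onto = URIRef(cfg.ontology_iri)
    g.add((onto, RDF.type, OWL.Ontology))
    if cfg.imports:
        g.add((onto, OWL.imports, URIRef(cfg.so_import)))
        g.add((onto, OWL.imports, URIRef(cfg.genia_import)))

    def ent(name: str):
        if name.startswith("owl:"):
            return OWL[name[4:]]
        if name.startswith("rdfs:"):
            return RDFS[name[5:]]
        return base[name]

    def expr(e: ClassExpr):
        if isinstance(e, Named):
            return ent(e.id)
        if isinstance(e, Thing):
            return OWL.Thing
        if isinstance(e, Nothing):
            return OWL.Nothing
        node = BNode()
        if isinstance(e, (Intersection, Union)):
            items = [expr(p) for p in e.parts]
            lst = BNode()
            Collection(g, lst, items)
            g.add((node, RDF.type, OWL.Class))
            pred = OWL.intersectionOf if isinstance(e, Intersection) else OWL.unionOf
            g.add((node, pred, lst))
        elif isinstance(e, Complement):
            g.add((node, RDF.type, OWL.Class))
            g.add((node, OWL.complementOf, expr(e.expr)))
        elif isinstance(e, Exists):
            g.add((node, RDF.type, OWL.Restriction))
            g.add((node, OWL.onProperty, ent(e.relation)))
            g.add((node, OWL.someValuesFrom, expr(e.filler)))
        else:
            raise TypeError(f"not a class expression: {e!r}")
        return node

    bad = non_simple_properties(axioms)
    for a in axioms:
        if isinstance(a, _RESTRICTED) and a.relation in bad:
            g.add((ent(a.relation), RDFS.comment,
                   Literal(OMISSION_NOTE.format(char=_CHAR_NAME[type(a)]))))
            continue
        if isinstance(a, Declaration):
            rdf_type = {"Class": OWL.Class, "ObjectProperty": OWL.ObjectProperty,
                        "AnnotationProperty": OWL.AnnotationProperty,
                        "NamedIndividual": OWL.NamedIndividual}[a.kind]
            g.add((ent(a.entity), RDF.type, rdf_type))
        elif isinstance(a, SubClassOf):
            g.add((expr(a.sub), RDFS.subClassOf, expr(a.sup)))
        elif isinstance(a, EquivalentClasses):
            nodes = [expr(e) for e in a.exprs]
            for n1, n2 in zip(nodes, nodes[1:]):
                g.add((n1, OWL.equivalentClass, n2))
        elif isinstance(a, DisjointClasses):
            nodes = [expr(e) for e in a.exprs]
            for i, n1 in enumerate(nodes):
                for n2 in nodes[i + 1:]:
                    g.add((n1, OWL.disjointWith, n2))
        elif isinstance(a, SubPropertyOf):
            g.add((ent(a.sub), RDFS.subPropertyOf, ent(a.sup)))
        elif isinstance(a, SubPropertyChain):
            lst = BNode()
            Collection(g, lst, [ent(p) for p in a.chain])
            g.add((ent(a.sup), OWL.propertyChainAxiom, lst))
        elif isinstance(a, InverseProperties):
            g.add((ent(a.first), OWL.inverseOf, ent(a.second)))
        elif isinstance(a, TransitiveProperty):
            g.add((ent(a.relation), RDF.type, OWL.TransitiveProperty))
        elif isinstance(a, SymmetricProperty):
            g.add((ent(a.relation), RDF.type, OWL.SymmetricProperty))
        elif isinstance(a, AsymmetricProperty):
            g.add((ent(a.relation), RDF.type, OWL.AsymmetricProperty))
        elif isinstance(a, ReflexiveProperty):
            g.add((ent(a.relation), RDF.type, OWL.ReflexiveProperty))
        elif isinstance(a, IrreflexiveProperty):
            g.add((ent(a.relation), RDF.type, OWL.IrreflexiveProperty))
        elif isinstance(a, ClassAssertion):
            g.add((ent(a.individual), RDF.type, expr(a.expr)))
        elif isinstance(a, PropertyAssertion):
            g.add((ent(a.subject), ent(a.relation), ent(a.object)))
        elif isinstance(a, AnnotationAssertion):
            prop = RDFS.comment if a.property == "rdfs:comment" else ent(a.property)
            g.add((ent(a.subject), prop, Literal(a.text)))
        elif isinstance(a, PatternContract):
            g.add((ent(json.loads(a.payload_json).get("anchor", "pattern")),
                   base["patternContract"],
                   Literal(a.kind + "|" + a.payload_json)))
        else:
            raise TypeError(f"not an axiom: {a!r}")
    return g.serialize(format="turtle")
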