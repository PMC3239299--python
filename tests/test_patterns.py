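"""Pattern expansions: the GGP class construction, the subclass-pattern
axiom disjunction, the variant pattern, proper parthood and location."""

import itertools
import random

import pytest
from hypothesis import given, strategies as st

from ggprel.axioms import (Exists, Intersection, Named, PatternContract,
                           SubClassOf, SubPropertyChain, Union)
from ggprel.checker import FiniteModel, check, closure, enumerate_models
from ggprel.patterns import (ConfigurationError, GgpClass, PatternInstance,
                             convert_subclass_relation, define_ggp_class,
                             expand_subclass_pattern, expand_variant_pattern,
                             location_chain_axioms, proper_part_axioms)
from ggprel.reference import (ggp_extension, naive_closure,
                              subclass_pattern_holds)
from ggprel.relations import build_genia_taxonomy

TAX = build_genia_taxonomy()


# -- GGP class construction ---------------------------------------------------

def _cd19_ggp():
    return GgpClass("G_CD19", "CD19_gene",
                    (("CD19", "Protein"), ("CD19_gene", "DNA"),
                     ("CD19_protein", "Protein")))


def test_ggp_class_worked_model():
    """A gene individual, its transcript, and the translated protein all
    fall into the gene/gene-product class extension."""
    axioms = define_ggp_class(_cd19_ggp(), TAX)
    m = FiniteModel({"d", "r", "p", "q"},
                    {"CD19_gene": {"d"}, "Protein": {"p", "q"}},
                    {"transcribed-from": {("r", "d")},
                     "translated-from": {("p", "r")}})
    closed = closure(m, axioms)
    assert closed.ext("G_CD19") == {"d", "r", "p"}
    assert "q" not in closed.ext("G_CD19")


def test_ggp_class_requires_so_primitives():
    from ggprel.relations import RelationTaxonomy, RelationSpec
    bare = RelationTaxonomy({"II-part-of": RelationSpec("II-part-of", "II")})
    with pytest.raises(ConfigurationError):
        define_ggp_class(_cd19_ggp(), bare)


def test_ggp_extension_matches_fol_on_random_models():
    """On randomized 6-individual models the closed extension equals the
    brute-force three-disjunct first-order evaluation."""
    axioms = define_ggp_class(_cd19_ggp(), TAX)
    rng = random.Random(17)
    inds = [f"x{i}" for i in range(6)]
    for _ in range(120):
        m = FiniteModel(set(inds))
        m.class_ext["CD19_gene"] = {x for x in inds if rng.random() < 0.3}
        m.class_ext["G_CD19"] = {x for x in inds if rng.random() < 0.2}
        for rel in ("transcribed-from", "translated-from"):
            m.rel_ext[rel] = {(a, b) for a in inds for b in inds
                              if rng.random() < 0.15}
        closed = closure(m, axioms)
        want = ggp_extension(closed, "CD19_gene", "transcribed-from",
                             "translated-from")
        assert closed.ext("G_CD19") >= want
        # the checker flags any G member outside the defining union
        report = check(closed, axioms, TAX, close=False)
        extra = closed.ext("G_CD19") - want
        assert bool(extra) == ("equivalence" in report.kinds())


# -- is-a ---------------------------------------------------------------------

def test_subclass_conversion():
    axioms = convert_subclass_relation("CD19_human_gene", "CD19")
    assert axioms == [SubClassOf(Named("CD19_human_gene"), Named("CD19"))]
    reflexive = convert_subclass_relation("C", "C")
    assert len(reflexive) == 2  # the degenerate case carries a warning


# -- subclass pattern ---------------------------------------------------------

def _pattern(relation="GGP-subclass-has-part", kinds=("DNA", "RNA", "Protein")):
    return PatternInstance("G", relation, "X", tuple(kinds))


def test_subclass_pattern_emits_contract_and_nothing_encoding():
    contract, encoding = expand_subclass_pattern(_pattern(), TAX)
    assert isinstance(contract, PatternContract)
    assert contract.payload["primitive"] == "II-has-part"
    assert isinstance(encoding.sub, Intersection)
    assert len(encoding.sub.parts) == 3
    assert encoding.source.endswith("#encoding")


def test_subclass_pattern_unresolvable_primitive():
    with pytest.raises(ConfigurationError):
        expand_subclass_pattern(_pattern(relation="II-part-of"), TAX)


def test_subclass_pattern_satisfaction_examples():
    contract, _ = expand_subclass_pattern(
        PatternInstance("G_CD19", "GGP-subclass-has-part", "CD19_promoter"),
        TAX)
    good = FiniteModel({"d", "p", "prom"},
                       {"G_CD19": {"d", "p"}, "DNA": {"d"}, "Protein": {"p"},
                        "CD19_promoter": {"prom"}},
                       {"II-has-part": {("d", "prom")}})
    assert check(good, [contract], None, close=False).ok
    # violated only when every kind-restricted subclass has a witness
    # instance lacking a successor (an empty kind satisfies its disjunct
    # vacuously)
    bad = FiniteModel({"d", "r", "p", "prom"},
                      {"G_CD19": {"d", "r", "p"}, "DNA": {"d"}, "RNA": {"r"},
                       "Protein": {"p"}, "CD19_promoter": {"prom"}}, {})
    report = check(bad, [contract], None, close=False)
    assert "pattern-disjunction" in report.kinds()
    assert report.entries[0].witnesses == ("d", "r", "p")


def test_subclass_pattern_agrees_with_bruteforce_and_owl_encoding():
    """On every model with <= 3 individuals, the native contract, the
    brute-force disjunction, and the owl:Nothing reformulation coincide."""
    contract, encoding = expand_subclass_pattern(
        PatternInstance("G", "GGP-subclass-member-of", "X", ("K1", "K2")), TAX)
    from ggprel.checker import eval_expr
    for n in (0, 1, 2, 3):
        count = 0
        for m in enumerate_models(["G", "K1"], ["II-member-of"], n):
            m.class_ext["K2"] = set()
            m.class_ext["X"] = {x for x in m.individuals if x != "x0"}
            native_ok = check(m, [contract], None, close=False).ok
            brute = subclass_pattern_holds(m, "G", "II-member-of", "X",
                                           ["K1", "K2"])
            encoding_ok = not eval_expr(m, encoding.sub)
            assert native_ok == brute == encoding_ok
            count += 1
        assert count == 2 ** (2 * n + n * n)


def test_subclass_pattern_monotone_in_primitive_extension():
    """Enlarging the primitive's extension never breaks a satisfied
    pattern instance."""
    contract, _ = expand_subclass_pattern(
        PatternInstance("G", "GGP-subclass-has-part", "X", ("K",)), TAX)
    rng = random.Random(5)
    inds = ["a", "b", "c", "d"]
    for _ in range(200):
        m = FiniteModel(set(inds))
        for cls in ("G", "K", "X"):
            m.class_ext[cls] = {x for x in inds if rng.random() < 0.5}
        m.rel_ext["II-has-part"] = {(x, y) for x in inds for y in inds
                                    if rng.random() < 0.3}
        if not check(m, [contract], None, close=False).ok:
            continue
        bigger = m.copy()
        bigger.rel_ext["II-has-part"] |= {
            (x, y) for x in inds for y in inds if rng.random() < 0.3}
        assert check(bigger, [contract], None, close=False).ok


# -- variant pattern ----------------------------------------------------------

def test_variant_pattern_fillers():
    contract, plain = expand_variant_pattern(
        PatternInstance("G_TR", "GGP-has-variant", "V35S"), TAX)
    assert contract.payload["relation"] == "GGP-has-variant"
    assert plain == SubClassOf(Named("V35S"),
                               Exists("II-has-variant", Named("G_TR")))
    _, isoform = expand_variant_pattern(
        PatternInstance("G_ACTA1", "GGP-has-isoform", "G_Actin"), TAX)
    assert isoform.sup == Exists(
        "II-has-isoform", Intersection([Named("G_ACTA1"), Named("Protein")]))
    _, recomb = expand_variant_pattern(
        PatternInstance("G_Oct2", "GGP-has-recombinant", "Vector"), TAX)
    assert recomb.sup.filler == Intersection([Named("G_Oct2"), Named("DNA")])


def test_variant_pattern_vacuous_on_empty_variant_class():
    ax = expand_variant_pattern(
        PatternInstance("G", "GGP-has-modified-protein", "D"), TAX)[1]
    m = FiniteModel({"g"}, {"G": {"g"}, "Protein": {"g"}}, {})
    assert check(m, [ax], None, close=False).ok


def test_variant_pattern_missing_primitive_config():
    with pytest.raises(ConfigurationError):
        expand_variant_pattern(
            PatternInstance("G", "GGP-has-isoform", "D"), TAX,
            kind_restriction={})


def test_mutant_symmetry_closure_and_irreflexivity():
    """Mutant-of symmetrizes; a self-mutant is an irreflexivity violation."""
    from ggprel.axioms import SymmetricProperty
    axioms = [SymmetricProperty("II-has-mutant")]
    m = FiniteModel({"g", "mu"}, {}, {"II-has-mutant": {("g", "mu")}})
    closed = closure(m, axioms)
    assert ("mu", "g") in closed.pairs("II-has-mutant")
    assert check(closed, axioms, TAX, close=False).ok
    closed.add_pair("II-has-mutant", "g", "g")
    report = check(closed, axioms, TAX, close=False)
    assert [e.kind for e in report.by_kind("irreflexivity")] == ["irreflexivity"]
    assert report.by_kind("irreflexivity")[0].witnesses == ("g",)


def test_variant_pattern_chain_relations_widen_filler():
    ax = expand_variant_pattern(
        PatternInstance("G", "GGP-has-variant", "D",
                        chain_relations=("t1", "t2")), TAX)[1]
    assert isinstance(ax.sup.filler, Union)
    # ordered chain: t1 then t2 ending at the base filler
    chained = ax.sup.filler.parts[1]
    assert chained == Exists("t1", Exists("t2", Named("G")))


# -- proper parthood ----------------------------------------------------------

def test_proper_part_direct_evaluation():
    contract = proper_part_axioms()[1]
    m = FiniteModel({"a", "b"}, {},
                    {"II-part-of": {("a", "a"), ("b", "b"), ("a", "b")},
                     "II-proper-part-of": {("a", "b")}})
    assert check(m, [contract], None, close=False).ok
    # mutual parthood excludes both directions from proper parthood
    m2 = FiniteModel({"a", "b"}, {},
                     {"II-part-of": {("a", "b"), ("b", "a")},
                      "II-proper-part-of": set()})
    assert check(m2, [contract], None, close=False).ok
    m2.add_pair("II-proper-part-of", "a", "b")
    assert "proper-part-definition" in check(m2, [contract], None,
                                             close=False).kinds()


def test_proper_part_equals_part_minus_identity_on_posets():
    """For reflexive-transitive-antisymmetric parthood, strict pairs are
    exactly the non-identity pairs."""
    rng = random.Random(23)
    contract = proper_part_axioms()[1]
    inds = ["a", "b", "c", "d"]
    for _ in range(100):
        order = {(x, x) for x in inds}
        for x, y in itertools.combinations(inds, 2):  # respects a < b < ...
            if rng.random() < 0.4:
                order.add((x, y))
        # transitive closure keeps it a partial order
        changed = True
        while changed:
            changed = False
            for (x, y), (y2, z) in itertools.product(list(order), repeat=2):
                if y == y2 and (x, z) not in order:
                    order.add((x, z))
                    changed = True
        strict = {(x, y) for x, y in order if x != y}
        m = FiniteModel(set(inds), {}, {"II-part-of": order,
                                        "II-proper-part-of": strict})
        assert check(m, [contract], None, close=False).ok


# -- location chains ----------------------------------------------------------

def test_location_chain_axioms():
    axioms = location_chain_axioms()
    assert SubPropertyChain(["II-part-of", "II-region-of"],
                            "II-region-of") in axioms
    assert SubPropertyChain(["II-region-of", "II-part-of"],
                            "II-region-of") in axioms
    m = FiniteModel({"x", "y", "z", "u"}, {},
                    {"II-part-of": {("x", "y"), ("z", "u")},
                     "II-region-of": {("y", "z")}})
    closed = closure(m, axioms)
    # part then located propagates, and located then part propagates
    assert ("x", "z") in closed.pairs("II-region-of")
    assert ("y", "u") in closed.pairs("II-region-of")
    assert closed == naive_closure(m, axioms)
    empty = closure(FiniteModel({"x"}), axioms)
    assert empty.pairs("II-region-of") == set()
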