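"""Finite-model checker: closure properties, flag semantics, oracle
agreement, model enumeration, and the headline counterexample pair."""

import itertools

import pytest

from ggprel.axioms import (Exists, Intersection, Named, SubClassOf,
                           SubPropertyChain, TransitiveProperty)
from ggprel.checker import (FiniteModel, build_canonical_model, check,
                            closure, enumerate_models, random_models)
from ggprel.convert import verify_annotation
from ggprel.fixtures import counterexample_document
from ggprel.reference import (compare_on_model, naive_closure,
                              smallscope_suite)
from ggprel.relations import build_genia_taxonomy

TAX = build_genia_taxonomy()


# -- closure ------------------------------------------------------------------

def test_chain_firing_adds_location():
    axioms = [SubPropertyChain(["II-part-of", "II-region-of"], "II-region-of")]
    m = FiniteModel({"x", "y", "z"}, {},
                    {"II-part-of": {("x", "y")},
                     "II-region-of": {("y", "z")}})
    closed = closure(m, axioms)
    assert ("x", "z") in closed.pairs("II-region-of")


def test_transitive_chain():
    axioms = [TransitiveProperty("II-part-of")]
    m = FiniteModel({"a", "b", "c"}, {},
                    {"II-part-of": {("a", "b"), ("b", "c")}})
    closed = closure(m, axioms)
    assert ("a", "c") in closed.pairs("II-part-of")


def test_closure_idempotent_and_monotone_on_random_models():
    axioms, _ = smallscope_suite(["c0", "c1"], ["r0", "r1"])
    # the suite's rule-like subset only (contracts don't close anything)
    for m in random_models(["c0", "c1"], ["r0", "r1"], 4, 60, seed=3):
        c1 = closure(m, axioms)
        assert closure(c1, axioms) == c1, "closure must be idempotent"
        bigger = m.copy()
        bigger.add_pair("r0", sorted(m.individuals)[0],
                        sorted(m.individuals)[-1])
        c2 = closure(bigger, axioms)
        assert c1.issubmodel(c2), "closure must be monotone"


def test_closure_matches_naive_fixpoint_on_random_models():
    axioms, _ = smallscope_suite(["c0", "c1"], ["r0", "r1"])
    for m in random_models(["c0", "c1"], ["r0", "r1"], 5, 80, seed=9):
        assert closure(m, axioms) == naive_closure(m, axioms)


# -- check: flag semantics ----------------------------------------------------

def test_irreflexivity_violation_with_witness():
    m = FiniteModel({"g"}, {}, {"II-has-mutant": {("g", "g")}})
    report = check(m, [], TAX, close=False)
    entries = report.by_kind("irreflexivity")
    assert entries and entries[0].witnesses == ("g",)
    assert entries[0].subject == "II-has-mutant"


def test_strong_supplementation_models():
    """A composite with two atoms satisfies strong supplementation; two
    wholes coinciding on their single atom violate it (every part of one
    overlaps the other, yet neither is part of the other)."""
    from ggprel.fixtures import oc_parthood_models
    satisfying, violating = oc_parthood_models()
    assert check(satisfying, [], TAX, close=False).ok
    report = check(violating, [], TAX, close=False)
    entries = report.by_kind("strong-supplementation")
    assert entries
    # the two coinciding wholes witness the violation in both directions
    assert {e.witnesses for e in entries} >= {("x", "y"), ("y", "x")}


def test_nothing_constraint_checked():
    constraint = SubClassOf(
        Intersection([Named("Protein_complex"),
                      Exists("II-has-part", Named("DNA"))]),
        __import__("ggprel.axioms", fromlist=["NOTHING"]).NOTHING)
    m = FiniteModel({"cx", "d"},
                    {"Protein_complex": {"cx"}, "DNA": {"d"}},
                    {"II-has-part": {("cx", "d")}})
    report = check(m, [constraint], None, close=False)
    assert report.by_kind("subclass")[0].witnesses == ("cx",)


# -- small-scope oracle equivalence -------------------------------------------

def test_exhaustive_small_scope_agreement():
    """On every model with <= 2 individuals over 2 classes / 2 relations,
    closure equals the naive fixpoint and every checker verdict equals
    direct first-order evaluation."""
    axioms, tax = smallscope_suite(["c0", "c1"], ["r0", "r1"])
    total = 0
    for n in (0, 1, 2):
        for m in enumerate_models(["c0", "c1"], ["r0", "r1"], n):
            assert compare_on_model(m, axioms, tax) == []
            total += 1
    assert total == 1 + 2 ** 4 + 2 ** 12


def test_random_small_scope_agreement():
    axioms, tax = smallscope_suite(["c0", "c1"], ["r0", "r1"])
    for m in random_models(["c0", "c1"], ["r0", "r1"], 5, 200, seed=41):
        assert compare_on_model(m, axioms, tax) == []


# -- enumeration --------------------------------------------------------------

def test_enumeration_counts():
    assert sum(1 for _ in enumerate_models(["c"], ["r"], 1)) == 4
    assert sum(1 for _ in enumerate_models([], [], 0)) == 1
    assert sum(1 for _ in enumerate_models(["c"], ["r"], 2)) == 2 ** (2 + 4)


def test_enumeration_guard():
    with pytest.raises(ValueError):
        list(enumerate_models(["c"], ["r", "s"], 4))


def test_random_models_reproducible():
    a = [m.freeze() for m in random_models(["c"], ["r"], 4, 20, seed=7)]
    b = [m.freeze() for m in random_models(["c"], ["r"], 4, 20, seed=7)]
    c = [m.freeze() for m in random_models(["c"], ["r"], 4, 20, seed=8)]
    assert a == b
    assert a != c


# -- the headline counterexample pair -----------------------------------------

def test_generic_schema_derives_promoter_in_complex():
    """Under the generic class-level parthood schema, transitivity derives
    that the promoter is part of the protein complex, tripping the
    background constraint; the witness chain is reconstructible from the
    closed model."""
    ex = counterexample_document()
    a = ex.parse()
    axioms, model, report = verify_annotation(a, TAX, generic_schema=True)
    assert not report.ok
    complex_cls = "CD19_CD21_CD81_Leu-13_complex"
    assert any(e.kind == "subclass" and f"{complex_cls}.1" in e.witnesses
               for e in report.entries)
    # the faulty derivation chain: promoter -> CD19 -> complex
    part = model.pairs("II-part-of")
    assert ("CD19_promoter.1", "CD19.1") in part
    assert ("CD19.1", f"{complex_cls}.1") in part
    assert ("CD19_promoter.1", f"{complex_cls}.1") in part


def test_ggp_pattern_blocks_the_faulty_inference():
    """The same facts expressed through the GGP subclass pattern assign
    the promoter to the DNA subclass and the complex membership to the
    protein subclass; nothing links the promoter to the complex."""
    ex = counterexample_document()
    a = ex.parse()
    axioms, model, report = verify_annotation(a, TAX, generic_schema=False)
    assert report.ok
    complex_cls = "CD19_CD21_CD81_Leu-13_complex"
    assert not any(x == "CD19_promoter.1" and y == f"{complex_cls}.1"
                   for (x, y) in model.pairs("II-part-of"))


# -- canonical model ----------------------------------------------------------

def test_canonical_model_is_deterministic(examples_by_name):
    a = examples_by_name["cd19_promoter"].parse()
    from ggprel.convert import convert_abstract
    from ggprel.termstub import BUILTIN_CLASSES
    axioms = convert_abstract(a, TAX)
    m1 = build_canonical_model(axioms, TAX, builtin_classes=BUILTIN_CLASSES)
    m2 = build_canonical_model(axioms, TAX, builtin_classes=BUILTIN_CLASSES)
    assert m1 == m2
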