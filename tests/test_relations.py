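"""Relation taxonomy: shipped flags, hierarchy, and flag-consistency."""

import pytest

from ggprel.relations import (AxiomFlag as F, FlagConflict, RelationSpec,
                              RelationTaxonomy, TaxonomyError,
                              VARIANT_SUBRELATIONS, build_genia_taxonomy,
                              validate_flags)
from ggprel.reference import enumerate_binary_relations


@pytest.fixture(scope="module")
def taxonomy():
    return build_genia_taxonomy()


@pytest.mark.parametrize("name,flags", [
    ("II-part-of", {F.REFLEXIVE, F.TRANSITIVE, F.ANTISYMMETRIC}),
    ("II-oc-part-of", {F.REFLEXIVE, F.TRANSITIVE, F.ANTISYMMETRIC,
                       F.STRONG_SUPPLEMENTATION}),
    ("II-member-of", {F.IRREFLEXIVE, F.ASYMMETRIC, F.NON_TRANSITIVE}),
    ("II-has-variant", {F.REFLEXIVE, F.SYMMETRIC, F.NON_TRANSITIVE}),
    ("II-has-mutant", {F.IRREFLEXIVE, F.SYMMETRIC, F.NON_TRANSITIVE}),
])
def test_shipped_flags(taxonomy, name, flags):
    assert taxonomy[name].flags == frozenset(flags)


def test_hierarchy_and_definitions(taxonomy):
    assert taxonomy["II-member-of"].parent == "II-proper-part-of"
    assert taxonomy["II-proper-part-of"].defined_from == "II-part-of"
    assert taxonomy["II-part-of"].inverse_of == "II-has-part"
    for name in ("GGP-subclass-has-part", "GGP-subclass-part-of",
                 "GGP-subclass-member-of", "GGP-subclass-region-of",
                 "GGP-has-variant") + VARIANT_SUBRELATIONS:
        spec = taxonomy[name]
        assert spec.level == "GGP"
        assert taxonomy[spec.defined_from].level == "II"
    for sub in VARIANT_SUBRELATIONS:
        assert taxonomy[sub].parent == "GGP-has-variant"


def test_parent_links_form_forest(taxonomy):
    # ancestors() terminates and never revisits a node for every relation
    for spec in taxonomy:
        chain = taxonomy.ancestors(spec.name)
        assert len(chain) == len(set(chain))
        assert spec.name not in chain


def test_cyclic_parent_links_rejected():
    with pytest.raises(TaxonomyError):
        RelationTaxonomy({
            "a": RelationSpec("a", "II", parent="b"),
            "b": RelationSpec("b", "II", parent="a"),
        })


def test_ggp_relation_requires_primitive():
    with pytest.raises(TaxonomyError):
        RelationTaxonomy({"g": RelationSpec("g", "GGP")})


def test_every_shipped_spec_has_consistent_flags(taxonomy):
    for spec in taxonomy:
        assert validate_flags(spec) == []


def test_contradictory_pairs_detected():
    spec = RelationSpec("bad", "II", frozenset({F.REFLEXIVE, F.IRREFLEXIVE}))
    conflicts = validate_flags(spec)
    assert len(conflicts) == 1
    assert set(conflicts[0].flags) == {F.REFLEXIVE, F.IRREFLEXIVE}


def test_forced_empty_flag_set_detected():
    """Symmetric + antisymmetric confines a relation to loops; adding
    irreflexivity then admits only the empty relation."""
    spec = RelationSpec("bad", "II", frozenset(
        {F.SYMMETRIC, F.ANTISYMMETRIC, F.IRREFLEXIVE}))
    conflicts = validate_flags(spec)
    assert [c.kind for c in conflicts] == ["forced-empty"]
    # independent confirmation by enumerating all 16 relations on 2 elements
    def ok(rel):
        return (all((y, x) in rel for x, y in rel)                # symmetric
                and all(x == y or (y, x) not in rel for x, y in rel)  # antisym
                and all(x != y for x, y in rel))                  # irreflexive
    satisfying = [r for r in enumerate_binary_relations(2) if ok(r)]
    assert satisfying == [frozenset()]


def test_satisfying_model_exists_and_checker_accepts_it(taxonomy):
    """Cross-module round trip: for every shipped relation a nonempty
    finite model satisfying its flags exists (found by enumeration on 2
    elements) and passes the checker."""
    from ggprel.checker import FiniteModel, check
    from ggprel.reference import flag_satisfied
    for spec in taxonomy:
        mini = RelationTaxonomy({spec.name: RelationSpec(
            spec.name, "II", spec.flags)})
        found = None
        for rel in enumerate_binary_relations(2):
            pairs = {(f"x{a}", f"x{b}") for a, b in rel}
            m = FiniteModel({"x0", "x1"}, {}, {spec.name: pairs})
            if rel and all(flag_satisfied(m, spec.name, f)
                           for f in spec.flags):
                found = m
                break
        assert found is not None, spec.name
        assert check(found, [], mini, close=False).ok, spec.name


def test_yaml_export_contains_flags(taxonomy):
    import yaml
    doc = yaml.safe_load(taxonomy.to_yaml())
    assert doc["II-part-of"]["flags"] == ["antisymmetric", "reflexive",
                                          "transitive"]
    assert doc["GGP-has-mutant"]["defined_from"] == "II-has-mutant"
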