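"""Fixture generation: worked-example coverage, corpus determinism, and
checker sensitivity/specificity on labelled corruptions."""

import json

import pytest

from ggprel.axioms import (Exists, PatternContract, SubClassOf,
                           SubPropertyChain, SubPropertyOf)
from ggprel.convert import convert_abstract, verify_annotation
from ggprel.fixtures import (CONSISTENT, CORRUPTION_EXPECTATIONS,
                             INCONSISTENT_GENERIC, counterexample_document,
                             oc_parthood_models, random_corpus,
                             worked_examples)
from ggprel.relations import build_genia_taxonomy
from ggprel.standoff import AnnotationError, parse_annotation, write_annotation

TAX = build_genia_taxonomy()


def test_worked_examples_cover_required_cases(examples):
    names = {e.name for e in examples}
    assert len(examples) >= 10
    assert {"cd19_equivalence", "cd19_promoter", "cd19_locus",
            "cd19_human_subclass", "hoxa1_family", "lck_src_family",
            "tr_alpha_modified", "acta1_isoform", "tnfri_mutant",
            "oct2_recombinant", "il16_precursor", "gata3_antisense",
            "cd19_complex_faulty"} <= names
    tags = {e.name: e.tag for e in examples}
    assert tags["cd19_complex_faulty"] == INCONSISTENT_GENERIC
    assert all(t == CONSISTENT for n, t in tags.items()
               if n != "cd19_complex_faulty")


def test_worked_examples_parse_and_round_trip(examples):
    for ex in examples:
        a = ex.parse()
        txt, ann = write_annotation(a)
        assert parse_annotation(txt, ann, doc_id=ex.name) == a


def _referenced_relations(axioms):
    out = set()
    for a in axioms:
        if isinstance(a, SubClassOf):
            stack = [a.sub, a.sup]
            while stack:
                e = stack.pop()
                if isinstance(e, Exists):
                    out.add(e.relation)
                    stack.append(e.filler)
                elif hasattr(e, "parts"):
                    stack.extend(e.parts)
                elif hasattr(e, "expr"):
                    stack.append(e.expr)
        elif isinstance(a, PatternContract):
            pl = a.payload
            for key in ("primitive", "relation", "transcribed_from",
                        "translated_from"):
                if key in pl:
                    out.add(pl[key])
        elif isinstance(a, SubPropertyChain):
            out.update(a.chain)
            out.add(a.sup)
    return out


def test_fixture_set_covers_every_taxonomy_relation(examples):
    """Every relation identifier in the shipped taxonomy is exercised at
    least once: instantiated in a worked-example canonical model, named by
    a pattern contract, applied as the generic CC-level schema, or
    exercised by the component-object parthood model fixture."""
    used = set()
    for ex in examples:
        a = ex.parse()
        axioms, model, _ = verify_annotation(a, TAX)
        used |= {rel for rel, pairs in model.rel_ext.items() if pairs}
        used |= _referenced_relations(axioms)
        generic = convert_abstract(a, TAX, background=False,
                                   generic_schema=True)
        # the generic conversions instantiate the CC-level schema
        if any(isinstance(x, SubClassOf) and isinstance(x.sup, Exists)
               and x.source for x in generic):
            used |= {"CC-part-of", "CC-has-part"}
    sat, _ = oc_parthood_models()
    used |= set(sat.rel_ext)
    missing = {s.name for s in TAX} - used
    assert not missing, f"taxonomy relations never exercised: {missing}"


def test_counterexample_document_flagged_only_under_generic_schema():
    ex = counterexample_document()
    a = ex.parse()
    assert not verify_annotation(a, TAX, generic_schema=True)[2].ok
    assert verify_annotation(a, TAX, generic_schema=False)[2].ok


# -- random corpora -----------------------------------------------------------

def test_random_corpus_is_seed_deterministic():
    a = random_corpus(5, 42, 0.0)
    b = random_corpus(5, 42, 0.0)
    assert a == b
    assert random_corpus(5, 43, 0.0) != a


def test_random_corpus_rejects_bad_rate():
    with pytest.raises(ValueError):
        random_corpus(1, 0, 1.5)


def test_clean_corpus_has_zero_violations():
    """Specificity: no false alarms on uncorrupted documents."""
    for doc in random_corpus(40, 3, 0.0):
        assert doc.corruptions == ()
        _, _, report = verify_annotation(doc.parse(), TAX)
        assert report.ok, f"{doc.doc_id}: {report.to_json()}"


def test_every_corruption_type_is_detected_with_expected_category():
    """Sensitivity: each injected corruption is flagged with its expected
    violation category (or fails validation, for dangling references)."""
    seen = set()
    for doc in random_corpus(60, 5, 1.0):
        assert len(doc.corruptions) == 1
        label = doc.corruptions[0]
        seen.add(label)
        expected = CORRUPTION_EXPECTATIONS[label]
        try:
            _, _, report = verify_annotation(doc.parse(), TAX)
        except AnnotationError:
            assert expected == ("parse-error",)
            continue
        assert set(expected) & report.kinds(), \
            f"{doc.doc_id} ({label}): got {sorted(report.kinds())}"
    assert seen == set(CORRUPTION_EXPECTATIONS)


def test_mutant_self_loop_triggers_irreflexivity_specifically():
    docs = [d for d in random_corpus(60, 5, 1.0)
            if d.corruptions == ("mutant-self-loop",)]
    assert docs
    _, _, report = verify_annotation(docs[0].parse(), TAX)
    assert any(e.subject == "II-has-mutant"
               for e in report.by_kind("irreflexivity"))
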