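"""Fixture documents: the worked examples and randomized corpora.

The worked examples are short synthetic sentences (no corpus text is
redistributed) embedding the entity names of the formalization's running
examples: the CD19 equivalence trio, the CD19 promoter / locus / human
subclass cases, Hox family and Src family membership, and the six variance
relationships (modified protein, isoform, mutant, recombinant, precursor,
experimental material).  One document deliberately reproduces the faulty
inference the generic class-level parthood schema licenses — a promoter
derived to be part of a protein complex — and is tagged accordingly.

:func:`random_corpus` generates seeded template-based documents, optionally
injecting corruptions from a typed menu (mutant self-loop, membership
cycle, kind-disjointness clash, dangling argument reference), each carrying
its ground-truth label so checker sensitivity/specificity can be measured.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

from .standoff import AbstractAnnotation, parse_annotation

CONSISTENT = "consistent"
INCONSISTENT_GENERIC = "inconsistent-under-generic-schema"

#: Corruption menu: label -> violation kinds the checker is expected to
#: raise for it ("parse-error" marks documents that must fail validation).
CORRUPTION_EXPECTATIONS: Dict[str, Tuple[str, ...]] = {
    "mutant-self-loop": ("irreflexivity",),
    "membership-cycle": ("asymmetry", "antisymmetry"),
    "kind-disjointness-clash": ("disjointness",),
    "dangling-arg": ("parse-error",),
}


@dataclass(frozen=True)
class WorkedExample:
    name: str
    txt: str
    ann: str
    tag: str

    def parse(self) -> AbstractAnnotation:
        return parse_annotation(self.txt, self.ann, doc_id=self.name)


@dataclass(frozen=True)
class CorpusDoc:
    doc_id: str
    txt: str
    ann: str
    corruptions: Tuple[str, ...]

    def parse(self) -> AbstractAnnotation:
        return parse_annotation(self.txt, self.ann, doc_id=self.doc_id)


# ---------------------------------------------------------------------------
# Document assembly
# ---------------------------------------------------------------------------

def _doc(sentence: str, mentions: Sequence[Tuple[str, str]],
         relations: Sequence[Tuple[str, int, int]] = (),
         equivs: Sequence[Sequence[int]] = ()) -> Tuple[str, str]:
    """Build a (text, standoff) pair.

    ``mentions`` are (surface, term class) pairs located by first
    occurrence search (later mentions resume after the previous match of
    the same surface); ``relations`` are (label, arg1 index, arg2 index);
    ``equivs`` are index groups.
    """
    lines: List[str] = []
    cursor: Dict[str, int] = {}
    for i, (surface, cls) in enumerate(mentions, start=1):
        start = sentence.index(surface, cursor.get(surface, 0))
        cursor[surface] = start + 1
        lines.append(f"T{i}\t{cls} {start} {start + len(surface)}\t{surface}")
    for j, (label, a1, a2) in enumerate(relations, start=1):
        lines.append(f"R{j}\t{label} Arg1:T{a1} Arg2:T{a2}")
    for group in equivs:
        lines.append("*\tEquiv " + " ".join(f"T{i}" for i in group))
    return sentence, "\n".join(lines) + "\n"


def worked_examples() -> List[WorkedExample]:
    docs: List[WorkedExample] = []

    def add(name: str, tag: str, sentence: str, mentions, relations=(),
            equivs=()):
        txt, ann = _doc(sentence, mentions, relations, equivs)
        docs.append(WorkedExample(name, txt, ann, tag))

    add("cd19_equivalence", CONSISTENT,
        "CD19, the CD19 protein and the CD19 gene denote one gene or gene "
        "product.",
        [("CD19", "Protein"), ("CD19 protein", "Protein"),
         ("CD19 gene", "DNA")],
        equivs=[(1, 2, 3)])

    add("cd19_promoter", CONSISTENT,
        "The CD19 promoter is a component of the CD19 gene, here called "
        "CD19.",
        [("CD19 promoter", "DNA_domain_or_region"), ("CD19 gene", "DNA"),
         ("CD19", "Protein")],
        relations=[("Object-Component", 3, 1)],
        equivs=[(2, 3)])

    add("cd19_locus", CONSISTENT,
        "CD19, encoded by the CD19 gene, is located at the CD19 locus.",
        [("CD19", "Protein"), ("CD19 gene", "DNA"),
         ("CD19 locus", "DNA_domain_or_region")],
        relations=[("Object-Region", 1, 3)],
        equivs=[(1, 2)])

    add("cd19_human_subclass", CONSISTENT,
        "The human CD19 gene is a CD19 gene.",
        [("human CD19 gene", "DNA"), ("CD19", "DNA")],
        relations=[("Subclass", 1, 2)])

    add("hoxa1_family", CONSISTENT,
        "HOXA1 is a member of the Hox gene family.",
        [("HOXA1", "DNA"), ("Hox gene family", "DNA_family_or_group")],
        relations=[("Member-Collection", 1, 2)])

    add("lck_src_family", CONSISTENT,
        "Lck is a member of the Src family.",
        [("Lck", "Protein"), ("Src family", "Protein_family_or_group")],
        relations=[("Member-Collection", 1, 2)])

    add("tr_alpha_modified", CONSISTENT,
        "35S-TR alpha 1 is a modified form of TR alpha 1.",
        [("TR alpha 1", "Protein"), ("35S-TR alpha 1", "Protein")],
        relations=[("Object-Variant:Modified-Protein", 1, 2)])

    add("tr_alpha_variant", CONSISTENT,
        "TR alpha 2 is a variant of TR alpha 1.",
        [("TR alpha 1", "Protein"), ("TR alpha 2", "Protein")],
        relations=[("Object-Variant", 1, 2)])

    add("acta1_isoform", CONSISTENT,
        "G-Actin is an isoform of ACTA1.",
        [("ACTA1", "Protein"), ("G-Actin", "Protein")],
        relations=[("Object-Variant:Isoform", 1, 2)])

    add("tnfri_mutant", CONSISTENT,
        "The dominant-negative mutant TNFRI blocks signalling by TNFRI.",
        [("TNFRI", "Protein"), ("dominant-negative mutant TNFRI", "Protein")],
        relations=[("Object-Variant:Mutant", 1, 2)])

    add("oct2_recombinant", CONSISTENT,
        "The Oct-2 expression vector drives expression of Oct-2.",
        [("Oct-2", "Protein"), ("Oct-2 expression vector", "DNA")],
        relations=[("Object-Variant:Recombinant", 1, 2)])

    add("il16_precursor", CONSISTENT,
        "Pro-IL-16 is cleaved to yield mature IL-16.",
        [("IL-16", "Protein"), ("Pro-IL-16", "Protein")],
        relations=[("Object-Variant:Precursor", 1, 2)])

    add("gata3_antisense", CONSISTENT,
        "Antisense GATA-3 RNA suppresses GATA-3.",
        [("GATA-3", "Protein"), ("Antisense GATA-3 RNA", "RNA")],
        relations=[("Object-Variant:Experimental-Material", 1, 2)])

    # under the generic class-level schema these two component annotations,
    # with transitive parthood, derive that the promoter is part of the
    # protein complex — which the background constraint rejects; the GGP
    # subclass pattern assigns the promoter to the DNA subclass and the
    # complex membership to the protein subclass, blocking the inference
    add("cd19_complex_faulty", INCONSISTENT_GENERIC,
        "The CD19 promoter is part of the CD19 gene; CD19 is a component "
        "of the CD19/CD21/CD81/Leu-13 complex.",
        [("CD19 promoter", "DNA_domain_or_region"), ("CD19 gene", "DNA"),
         ("CD19", "Protein"), ("CD19/CD21/CD81/Leu-13 complex", "Protein_complex")],
        relations=[("Object-Component", 3, 1), ("Object-Component", 4, 3)],
        equivs=[(2, 3)])

    return docs


def oc_parthood_models():
    """Finite models exercising component-object parthood
    (``II-oc-part-of``) and its strong-supplementation principle.

    Returns ``(satisfying, violating)``: a composite with two atoms
    satisfies the principle; two distinct wholes sharing their only atom
    violate it (every part of one whole overlaps the other, yet neither is
    part of the other — extensional mereology rejects such coincidence).
    """
    from .checker import FiniteModel
    satisfying = FiniteModel(
        {"c", "a", "b"}, {},
        {"II-oc-part-of": {("c", "c"), ("a", "a"), ("b", "b"),
                           ("a", "c"), ("b", "c")}})
    violating = FiniteModel(
        {"x", "y", "a"}, {},
        {"II-oc-part-of": {("x", "x"), ("y", "y"), ("a", "a"),
                           ("a", "x"), ("a", "y")}})
    return satisfying, violating


def counterexample_document() -> WorkedExample:
    """The document reproducing the faulty promoter-in-complex inference."""
    return next(d for d in worked_examples()
                if d.tag == INCONSISTENT_GENERIC)


# ---------------------------------------------------------------------------
# Randomized corpora
# ---------------------------------------------------------------------------

_GENE_POOL = (
    "CD19", "HOXA1", "Lck", "GATA-3", "TNFRI", "IL-16", "Oct-2", "STAT1",
    "ACTA1", "NFAT1", "IRF4", "CD28", "TAL1", "PU-1", "RelB", "Fyn",
)

_TEMPLATES = ("component", "member", "region", "subclass", "isoform",
              "mutant", "precursor", "recombinant", "modified",
              "experimental", "equivalence")


def _template_doc(kind: str, genes: Sequence[str]):
    g, h = genes[0], genes[1]
    if kind == "component":
        return (f"The {g} promoter is a component of the {g} gene, also "
                f"written {g}.",
                [(f"{g} promoter", "DNA_domain_or_region"),
                 (f"{g} gene", "DNA"), (g, "Protein")],
                [("Object-Component", 3, 1)], [(2, 3)])
    if kind == "member":
        return (f"{g} is a member of the {h} family.",
                [(g, "Protein"), (f"{h} family", "Protein_family_or_group")],
                [("Member-Collection", 1, 2)], [])
    if kind == "region":
        return (f"The {g} gene, {g}, is located at the {g} locus.",
                [(f"{g} gene", "DNA"), (g, "Protein"),
                 (f"{g} locus", "DNA_domain_or_region")],
                [("Object-Region", 2, 3)], [(1, 2)])
    if kind == "subclass":
        return (f"The human {g} gene is a {g} gene.",
                [(f"human {g} gene", "DNA"), (g, "DNA")],
                [("Subclass", 1, 2)], [])
    if kind == "isoform":
        return (f"The {g} beta chain is an isoform of {g}.",
                [(g, "Protein"), (f"{g} beta chain", "Protein")],
                [("Object-Variant:Isoform", 1, 2)], [])
    if kind == "mutant":
        return (f"The dominant-negative mutant {g} inhibits {g}.",
                [(g, "Protein"), (f"dominant-negative mutant {g}", "Protein")],
                [("Object-Variant:Mutant", 1, 2)], [])
    if kind == "precursor":
        return (f"Pro-{g} is the precursor of {g}.",
                [(g, "Protein"), (f"Pro-{g}", "Protein")],
                [("Object-Variant:Precursor", 1, 2)], [])
    if kind == "recombinant":
        return (f"The {g} expression vector encodes {g}.",
                [(g, "Protein"), (f"{g} expression vector", "DNA")],
                [("Object-Variant:Recombinant", 1, 2)], [])
    if kind == "modified":
        return (f"Phospho-{g} is a modified form of {g}.",
                [(g, "Protein"), (f"Phospho-{g}", "Protein")],
                [("Object-Variant:Modified-Protein", 1, 2)], [])
    if kind == "experimental":
        return (f"Antisense {g} RNA was used to silence {g}.",
                [(g, "Protein"), (f"Antisense {g} RNA", "RNA")],
                [("Object-Variant:Experimental-Material", 1, 2)], [])
    if kind == "equivalence":
        return (f"{g}, the {g} protein and the {g} gene denote one gene or "
                f"gene product.",
                [(g, "Protein"), (f"{g} protein", "Protein"),
                 (f"{g} gene", "DNA")],
                [], [(1, 2, 3)])
    raise ValueError(kind)


def _corrupt(kind: str, genes: Sequence[str]):
    g, h = genes[0], genes[1]
    if kind == "mutant-self-loop":
        # both mentions denote the same class -> the variance pattern
        # forces a mutant-of self link, violating irreflexivity
        return (f"{g} is reported as a mutant of {g}.",
                [(g, "Protein"), (g, "Protein")],
                [("Object-Variant:Mutant", 1, 2)], [])
    if kind == "membership-cycle":
        return (f"{g} is a member of the {h} family, and the {h} family is "
                f"a member of {g}.",
                [(g, "Protein"), (f"{h} family", "Protein_family_or_group")],
                [("Member-Collection", 1, 2), ("Member-Collection", 2, 1)], [])
    if kind == "kind-disjointness-clash":
        # the same surface typed both DNA and Protein mints one class
        # subsumed by two disjoint kinds
        return (f"{g} binds {g} at the promoter.",
                [(g, "DNA"), (g, "Protein")], [], [])
    if kind == "dangling-arg":
        txt, mentions, relations, equivs = _template_doc("member", genes)
        relations = [("Member-Collection", 1, 99)]
        return txt, mentions, relations, equivs
    raise ValueError(kind)


def random_corpus(n_docs: int, seed: int,
                  corruption_rate: float) -> List[CorpusDoc]:
    """Seeded template-based documents with labelled corruptions.

    Each document is drawn uniformly from the template grammar; with
    probability ``corruption_rate`` it is replaced by one corrupted
    document drawn from the typed menu, with its ground-truth label
    recorded in ``corruptions``.  Deterministic per seed.
    """
    if not 0.0 <= corruption_rate <= 1.0:
        raise ValueError(f"corruption_rate must be in [0, 1], got "
                         f"{corruption_rate}")
    rng = random.Random(seed)
    menu = sorted(CORRUPTION_EXPECTATIONS)
    docs: List[CorpusDoc] = []
    for i in range(n_docs):
        genes = rng.sample(_GENE_POOL, 2)
        if rng.random() < corruption_rate:
            label = rng.choice(menu)
            sentence, mentions, relations, equivs = _corrupt(label, genes)
            corruptions: Tuple[str, ...] = (label,)
        else:
            template = rng.choice(_TEMPLATES)
            sentence, mentions, relations, equivs = _template_doc(template, genes)
            corruptions = ()
        txt, ann = _doc(sentence, mentions, relations, equivs)
        docs.append(CorpusDoc(f"doc{i:04d}", txt, ann, corruptions))
    return docs
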