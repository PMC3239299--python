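"""Minimal in-repo stubs of the imported vocabularies.

The relation ontology refers to classes from the GENIA term ontology
(``DNA``, ``RNA``, ``Protein`` and their domain/region, family/group and
complex subclasses) and to the Sequence Ontology primitives
``transcribed-from`` / ``translated-from``.  The full external ontologies
are referenced by IRI only; these stubs declare just the entities the
definitions need, so conversion and testing require no download.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Tuple

from .axioms import Axiom, Declaration, Named, SubClassOf
from .relations import TRANSCRIBED_FROM, TRANSLATED_FROM, GGP_CLASS

#: The three molecular kinds a gene/gene-product class unifies.
KIND_CLASSES: Tuple[str, str, str] = ("DNA", "RNA", "Protein")

#: GENIA term classes the converter understands, mapped to their parent in
#: the stub hierarchy (the three kinds are roots).
TERM_HIERARCHY: Dict[str, str] = {
    "DNA_domain_or_region": "DNA",
    "DNA_family_or_group": "DNA",
    "DNA_molecule": "DNA",
    "RNA_domain_or_region": "RNA",
    "RNA_family_or_group": "RNA",
    "RNA_molecule": "RNA",
    "Protein_domain_or_region": "Protein",
    "Protein_family_or_group": "Protein",
    "Protein_complex": "Protein",
    "Protein_molecule": "Protein",
}

#: Classes belonging to the imported vocabularies (no prototype individual
#: is minted for them during canonical-model construction).
BUILTIN_CLASSES = set(KIND_CLASSES) | set(TERM_HIERARCHY) | {GGP_CLASS}


def kind_of(term_class: str) -> Optional[str]:
    """Molecular kind (DNA/RNA/Protein) of a GENIA term class, if any."""
    if term_class in KIND_CLASSES:
        return term_class
    parent = TERM_HIERARCHY.get(term_class)
    return parent if parent in KIND_CLASSES else None


def genia_stub_ontology() -> str:
    """Text of the GENIA term-ontology stub shipped in ``ontologies/``."""
    from .owlio import OntologyConfig, write_ontology
    axioms: List[Axiom] = [Declaration("Class", k) for k in KIND_CLASSES]
    for sub, sup in sorted(TERM_HIERARCHY.items()):
        axioms.append(Declaration("Class", sub))
        axioms.append(SubClassOf(Named(sub), Named(sup)))
    cfg = OntologyConfig(
        ontology_iri="http://example.org/ggprel/genia-term-stub",
        imports=False)
    return write_ontology(axioms, cfg)


def so_stub_ontology() -> str:
    """Text of the Sequence Ontology stub (the two derivation primitives)."""
    from .owlio import OntologyConfig, write_ontology
    axioms: List[Axiom] = [Declaration("ObjectProperty", TRANSCRIBED_FROM),
                           Declaration("ObjectProperty", TRANSLATED_FROM)]
    cfg = OntologyConfig(
        ontology_iri="http://example.org/ggprel/so-stub", imports=False)
    return write_ontology(axioms, cfg)


def stub_axioms() -> List[Axiom]:
    """Declarations and hierarchy of the stub vocabulary, as IR axioms."""
    out: List[Axiom] = [Declaration("Class", GGP_CLASS)]
    for k in KIND_CLASSES:
        out.append(Declaration("Class", k))
    for sub, sup in sorted(TERM_HIERARCHY.items()):
        out.append(Declaration("Class", sub))
        out.append(SubClassOf(Named(sub), Named(sup)))
    for rel in (TRANSCRIBED_FROM, TRANSLATED_FROM):
        out.append(Declaration("ObjectProperty", rel))
    return out
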