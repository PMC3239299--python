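"""Standoff annotation documents: parsing, validation and writing.

The dialect is the BioNLP-shared-task style used for relation annotation
layers distributed separately from the abstract text:

* term mention lines      ``Tn<TAB><Class> <start> <end><TAB><surface>``
* relation mention lines  ``Rn<TAB><Label> Arg1:Tx Arg2:Ty``
* equivalence lines       ``*<TAB>Equiv Tx Ty [Tz ...]``

Offsets are 0-based, half-open, counted in Unicode code points; the
surface string of a term line must equal the corresponding slice of the
abstract text.  Equivalence groups are normalized on parse: overlapping
groups are merged transitively, so after parsing the groups partition the
mentions they cover.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Tuple


class AnnotationError(ValueError):
    """Base class for parse and validation failures."""


class AnnotationParseError(AnnotationError):
    def __init__(self, line_no: int, message: str):
        super().__init__(f"line {line_no}: {message}")
        self.line_no = line_no


class AnnotationValidationError(AnnotationError):
    def __init__(self, ident: str, message: str, line_no: int | None = None):
        where = f"line {line_no}: " if line_no is not None else ""
        super().__init__(f"{where}{ident}: {message}")
        self.ident = ident
        self.line_no = line_no


@dataclass(frozen=True)
class TermMention:
    id: str
    term_class: str
    start: int
    end: int
    surface: str


@dataclass(frozen=True)
class RelationMention:
    id: str
    label: str
    arg1: str
    arg2: str


@dataclass(frozen=True)
class EquivLink:
    members: FrozenSet[str]

    def __init__(self, members):
        object.__setattr__(self, "members", frozenset(members))


@dataclass
class AbstractAnnotation:
    doc_id: str
    text: str
    terms: List[TermMention] = field(default_factory=list)
    relations: List[RelationMention] = field(default_factory=list)
    equivs: List[EquivLink] = field(default_factory=list)

    def term_by_id(self, tid: str) -> TermMention:
        for t in self.terms:
            if t.id == tid:
                return t
        raise KeyError(tid)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AbstractAnnotation):
            return NotImplemented
        return (self.doc_id == other.doc_id and self.text == other.text
                and self.terms == other.terms
                and self.relations == other.relations
                and sorted(self.equivs, key=lambda e: sorted(e.members))
                == sorted(other.equivs, key=lambda e: sorted(e.members)))


_T_RE = re.compile(r"^(T\d+)\t(\S+) (\d+) (\d+)\t(.*)$")
_R_RE = re.compile(r"^(R\d+)\t(\S+) Arg1:(T\d+) Arg2:(T\d+)\s*$")
_EQ_RE = re.compile(r"^\*\tEquiv((?: T\d+)+)\s*$")


def _merge_equivs(groups: List[Tuple[int, FrozenSet[str]]]) -> List[EquivLink]:
    """Transitively merge overlapping equivalence groups."""
    merged: List[set] = []
    for _line, members in groups:
        hits = [g for g in merged if g & members]
        for g in hits:
            merged.remove(g)
        new = set(members)
        for g in hits:
            new |= g
        merged.append(new)
    return [EquivLink(g) for g in sorted(merged, key=lambda g: sorted(g))]


def parse_annotation(txt_document: str, ann_document: str,
                     doc_id: str = "doc") -> AbstractAnnotation:
    """Parse and validate a (text, standoff) document pair.

    Raises :class:`AnnotationParseError` for malformed lines (with the line
    number) and :class:`AnnotationValidationError` for span/surface
    mismatches, duplicate term identifiers and dangling argument
    references (naming the offending identifier).
    """
    text = txt_document
    terms: List[TermMention] = []
    relations: List[RelationMention] = []
    raw_equivs: List[Tuple[int, FrozenSet[str]]] = []
    term_lines: Dict[str, int] = {}

    for line_no, line in enumerate(ann_document.splitlines(), start=1):
        if not line.strip():
            continue
        if line.startswith("T"):
            m = _T_RE.match(line)
            if not m:
                raise AnnotationParseError(line_no, f"malformed term line: {line!r}")
            tid, cls, start, end, surface = m.groups()
            start, end = int(start), int(end)
            if tid in term_lines:
                raise AnnotationValidationError(tid, "duplicate term identifier", line_no)
            if not (0 <= start < end <= len(text)):
                raise AnnotationValidationError(
                    tid, f"span {start}..{end} outside text of length {len(text)}",
                    line_no)
            if text[start:end] != surface:
                raise AnnotationValidationError(
                    tid, f"surface {surface!r} does not match text slice "
                         f"{text[start:end]!r}", line_no)
            term_lines[tid] = line_no
            terms.append(TermMention(tid, cls, start, end, surface))
        elif line.startswith("R"):
            m = _R_RE.match(line)
            if not m:
                raise AnnotationParseError(line_no, f"malformed relation line: {line!r}")
            rid, label, a1, a2 = m.groups()
            if a1 == a2:
                raise AnnotationValidationError(
                    rid, "relation arguments must be distinct mentions", line_no)
            relations.append(RelationMention(rid, label, a1, a2))
        elif line.startswith("*"):
            m = _EQ_RE.match(line)
            if not m:
                raise AnnotationParseError(line_no, f"malformed equivalence line: {line!r}")
            members = frozenset(m.group(1).split())
            if len(members) < 2:
                raise AnnotationParseError(line_no, "equivalence needs >= 2 members")
            raw_equivs.append((line_no, members))
        else:
            raise AnnotationParseError(line_no, f"unrecognized line: {line!r}")

    known = set(term_lines)
    for r in relations:
        for arg in (r.arg1, r.arg2):
            if arg not in known:
                raise AnnotationValidationError(
                    r.id, f"dangling argument reference {arg}")
    for line_no, members in raw_equivs:
        for tid in members:
            if tid not in known:
                raise AnnotationValidationError(
                    "Equiv", f"dangling member reference {tid}", line_no)

    return AbstractAnnotation(doc_id, text, terms, relations,
                              _merge_equivs(raw_equivs))


def write_annotation(a: AbstractAnnotation) -> Tuple[str, str]:
    """Serialize back to the (text, standoff) pair; inverse of parsing."""
    lines: List[str] = []
    for t in a.terms:
        lines.append(f"{t.id}\t{t.term_class} {t.start} {t.end}\t{t.surface}")
    for r in a.relations:
        lines.append(f"{r.id}\t{r.label} Arg1:{r.arg1} Arg2:{r.arg2}")
    for e in sorted(a.equivs, key=lambda e: sorted(e.members)):
        lines.append("*\tEquiv " + " ".join(sorted(e.members)))
    ann = "\n".join(lines)
    if ann:
        ann += "\n"
    return a.text, ann
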