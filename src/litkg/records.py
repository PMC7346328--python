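"""Core record types shared by every stage of the knowledge-graph pipeline.

Character offsets are 0-based with an INCLUSIVE ``end_index``: for a mention
of ``text_name`` inside ``sentence.text``, ``sentence.text[start_index :
end_index + 1] == text_name``.  Most NLP ecosystems use half-open spans; the
inclusive convention here mirrors the attribute table of the predication
records this toolkit consumes ("first/last character position"), so it is
stated prominently and enforced by :meth:`EntityMention.validate`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, List, Sequence, Tuple

__all__ = [
    "SOURCES",
    "EXTRACTORS",
    "ValidationError",
    "SentenceRecord",
    "EntityMention",
    "PredicationTriple",
    "TaggedDocument",
    "normalize_whitespace",
    "validate_bio",
    "repair_bio",
    "bio_spans",
]

#: Allowed provenance sources for a sentence/triple.
SOURCES = ("literature", "uptodate", "clinicaltrials", "semmeddb", "synthetic")

#: Which system produced a predication.
EXTRACTORS = ("relation_extractor", "verifier", "synthetic_gold")


class ValidationError(ValueError):
    """A record violates one of the structural invariants."""


def normalize_whitespace(text: str) -> str:
    """Collapse runs of whitespace to single spaces and strip the ends."""
    return " ".join(text.split())


@dataclass(frozen=True)
class SentenceRecord:
    """One sentence of a source document, with provenance.

    Parameters
    ----------
    doc_id:
        Source-document identifier (PubMed ID, trial or guideline id, or a
        synthetic id).
    source:
        One of :data:`SOURCES`.
    text:
        The raw sentence string.
    index:
        0-based ordinal position of the sentence within its document.
    """

    doc_id: str
    source: str
    text: str
    index: int

    def validate(self) -> None:
        if self.source not in SOURCES:
            raise ValidationError(
                f"unknown source {self.source!r} for doc {self.doc_id}"
            )
        if self.index < 0:
            raise ValidationError(f"negative sentence index in doc {self.doc_id}")
        if not self.text.strip():
            raise ValidationError(f"empty sentence text in doc {self.doc_id}")


@dataclass(frozen=True)
class EntityMention:
    """One entity occurrence in a sentence.

    ``start_index``/``end_index`` are 0-based character positions within
    ``sentence.text``; ``end_index`` is inclusive.
    """

    text_name: str
    standard_name: str
    entity_id: str
    entity_type: str
    start_index: int
    end_index: int
    sentence: SentenceRecord

    def validate(self, concepts: Iterable[str] | None = None) -> None:
        self.sentence.validate()
        n = len(self.sentence.text)
        if not (0 <= self.start_index <= self.end_index < n):
            raise ValidationError(
                f"offsets [{self.start_index}, {self.end_index}] out of range "
                f"for sentence of length {n} (doc {self.sentence.doc_id})"
            )
        span = self.sentence.text[self.start_index : self.end_index + 1]
        if span != self.text_name:
            raise ValidationError(
                f"doc {self.sentence.doc_id} sentence {self.sentence.index}: "
                f"text at [{self.start_index}, {self.end_index}] is {span!r}, "
                f"not {self.text_name!r}"
            )
        if concepts is not None and self.entity_type not in set(concepts):
            raise ValidationError(
                f"entity type {self.entity_type!r} not in schema concepts "
                f"(doc {self.sentence.doc_id})"
            )


@dataclass(frozen=True)
class PredicationTriple:
    """A (subject, relation, object) assertion extracted from one sentence."""

    subject: EntityMention
    relation: str
    object: EntityMention
    extractor: str = "relation_extractor"

    @property
    def doc_id(self) -> str:
        return self.subject.sentence.doc_id

    @property
    def source(self) -> str:
        return self.subject.sentence.source

    @property
    def sentence(self) -> SentenceRecord:
        return self.subject.sentence

    def validate(self, concepts: Iterable[str] | None = None) -> None:
        if not self.relation:
            raise ValidationError("empty relation label")
        if self.extractor not in EXTRACTORS:
            raise ValidationError(f"unknown extractor {self.extractor!r}")
        if self.subject.sentence != self.object.sentence:
            raise ValidationError(
                "subject and object mentions come from different sentences "
                f"(doc {self.subject.sentence.doc_id})"
            )
        self.subject.validate(concepts)
        self.object.validate(concepts)

    def key(self) -> Tuple[str, int, str, str, str]:
        """Content identity used for gold comparison and deduplication."""
        return (
            self.doc_id,
            self.sentence.index,
            self.subject.standard_name,
            self.relation,
            self.object.standard_name,
        )


# --------------------------------------------------------------------------
# BIO tagging utilities


def validate_bio(labels: Sequence[str]) -> List[int]:
    """Return indices of BIO violations (I-X after O, start, or B-Y/I-Y)."""
    bad = []
    prev = "O"
    for i, lab in enumerate(labels):
        if lab.startswith("I-"):
            ok = prev != "O" and prev[2:] == lab[2:]
            if not ok:
                bad.append(i)
        elif lab != "O" and not lab.startswith("B-"):
            bad.append(i)
        prev = lab
    return bad


def repair_bio(labels: Sequence[str]) -> Tuple[List[str], List[int]]:
    """Convert dangling I- tags to B-; returns (repaired labels, positions)."""
    out: List[str] = []
    fixed: List[int] = []
    prev = "O"
    for i, lab in enumerate(labels):
        if lab.startswith("I-") and (prev == "O" or prev[2:] != lab[2:]):
            lab = "B-" + lab[2:]
            fixed.append(i)
        out.append(lab)
        prev = lab
    return out, fixed


def bio_spans(labels: Sequence[str]) -> List[Tuple[int, int, str]]:
    """Extract (first_token, last_token, type) spans from a BIO sequence."""
    spans: List[Tuple[int, int, str]] = []
    start = None
    typ = ""
    for i, lab in enumerate(labels):
        if lab.startswith("B-"):
            if start is not None:
                spans.append((start, i - 1, typ))
            start, typ = i, lab[2:]
        elif lab.startswith("I-") and start is not None and lab[2:] == typ:
            continue
        else:
            if start is not None:
                spans.append((start, i - 1, typ))
                start = None
            if lab.startswith("I-"):  # dangling I- treated as its own span
                start, typ = i, lab[2:]
    if start is not None:
        spans.append((start, len(labels) - 1, typ))
    return spans


@dataclass
class TaggedDocument:
    """A document as ordered sentences of tokens with parallel BIO labels.

    ``char_offsets`` gives each token's (start, end) character positions
    within its sentence, end inclusive, consistent with
    :class:`EntityMention` offsets.
    """

    doc_id: str
    sentences: List[List[str]]
    labels: List[List[str]]
    char_offsets: List[List[Tuple[int, int]]]
    source: str = "synthetic"

    def validate(self) -> None:
        if not (len(self.sentences) == len(self.labels) == len(self.char_offsets)):
            raise ValidationError(f"ragged document {self.doc_id}")
        for s, (toks, labs, offs) in enumerate(
            zip(self.sentences, self.labels, self.char_offsets)
        ):
            if not (len(toks) == len(labs) == len(offs)):
                raise ValidationError(
                    f"doc {self.doc_id} sentence {s}: tokens/labels/offsets "
                    "are not parallel"
                )
            bad = validate_bio(labs)
            if bad:
                raise ValidationError(
                    f"doc {self.doc_id} sentence {s}: invalid BIO at "
                    f"positions {bad}"
                )
            prev_end = -1
            for tok, (a, b) in zip(toks, offs):
                if a <= prev_end or b - a + 1 != len(tok):
                    raise ValidationError(
                        f"doc {self.doc_id} sentence {s}: bad offsets "
                        f"({a}, {b}) for token {tok!r}"
                    )
                prev_end = b

    def sentence_text(self, i: int) -> str:
        """Reconstruct sentence text from tokens and offsets (gaps = spaces)."""
        toks, offs = self.sentences[i], self.char_offsets[i]
        if not toks:
            return ""
        length = offs[-1][1] + 1
        chars = [" "] * length
        for tok, (a, _b) in zip(toks, offs):
            chars[a : a + len(tok)] = list(tok)
        return "".join(chars)

    def with_labels(self, labels: List[List[str]]) -> "TaggedDocument":
        return replace(self, labels=labels)
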