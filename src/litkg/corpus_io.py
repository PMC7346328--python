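"""Readers and writers for predication records and BIO-tagged corpora.

Predication TSV dialect: UTF-8, tab-separated, one triple per row, header
row mandatory.  Tabs, newlines, carriage returns and backslashes inside
field values are backslash-escaped, so a row never spans lines.  The JSONL
dialect stores one triple as one JSON object per line.  Both round-trip
exactly.

CoNLL-style BIO corpus: ``token<TAB>start<TAB>end<TAB>label`` (character
offsets within the sentence, end inclusive), blank line between sentences,
``-DOCSTART- <doc_id>`` line between documents.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import List, Sequence, Tuple

from .records import (
    EntityMention,
    PredicationTriple,
    SentenceRecord,
    TaggedDocument,
    ValidationError,
    repair_bio,
    validate_bio,
)

__all__ = [
    "FormatError",
    "RowError",
    "PREDICATION_COLUMNS",
    "read_predications",
    "write_predications",
    "read_conll",
    "write_conll",
]

logger = logging.getLogger(__name__)


class FormatError(ValueError):
    """The file does not match the expected dialect (e.g. missing column)."""


@dataclass(frozen=True)
class RowError:
    """One malformed row, reported rather than silently dropped."""

    row: int  # 1-based data-row number (or line number for JSONL)
    doc_id: str
    message: str


PREDICATION_COLUMNS = (
    "pmid",
    "source",
    "sentence_index",
    "sentence",
    "subj_text",
    "subj_standard",
    "subj_id",
    "subj_type",
    "subj_start",
    "subj_end",
    "relation",
    "obj_text",
    "obj_standard",
    "obj_id",
    "obj_type",
    "obj_start",
    "obj_end",
    "extractor",
)

_ESCAPES = {"\\": "\\\\", "\t": "\\t", "\n": "\\n", "\r": "\\r"}
_UNESCAPES = {"\\": "\\", "t": "\t", "n": "\n", "r": "\r"}


def _escape(value: str) -> str:
    for raw, esc in _ESCAPES.items():
        value = value.replace(raw, esc)
    return value


def _unescape(value: str) -> str:
    return re.sub(r"\\(.)", lambda m: _UNESCAPES.get(m.group(1), m.group(1)), value)


def _triple_to_row(t: PredicationTriple) -> dict:
    s = t.sentence
    return {
        "pmid": s.doc_id,
        "source": s.source,
        "sentence_index": s.index,
        "sentence": s.text,
        "subj_text": t.subject.text_name,
        "subj_standard": t.subject.standard_name,
        "subj_id": t.subject.entity_id,
        "subj_type": t.subject.entity_type,
        "subj_start": t.subject.start_index,
        "subj_end": t.subject.end_index,
        "relation": t.relation,
        "obj_text": t.object.text_name,
        "obj_standard": t.object.standard_name,
        "obj_id": t.object.entity_id,
        "obj_type": t.object.entity_type,
        "obj_start": t.object.start_index,
        "obj_end": t.object.end_index,
        "extractor": t.extractor,
    }


def _row_to_triple(row: dict) -> PredicationTriple:
    sentence = SentenceRecord(
        doc_id=str(row["pmid"]),
        source=str(row["source"]),
        text=str(row["sentence"]),
        index=int(row["sentence_index"]),
    )

    def mention(prefix: str) -> EntityMention:
        return EntityMention(
            text_name=str(row[f"{prefix}_text"]),
            standard_name=str(row[f"{prefix}_standard"]),
            entity_id=str(row[f"{prefix}_id"]),
            entity_type=str(row[f"{prefix}_type"]),
            start_index=int(row[f"{prefix}_start"]),
            end_index=int(row[f"{prefix}_end"]),
            sentence=sentence,
        )

    triple = PredicationTriple(
        subject=mention("subj"),
        relation=str(row["relation"]),
        object=mention("obj"),
        extractor=str(row["extractor"]),
    )
    triple.validate()
    return triple


def read_predications(
    path: str | Path, format: str = "tsv"
) -> Tuple[List[PredicationTriple], List[RowError]]:
    """Read predication triples; malformed rows go into the error report.

    Returns ``(triples, errors)``.  A structurally broken file (missing
    mandatory column) raises :class:`FormatError`; a row that merely
    violates a record invariant (e.g. the sentence substring at
    [start, end] differs from the text name) is collected as a
    :class:`RowError` instead.
    """
    path = Path(path)
    triples: List[PredicationTriple] = []
    errors: List[RowError] = []
    if format == "tsv":
        with path.open("r", encoding="utf-8", newline="") as fh:
            lines = fh.read().split("\n")
        if lines and lines[-1] == "":
            lines.pop()
        if not lines:
            raise FormatError(f"{path}: empty file, expected a header row")
        header = lines[0].split("\t")
        missing = [c for c in PREDICATION_COLUMNS if c not in header]
        if missing:
            raise FormatError(f"{path}: missing mandatory column(s) {missing}")
        for i, line in enumerate(lines[1:], start=1):
            fields = line.split("\t")
            if len(fields) != len(header):
                errors.append(
                    RowError(i, "?", f"expected {len(header)} fields, got {len(fields)}")
                )
                continue
            row = {k: _unescape(v) for k, v in zip(header, fields)}
            _collect(row, i, triples, errors)
    elif format == "jsonl":
        with path.open("r", encoding="utf-8") as fh:
            for i, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                try:
                    obj = json.loads(line)
                except json.JSONDecodeError as exc:
                    errors.append(RowError(i, "?", f"invalid JSON: {exc}"))
                    continue
                row = _flatten_jsonl(obj, i, errors)
                if row is not None:
                    _collect(row, i, triples, errors)
    else:
        raise ValueError(f"unknown format {format!r}")
    return triples, errors


def _flatten_jsonl(obj: dict, line: int, errors: List[RowError]) -> dict | None:
    try:
        row = {
            "pmid": obj["pmid"],
            "source": obj["source"],
            "sentence_index": obj["sentence_index"],
            "sentence": obj["sentence"],
            "relation": obj["relation"],
            "extractor": obj["extractor"],
        }
        for prefix, key in (("subj", "subject"), ("obj", "object")):
            m = obj[key]
            row[f"{prefix}_text"] = m["text_name"]
            row[f"{prefix}_standard"] = m["standard_name"]
            row[f"{prefix}_id"] = m["entity_id"]
            row[f"{prefix}_type"] = m["entity_type"]
            row[f"{prefix}_start"] = m["start_index"]
            row[f"{prefix}_end"] = m["end_index"]
    except (KeyError, TypeError) as exc:
        raise FormatError(f"line {line}: missing mandatory field {exc}") from exc
    return row


def _collect(
    row: dict,
    rownum: int,
    triples: List[PredicationTriple],
    errors: List[RowError],
) -> None:
    try:
        triples.append(_row_to_triple(row))
    except (ValidationError, ValueError) as exc:
        errors.append(RowError(rownum, str(row.get("pmid", "?")), str(exc)))


def write_predications(
    triples: Sequence[PredicationTriple], path: str | Path, format: str = "tsv"
) -> Path:
    """Write triples so that :func:`read_predications` round-trips exactly."""
    path = Path(path)
    if format == "tsv":
        with path.open("w", encoding="utf-8", newline="") as fh:
            fh.write("\t".join(PREDICATION_COLUMNS) + "\n")
            for t in triples:
                row = _triple_to_row(t)
                fh.write(
                    "\t".join(_escape(str(row[c])) for c in PREDICATION_COLUMNS)
                    + "\n"
                )
    elif format == "jsonl":
        with path.open("w", encoding="utf-8") as fh:
            for t in triples:
                row = _triple_to_row(t)
                obj = {
                    "pmid": row["pmid"],
                    "source": row["source"],
                    "sentence_index": row["sentence_index"],
                    "sentence": row["sentence"],
                    "subject": {
                        "text_name": row["subj_text"],
                        "standard_name": row["subj_standard"],
                        "entity_id": row["subj_id"],
                        "entity_type": row["subj_type"],
                        "start_index": row["subj_start"],
                        "end_index": row["subj_end"],
                    },
                    "relation": row["relation"],
                    "object": {
                        "text_name": row["obj_text"],
                        "standard_name": row["obj_standard"],
                        "entity_id": row["obj_id"],
                        "entity_type": row["obj_type"],
                        "start_index": row["obj_start"],
                        "end_index": row["obj_end"],
                    },
                    "extractor": row["extractor"],
                }
                fh.write(json.dumps(obj, ensure_ascii=False) + "\n")
    else:
        raise ValueError(f"unknown format {format!r}")
    return path


# --------------------------------------------------------------------------
# CoNLL-style BIO corpus


def read_conll(path: str | Path, policy: str = "repair") -> List[TaggedDocument]:
    """Read a CoNLL-style BIO corpus.

    ``policy`` controls what happens to a dangling ``I-`` tag: ``"repair"``
    (default) converts it to ``B-`` and logs the fix; ``"reject"`` raises
    :class:`~litkg.records.ValidationError`.
    """
    if policy not in ("repair", "reject"):
        raise ValueError(f"unknown BIO policy {policy!r}")
    path = Path(path)
    docs: List[TaggedDocument] = []
    doc_id = None
    sentences: List[List[str]] = []
    labels: List[List[str]] = []
    offsets: List[List[Tuple[int, int]]] = []
    toks: List[str] = []
    labs: List[str] = []
    offs: List[Tuple[int, int]] = []

    def close_sentence() -> None:
        nonlocal toks, labs, offs
        if toks:
            sentences.append(toks)
            labels.append(labs)
            offsets.append(offs)
            toks, labs, offs = [], [], []

    def close_doc() -> None:
        nonlocal sentences, labels, offsets
        close_sentence()
        if doc_id is not None:
            doc = TaggedDocument(doc_id, sentences, labels, offsets)
            _apply_bio_policy(doc, policy)
            doc.validate()
            docs.append(doc)
        sentences, labels, offsets = [], [], []

    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if line.startswith("-DOCSTART-"):
                close_doc()
                doc_id = line[len("-DOCSTART-") :].strip() or f"doc{len(docs)}"
                continue
            if not line.strip():
                close_sentence()
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise FormatError(
                    f"{path}:{lineno}: expected token<TAB>start<TAB>end<TAB>label"
                )
            tok, a, b, lab = parts
            toks.append(tok)
            labs.append(lab)
            offs.append((int(a), int(b)))
    close_doc()
    return docs


def _apply_bio_policy(doc: TaggedDocument, policy: str) -> None:
    for s, labs in enumerate(doc.labels):
        bad = validate_bio(labs)
        if not bad:
            continue
        if policy == "reject":
            raise ValidationError(
                f"doc {doc.doc_id} sentence {s}: invalid BIO at positions {bad}"
            )
        repaired, fixed = repair_bio(labs)
        logger.warning(
            "repaired dangling I- tags in doc %s sentence %d at %s",
            doc.doc_id,
            s,
            fixed,
        )
        doc.labels[s] = repaired


def write_conll(docs: Sequence[TaggedDocument], path: str | Path) -> Path:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for doc in docs:
            fh.write(f"-DOCSTART- {doc.doc_id}\n")
            for toks, labs, offs in zip(doc.sentences, doc.labels, doc.char_offsets):
                for tok, lab, (a, b) in zip(toks, labs, offs):
                    fh.write(f"{tok}\t{a}\t{b}\t{lab}\n")
                fh.write("\n")
    return path
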