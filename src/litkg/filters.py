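"""Triple filtering: conclusiveness, schema conformance, verifier agreement.

Three independent filters, each returning a :class:`FilterReport` that
conserves its input (every triple is either retained or removed with a
reason).  The pipeline convention is ``schema_filter`` →
``drop_nonconclusive`` → ``verify_against``; the first two commute.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Sequence, Tuple

from .records import (
    EntityMention,
    PredicationTriple,
    SentenceRecord,
    normalize_whitespace,
)
from .schema import DEFAULT_VERIFIER_CONCEPTS, SchemaConfig

__all__ = [
    "REMOVAL_REASONS",
    "DEFAULT_QUESTION_CUES",
    "FilterReport",
    "VerifierPolicy",
    "is_question",
    "drop_nonconclusive",
    "schema_filter",
    "verify_against",
    "run_filter_pipeline",
]

REMOVAL_REASONS = (
    "question_sentence",
    "verifier_missing",
    "attribute_mismatch",
    "schema_violation",
)

#: Interrogative/auxiliary cue words that open a question sentence.
DEFAULT_QUESTION_CUES = frozenset(
    {
        "is", "are", "does", "do", "can", "could",
        "what", "which", "who", "how", "why", "when",
    }
)


@dataclass
class FilterReport:
    """Outcome of one filtering stage.

    ``retained`` and the triples of ``removed`` partition the input as
    multisets.  ``flagged`` lists retained triples that carry an advisory
    note (e.g. an argument exempted from verification under the
    type_scoped policy); flagged triples are still retained.
    """

    retained: List[PredicationTriple] = field(default_factory=list)
    removed: List[Tuple[PredicationTriple, str, str]] = field(default_factory=list)
    flagged: List[Tuple[PredicationTriple, str]] = field(default_factory=list)

    def removal_counts(self) -> Dict[str, int]:
        counts: Dict[str, int] = {}
        for _t, reason, _detail in self.removed:
            counts[reason] = counts.get(reason, 0) + 1
        return counts


@dataclass(frozen=True)
class VerifierPolicy:
    """How verifier agreement is enforced.

    ``strict`` requires both arguments of a triple to match a verifier
    mention on all five compared attributes.  ``type_scoped`` (default)
    exempts arguments whose type is outside the verifier's concept
    inventory — the verifier could never have produced them — and flags
    the triple instead.
    """

    mode: str = "type_scoped"
    verifier_concepts: frozenset = frozenset(DEFAULT_VERIFIER_CONCEPTS)
    # Fixed by the agreement rule; listed for the record.
    compared_attributes: Tuple[str, ...] = (
        "text_name",
        "entity_start_index",
        "entity_end_index",
        "sentence",
        "source",
    )

    def __post_init__(self) -> None:
        if self.mode not in ("strict", "type_scoped"):
            raise ValueError(f"unknown verifier mode {self.mode!r}")


def is_question(
    sentence: SentenceRecord | str, cues: Iterable[str] | None = None
) -> bool:
    """Decide whether a sentence is interrogative.

    True iff the stripped text ends with ``?`` OR begins with an
    interrogative/auxiliary cue word (case-insensitive) while containing
    no declarative terminal period.
    """
    text = sentence.text if isinstance(sentence, SentenceRecord) else sentence
    text = text.strip()
    if not text:
        return False
    if text.endswith("?"):
        return True
    cue_set = DEFAULT_QUESTION_CUES if cues is None else {c.lower() for c in cues}
    first = text.split(None, 1)[0].lower().strip(",;:")
    return first in cue_set and "." not in text


def drop_nonconclusive(
    triples: Sequence[PredicationTriple], cues: Iterable[str] | None = None
) -> FilterReport:
    """Remove triples extracted from question (non-conclusive) sentences."""
    report = FilterReport()
    for t in triples:
        if is_question(t.sentence, cues):
            report.removed.append(
                (t, "question_sentence", t.sentence.text[:80])
            )
        else:
            report.retained.append(t)
    return report


def schema_filter(
    triples: Sequence[PredicationTriple], schema: SchemaConfig
) -> FilterReport:
    """Keep only triples whose entity types and relation fit the schema."""
    report = FilterReport()
    for t in triples:
        problems = []
        for role, m in (("subject", t.subject), ("object", t.object)):
            if m.entity_type not in schema.concepts:
                problems.append(f"{role} type {m.entity_type!r} not a schema concept")
        if t.relation not in schema.relations:
            problems.append(f"relation {t.relation!r} not in whitelist")
        if problems:
            report.removed.append((t, "schema_violation", "; ".join(problems)))
        else:
            report.retained.append(t)
    return report


def _mention_fingerprint(m: EntityMention) -> tuple:
    """The five compared attributes of the agreement rule."""
    return (
        m.text_name,
        m.start_index,
        m.end_index,
        normalize_whitespace(m.sentence.text),
        m.sentence.source,
    )


def verify_against(
    triples: Sequence[PredicationTriple],
    verifier_mentions: Sequence[EntityMention],
    policy: VerifierPolicy | None = None,
) -> FilterReport:
    """Retain triples whose arguments the verifier reproduced verbatim.

    A triple is retained iff each of its arguments has a verifier mention
    agreeing on all five compared attributes (text name, start index, end
    index, sentence, source).  With ``policy.mode == "type_scoped"`` an
    argument whose type is outside the verifier's inventory is exempt and
    the triple is flagged rather than removed for that argument.  Removal
    reasons distinguish ``verifier_missing`` (the verifier produced
    nothing in that sentence) from ``attribute_mismatch``.
    """
    policy = policy or VerifierPolicy()
    by_sentence: Dict[Tuple[str, int], List[EntityMention]] = {}
    for m in verifier_mentions:
        by_sentence.setdefault((m.sentence.doc_id, m.sentence.index), []).append(m)

    report = FilterReport()
    for t in triples:
        key = (t.sentence.doc_id, t.sentence.index)
        candidates = by_sentence.get(key, [])
        fingerprints = {_mention_fingerprint(m) for m in candidates}
        verdicts = []
        flags = []
        for role, m in (("subject", t.subject), ("object", t.object)):
            if (
                policy.mode == "type_scoped"
                and m.entity_type not in policy.verifier_concepts
            ):
                flags.append(
                    f"{role} type {m.entity_type!r} outside verifier inventory; exempt"
                )
                continue
            if _mention_fingerprint(m) in fingerprints:
                continue
            if not candidates:
                verdicts.append(("verifier_missing", f"no verifier output for {role}"))
            else:
                verdicts.append(
                    (
                        "attribute_mismatch",
                        f"{role} {m.text_name!r} [{m.start_index},{m.end_index}] "
                        "has no attribute-identical verifier mention",
                    )
                )
        if verdicts:
            # verifier_missing only if nothing matched for lack of output
            reasons = {r for r, _ in verdicts}
            reason = "attribute_mismatch" if "attribute_mismatch" in reasons else "verifier_missing"
            detail = "; ".join(d for _, d in verdicts)
            report.removed.append((t, reason, detail))
        else:
            report.retained.append(t)
            if flags:
                report.flagged.append((t, "; ".join(flags)))
    return report


def run_filter_pipeline(
    triples: Sequence[PredicationTriple],
    verifier_mentions: Sequence[EntityMention],
    schema: SchemaConfig | None = None,
    policy: VerifierPolicy | None = None,
    cues: Iterable[str] | None = None,
) -> FilterReport:
    """schema_filter → drop_nonconclusive → verify_against, reports merged."""
    schema = schema or SchemaConfig.default()
    r1 = schema_filter(triples, schema)
    r2 = drop_nonconclusive(r1.retained, cues)
    r3 = verify_against(r2.retained, verifier_mentions, policy)
    return FilterReport(
        retained=r3.retained,
        removed=r1.removed + r2.removed + r3.removed,
        flagged=r3.flagged,
    )
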