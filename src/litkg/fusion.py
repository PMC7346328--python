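"""Entity mapping, alignment and type voting.

Entity mapping groups mentions by their *standard* (preferred) name, keeps
every observed surface form as a synonym, and resolves conflicting type
observations by plurality vote.  Entity alignment compares standard names
across extractors with a token-set Jaccard similarity: only an exact
token-set match (Jaccard = 1 after normalization) aligns automatically;
anything else is queued for manual review, as is a tied type vote.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Optional, Sequence, Set, Tuple

from .records import EntityMention, PredicationTriple

__all__ = [
    "CanonicalEntity",
    "CanonicalEdge",
    "AlignmentDecision",
    "ReviewItem",
    "FusionResult",
    "normalize_name",
    "name_jaccard",
    "align",
    "vote_type",
    "canonicalize_and_merge",
]

_PUNCT = re.compile(r"[^\w]+", flags=re.UNICODE)


def normalize_name(name: str) -> FrozenSet[str]:
    """Lowercase, strip punctuation to spaces, split; empty tokens dropped."""
    return frozenset(tok for tok in _PUNCT.split(name.lower()) if tok)


def name_jaccard(a: str, b: str) -> float:
    """Token-set Jaccard similarity of two names; both empty → 0."""
    ta, tb = normalize_name(a), normalize_name(b)
    union = ta | tb
    if not union:
        return 0.0
    return len(ta & tb) / len(union)


@dataclass(frozen=True)
class AlignmentDecision:
    """Outcome of comparing two standard names across extractors."""

    status: str  # "aligned" | "needs_review"
    similarity: float
    pair: Tuple[str, str]


def align(e1: str, e2: str) -> AlignmentDecision:
    """Aligned iff the normalized token sets are exactly equal (Jaccard 1)."""
    sim = name_jaccard(e1, e2)
    exact = normalize_name(e1) == normalize_name(e2) and bool(normalize_name(e1))
    return AlignmentDecision(
        status="aligned" if exact else "needs_review",
        similarity=1.0 if exact else sim,
        pair=(e1, e2),
    )


def vote_type(observations: Sequence[str]) -> Tuple[Optional[str], bool]:
    """Plurality vote over type observations.

    Returns ``(winner, tie)``; a shared top count yields ``(None, True)``
    and is escalated to manual review by the caller.
    """
    if not observations:
        raise ValueError("vote_type requires a non-empty multiset of observations")
    counts = Counter(observations)
    ranked = counts.most_common()
    if len(ranked) > 1 and ranked[0][1] == ranked[1][1]:
        return None, True
    return ranked[0][0], False


@dataclass
class CanonicalEntity:
    """A fused knowledge-graph node."""

    name: str
    synonyms: Set[str] = field(default_factory=set)
    entity_type: Optional[str] = None  # None ⇒ unresolved (tied vote)
    ids: Set[str] = field(default_factory=set)
    provenance: Set[Tuple[str, str]] = field(default_factory=set)  # (doc_id, source)


@dataclass
class CanonicalEdge:
    """A deduplicated canonical triple with unioned provenance."""

    subject: str
    relation: str
    object: str
    pmids: Set[str] = field(default_factory=set)
    sentences: Set[str] = field(default_factory=set)
    sources: Set[str] = field(default_factory=set)

    def key(self) -> Tuple[str, str, str]:
        return (self.subject, self.relation, self.object)


@dataclass(frozen=True)
class ReviewItem:
    """Something the pipeline refuses to auto-resolve."""

    kind: str  # "alignment" | "type_tie"
    detail: str
    triple: Optional[PredicationTriple] = None
    decision: Optional[AlignmentDecision] = None


@dataclass
class FusionResult:
    entities: List[CanonicalEntity]
    edges: List[CanonicalEdge]
    review_queue: List[ReviewItem]


def _span_key(m: EntityMention) -> tuple:
    return (
        m.sentence.doc_id,
        m.sentence.index,
        m.start_index,
        m.end_index,
        m.text_name,
    )


def canonicalize_and_merge(triples: Sequence[PredicationTriple]) -> FusionResult:
    """Fuse retained triples into canonical entities and deduplicated edges.

    Mentions are grouped by *normalized standard name* (not entity id,
    because the same entity can carry different ids and standard names
    across extractors); each group becomes one :class:`CanonicalEntity`
    whose node name is the most frequent raw standard name, with all text
    names kept as synonyms and the type resolved by :func:`vote_type`.

    When the same surface span was annotated with conflicting standard
    names by different extractors and the names fail :func:`align`, every
    triple touching that span goes to the review queue, as do triples
    whose endpoint entity has a tied type vote.  Every input triple maps
    to exactly one output edge or one review item.
    """
    # 1. cross-extractor alignment on identical surface spans
    span_names: Dict[tuple, Set[str]] = {}
    for t in triples:
        for m in (t.subject, t.object):
            span_names.setdefault(_span_key(m), set()).add(m.standard_name)
    conflicted_spans: Dict[tuple, AlignmentDecision] = {}
    for span, names in span_names.items():
        ordered = sorted(names)
        for i in range(len(ordered)):
            for j in range(i + 1, len(ordered)):
                decision = align(ordered[i], ordered[j])
                if decision.status == "needs_review":
                    conflicted_spans[span] = decision
                    break
            if span in conflicted_spans:
                break

    # 2. entity mapping over mentions of unconflicted triples
    groups: Dict[FrozenSet[str], List[EntityMention]] = {}
    clean_triples: List[PredicationTriple] = []
    review: List[ReviewItem] = []
    for t in triples:
        hit = next(
            (
                (m, conflicted_spans[_span_key(m)])
                for m in (t.subject, t.object)
                if _span_key(m) in conflicted_spans
            ),
            None,
        )
        if hit is not None:
            m, decision = hit
            review.append(
                ReviewItem(
                    kind="alignment",
                    detail=(
                        f"standard names {decision.pair} for span {m.text_name!r} "
                        f"disagree (Jaccard {decision.similarity:.4f})"
                    ),
                    triple=t,
                    decision=decision,
                )
            )
            continue
        clean_triples.append(t)
        for m in (t.subject, t.object):
            groups.setdefault(normalize_name(m.standard_name), []).append(m)

    entities: Dict[FrozenSet[str], CanonicalEntity] = {}
    unresolved: Set[FrozenSet[str]] = set()
    for key, mentions in groups.items():
        name_counts = Counter(m.standard_name for m in mentions)
        # deterministic: highest count, then lexicographically smallest
        best_count = max(name_counts.values())
        name = min(n for n, c in name_counts.items() if c == best_count)
        winner, tie = vote_type([m.entity_type for m in mentions])
        entity = CanonicalEntity(
            name=name,
            synonyms={m.text_name for m in mentions},
            entity_type=winner,
            ids={m.entity_id for m in mentions if m.entity_id},
            provenance={(m.sentence.doc_id, m.sentence.source) for m in mentions},
        )
        entities[key] = entity
        if tie:
            unresolved.add(key)
            review.append(
                ReviewItem(
                    kind="type_tie",
                    detail=(
                        f"entity {name!r}: tied type vote "
                        f"{dict(Counter(m.entity_type for m in mentions))}"
                    ),
                )
            )

    # 3. edge deduplication; triples touching an unresolved entity → review
    edges: Dict[Tuple[str, str, str], CanonicalEdge] = {}
    for t in clean_triples:
        skey = normalize_name(t.subject.standard_name)
        okey = normalize_name(t.object.standard_name)
        if skey in unresolved or okey in unresolved:
            review.append(
                ReviewItem(
                    kind="type_tie",
                    detail="endpoint entity has a tied type vote",
                    triple=t,
                )
            )
            continue
        ekey = (entities[skey].name, t.relation, entities[okey].name)
        edge = edges.get(ekey)
        if edge is None:
            edge = CanonicalEdge(*ekey)
            edges[ekey] = edge
        edge.pmids.add(t.doc_id)
        edge.sentences.add(t.sentence.text)
        edge.sources.add(t.source)

    kept_entities = [e for k, e in entities.items() if k not in unresolved]
    return FusionResult(
        entities=kept_entities,
        edges=list(edges.values()),
        review_queue=review,
    )
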