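"""Shared fixtures and record builders for the test suite."""

from __future__ import annotations

import pytest

from litkg.records import EntityMention, PredicationTriple, SentenceRecord
from litkg.schema import SchemaConfig
from litkg.synthetic import GenConfig, gen_gold


def make_sentence(
    text: str,
    doc_id: str = "PMID1",
    source: str = "literature",
    index: int = 0,
) -> SentenceRecord:
    return SentenceRecord(doc_id=doc_id, source=source, text=text, index=index)


def make_mention(
    surface: str,
    sentence: SentenceRecord,
    entity_type: str = "disease",
    standard_name: str | None = None,
    entity_id: str = "C1",
    occurrence: int = 0,
) -> EntityMention:
    """Locate ``surface`` inside the sentence and build a mention for it."""
    start = -1
    for _ in range(occurrence + 1):
        start = sentence.text.index(surface, start + 1)
    return EntityMention(
        text_name=surface,
        standard_name=standard_name or surface,
        entity_id=entity_id,
        entity_type=entity_type,
        start_index=start,
        end_index=start + len(surface) - 1,
        sentence=sentence,
    )


def make_triple(
    subj: EntityMention,
    relation: str,
    obj: EntityMention,
    extractor: str = "relation_extractor",
) -> PredicationTriple:
    return PredicationTriple(subject=subj, relation=relation, object=obj, extractor=extractor)


@pytest.fixture(scope="session")
def schema() -> SchemaConfig:
    return SchemaConfig.default()


@pytest.fixture(scope="session")
def gold_bundle():
    """A small deterministic gold corpus spanning all nine concepts."""
    return gen_gold(GenConfig(n_docs=30, sentences_per_doc=5, seed=11))


@pytest.fixture(scope="session")
def verifier_gold_bundle():
    """Gold corpus restricted to verifier-typable concepts (strict mode)."""
    from litkg.schema import DEFAULT_VERIFIER_CONCEPTS

    return gen_gold(
        GenConfig(
            n_docs=30,
            sentences_per_doc=5,
            seed=11,
            concepts=DEFAULT_VERIFIER_CONCEPTS,
        )
    )
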