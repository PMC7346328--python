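"""Entity mapping, Jaccard alignment and type voting."""

from __future__ import annotations

import pytest
from hypothesis import given, settings, strategies as st

from litkg.fusion import (
    align,
    canonicalize_and_merge,
    name_jaccard,
    normalize_name,
    vote_type,
)
from litkg.records import PredicationTriple

from conftest import make_mention, make_sentence, make_triple

SEMREP_NAME = "Primary carcinoma of the liver cells"
BIOIE_NAME = "Hepatocellular Carcinoma"


def test_normalize_name_rules():
    assert normalize_name("Hepatocellular Carcinoma") == {"hepatocellular", "carcinoma"}
    assert normalize_name("TGF-beta receptor-2") == {"tgf", "beta", "receptor", "2"}
    assert normalize_name("") == frozenset()
    assert normalize_name("  --  ") == frozenset()


def test_name_jaccard_examples():
    assert name_jaccard("alpha beta", "Alpha   Beta") == 1.0
    assert name_jaccard("alpha", "beta") == 0.0
    assert name_jaccard("", "") == 0.0
    assert name_jaccard(SEMREP_NAME, BIOIE_NAME) == pytest.approx(1 / 7)


@settings(derandomize=True, max_examples=200)
@given(
    a=st.text(alphabet="abc xyz-", max_size=20),
    b=st.text(alphabet="abc xyz-", max_size=20),
)
def test_name_jaccard_properties(a, b):
    s = name_jaccard(a, b)
    assert 0.0 <= s <= 1.0
    assert s == name_jaccard(b, a)
    if normalize_name(a) or normalize_name(b):
        assert (s == 1.0) == (normalize_name(a) == normalize_name(b))
    else:
        assert s == 0.0


def test_align_case_insensitive_match():
    d = align("Hepatocellular Carcinoma", "hepatocellular carcinoma")
    assert d.status == "aligned" and d.similarity == 1.0


def test_align_paper_pair_needs_review():
    d = align(SEMREP_NAME, BIOIE_NAME)
    assert d.status == "needs_review"
    assert d.similarity == pytest.approx(1 / 7)


def test_align_identical_singletons():
    assert align("sorafenib", "Sorafenib").status == "aligned"


def test_vote_type_plurality_tie_and_unanimous():
    assert vote_type(["disease", "disease", "drug"]) == ("disease", False)
    assert vote_type(["disease", "drug"]) == (None, True)
    assert vote_type(["gene"] * 5) == ("gene", False)
    with pytest.raises(ValueError):
        vote_type([])


def _hcc_triples():
    s1 = make_sentence("Alcohol can cause HCC", doc_id="P1")
    s2 = make_sentence(
        "Alcohol may cause hepatocellular carcinoma", doc_id="P2", source="semmeddb"
    )
    t1 = make_triple(
        make_mention("Alcohol", s1, "drug", "Alcohol", "C10"),
        "causes",
        make_mention("HCC", s1, "disease", "Hepatocellular Carcinoma", "C20"),
    )
    t2 = make_triple(
        make_mention("Alcohol", s2, "drug", "Alcohol", "C10"),
        "causes",
        make_mention(
            "hepatocellular carcinoma", s2, "disease", "Hepatocellular Carcinoma", "C21"
        ),
    )
    return t1, t2


def test_merge_collects_synonyms_under_standard_name():
    t1, t2 = _hcc_triples()
    result = canonicalize_and_merge([t1, t2])
    hcc = next(e for e in result.entities if e.name == "Hepatocellular Carcinoma")
    assert hcc.synonyms == {"HCC", "hepatocellular carcinoma"}
    assert hcc.entity_type == "disease"
    assert hcc.ids == {"C20", "C21"}


def test_merge_deduplicates_identical_triples_with_provenance_union():
    s_lit = make_sentence("Alcohol can cause HCC", doc_id="P1", source="literature")
    s_db = make_sentence("Alcohol can cause HCC", doc_id="P9", source="semmeddb")
    t1 = make_triple(
        make_mention("Alcohol", s_lit, "drug", "Alcohol"),
        "causes",
        make_mention("HCC", s_lit, "disease", "Hepatocellular Carcinoma"),
    )
    t2 = make_triple(
        make_mention("Alcohol", s_db, "drug", "Alcohol"),
        "causes",
        make_mention("HCC", s_db, "disease", "Hepatocellular Carcinoma"),
    )
    result = canonicalize_and_merge([t1, t2])
    (edge,) = result.edges
    assert edge.key() == ("Alcohol", "causes", "Hepatocellular Carcinoma")
    assert edge.sources == {"literature", "semmeddb"}
    assert edge.pmids == {"P1", "P9"}


def test_conflicting_span_standard_names_go_to_review():
    s = make_sentence("Alcohol can cause HCC")
    t1 = make_triple(
        make_mention("Alcohol", s, "drug", "Alcohol"),
        "causes",
        make_mention("HCC", s, "disease", SEMREP_NAME),
    )
    t2 = make_triple(
        make_mention("Alcohol", s, "drug", "Alcohol"),
        "causes",
        make_mention("HCC", s, "disease", BIOIE_NAME, entity_id="C2"),
        extractor="verifier",
    )
    result = canonicalize_and_merge([t1, t2])
    assert result.edges == []
    assert {item.kind for item in result.review_queue} == {"alignment"}
    assert len(result.review_queue) == 2  # both triples queued


def test_tied_type_vote_queues_and_emits_no_typed_node():
    s1 = make_sentence("glucagon level rose", doc_id="P1")
    s2 = make_sentence("glucagon level rose", doc_id="P2")
    base = make_mention("level", s1, "disease", "Level")
    t1 = make_triple(make_mention("glucagon", s1, "drug", "Glucagon"), "affects", base)
    t2 = make_triple(
        make_mention("glucagon", s2, "protein", "Glucagon"),
        "affects",
        make_mention("level", s2, "disease", "Level"),
    )
    result = canonicalize_and_merge([t1, t2])
    assert all(e.name != "Glucagon" for e in result.entities)
    kinds = [i.kind for i in result.review_queue]
    assert "type_tie" in kinds
    # both triples depend on the unresolved entity → no edges survive
    assert result.edges == []


def test_edge_conservation_every_triple_accounted(gold_bundle):
    result = canonicalize_and_merge(gold_bundle.gold_triples)
    keys = {t.key() for t in gold_bundle.gold_triples}
    n_edge_support = sum(len(e.pmids & {k[0] for k in keys}) > 0 for e in result.edges)
    queued = sum(1 for item in result.review_queue if item.triple is not None)
    # distinct (subject, relation, object) keys may merge, so compare via keys
    edge_keys = {(e.subject, r, e.object) for e in result.edges for r in [e.relation]}
    assert len(edge_keys) == len(result.edges)
    assert len(result.edges) + queued <= len(gold_bundle.gold_triples)
    assert queued == 0  # gold data has consistent names and types


def test_merge_idempotent_on_canonical_output(gold_bundle):
    result = canonicalize_and_merge(gold_bundle.gold_triples)
    # rebuild mention-level triples from the canonical edges and re-fuse
    rebuilt = []
    types = {e.name: e.entity_type for e in result.entities}
    for i, edge in enumerate(result.edges):
        text = f"{edge.subject} rel {edge.object}"
        s = make_sentence(text, doc_id=f"R{i}")
        rebuilt.append(
            make_triple(
                make_mention(edge.subject, s, types[edge.subject], edge.subject),
                edge.relation,
                make_mention(edge.object, s, types[edge.object], edge.object),
            )
        )
    again = canonicalize_and_merge(rebuilt)
    assert {e.key() for e in again.edges} == {e.key() for e in result.edges}
    assert {e.name for e in again.entities} == {e.name for e in result.entities}
    assert again.review_queue == []
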