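"""Conclusiveness, schema and verifier-agreement filtering."""

from __future__ import annotations

import dataclasses

import pytest

from litkg.filters import (
    VerifierPolicy,
    drop_nonconclusive,
    is_question,
    run_filter_pipeline,
    schema_filter,
    verify_against,
)
from litkg.schema import SchemaConfig
from litkg.synthetic import GenConfig, NoiseConfig, corrupt, gen_gold

from conftest import make_mention, make_sentence, make_triple

QUESTION = "Is excessive alcohol abuse one of the causes of hepatocellular carcinoma?"
DECLARATIVE = "Alcohol can cause HCC."


@pytest.mark.parametrize(
    "text,expected",
    [
        (QUESTION, True),
        (DECLARATIVE, False),
        ("", False),
        ("   ", False),
        ("What explains this finding", True),  # cue word, no terminal period
        ("Is this a question.", False),  # cue word but declarative period
        ("alcohol can cause HCC?", True),
    ],
)
def test_is_question_rule(text, expected):
    assert is_question(text) is expected


def test_is_question_custom_cue_list():
    assert is_question("Whether this holds remains open", cues=["whether"])
    assert not is_question("What explains this finding", cues=["whether"])


def _question_and_declarative_triples():
    q = make_sentence(QUESTION)
    d = make_sentence(DECLARATIVE, index=1)
    t_q = make_triple(
        make_mention("alcohol", q, "drug", "Alcohol"),
        "causes",
        make_mention("hepatocellular carcinoma", q, "disease", "Hepatocellular Carcinoma"),
    )
    t_d = make_triple(
        make_mention("Alcohol", d, "drug", "Alcohol"),
        "causes",
        make_mention("HCC", d, "disease", "Hepatocellular Carcinoma"),
    )
    return t_q, t_d


def test_drop_nonconclusive_removes_question_triples():
    t_q, t_d = _question_and_declarative_triples()
    report = drop_nonconclusive([t_q, t_d])
    assert report.retained == [t_d]
    assert [(t, r) for t, r, _d in report.removed] == [(t_q, "question_sentence")]


def test_drop_nonconclusive_empty_input():
    report = drop_nonconclusive([])
    assert report.retained == [] and report.removed == []


def test_schema_filter_relation_and_type(schema):
    s = make_sentence("sorafenib treats hepatoma")
    good = make_triple(
        make_mention("sorafenib", s, "drug"), "treats", make_mention("hepatoma", s, "disease")
    )
    bad_rel = dataclasses.replace(good, relation="mentions_in_passing")
    bad_type = make_triple(
        make_mention("sorafenib", s, "induction"), "treats", make_mention("hepatoma", s, "disease")
    )
    report = schema_filter([good, bad_rel, bad_type], schema)
    assert report.retained == [good]
    reasons = {t: r for t, r, _ in report.removed}
    assert reasons[bad_rel] == "schema_violation"
    assert reasons[bad_type] == "schema_violation"


def test_verify_against_attribute_mismatch():
    s = make_sentence(
        "Combined chitosan-mediated p53 gene therapy for hepatocellular carcinoma"
    )
    triple = make_triple(
        make_mention("gene", s, "gene"),
        "associated_with",
        make_mention("hepatocellular carcinoma", s, "disease"),
    )
    verifier = [
        make_mention("p53 gene", s, "gene"),
        make_mention("hepatocellular carcinoma", s, "disease"),
    ]
    report = verify_against([triple], verifier, VerifierPolicy(mode="strict"))
    assert report.retained == []
    ((t, reason, detail),) = report.removed
    assert reason == "attribute_mismatch" and "gene" in detail


def test_verify_against_exact_match_retained():
    s = make_sentence("sorafenib treats hepatoma in this trial")
    triple = make_triple(
        make_mention("sorafenib", s, "drug"), "treats", make_mention("hepatoma", s, "disease")
    )
    verifier = [make_mention("sorafenib", s, "drug"), make_mention("hepatoma", s, "disease")]
    report = verify_against([triple], verifier, VerifierPolicy(mode="strict"))
    assert report.retained == [triple] and report.removed == []


def test_verify_against_missing_verifier_output():
    s = make_sentence("sorafenib treats hepatoma in this trial")
    triple = make_triple(
        make_mention("sorafenib", s, "drug"), "treats", make_mention("hepatoma", s, "disease")
    )
    report = verify_against([triple], [], VerifierPolicy(mode="strict"))
    ((_t, reason, _d),) = report.removed
    assert reason == "verifier_missing"


def test_type_scoped_exempts_unverifiable_argument():
    s = make_sentence("radiofrequency ablation treats hepatoma effectively")
    triple = make_triple(
        make_mention("radiofrequency ablation", s, "therapeutic_technique"),
        "treats",
        make_mention("hepatoma", s, "disease"),
    )
    verifier = [make_mention("hepatoma", s, "disease")]
    strict = verify_against([triple], verifier, VerifierPolicy(mode="strict"))
    assert strict.retained == []
    scoped = verify_against([triple], verifier, VerifierPolicy(mode="type_scoped"))
    assert scoped.retained == [triple]
    ((flagged, note),) = scoped.flagged
    assert flagged is triple and "exempt" in note


@pytest.mark.parametrize("stage", ["question", "schema", "verify"])
def test_filters_conserve_their_input(stage, schema, gold_bundle):
    noisy = corrupt(gold_bundle, NoiseConfig(p_question=0.4, p_passive_swap=0.2, seed=3))
    triples = noisy.triples
    if stage == "question":
        report = drop_nonconclusive(triples)
    elif stage == "schema":
        report = schema_filter(triples, schema)
    else:
        report = verify_against(triples, noisy.verifier_mentions)
    assert len(report.retained) + len(report.removed) == len(triples)
    survivors = {id(t) for t in report.retained}
    assert all(id(t) not in survivors for t, _r, _d in report.removed)


@pytest.mark.parametrize("stage", ["question", "schema", "verify"])
def test_filters_are_idempotent(stage, schema, gold_bundle):
    noisy = corrupt(gold_bundle, NoiseConfig(p_question=0.3, seed=9))

    def apply(triples):
        if stage == "question":
            return drop_nonconclusive(triples).retained
        if stage == "schema":
            return schema_filter(triples, schema).retained
        return verify_against(triples, noisy.verifier_mentions).retained

    once = apply(noisy.triples)
    assert apply(once) == once


def test_question_and_schema_filters_commute(schema, gold_bundle):
    noisy = corrupt(gold_bundle, NoiseConfig(p_question=0.5, seed=2))
    a = schema_filter(drop_nonconclusive(noisy.triples).retained, schema).retained
    b = drop_nonconclusive(schema_filter(noisy.triples, schema).retained).retained
    assert a == b


def test_strict_zero_noise_retains_exactly_verifier_reproduced(verifier_gold_bundle):
    noisy = corrupt(verifier_gold_bundle, NoiseConfig(seed=0))
    report = verify_against(
        noisy.triples, noisy.verifier_mentions, VerifierPolicy(mode="strict")
    )
    assert report.retained == noisy.triples and report.removed == []


def test_pipeline_merges_stage_reports(schema, gold_bundle):
    noisy = corrupt(gold_bundle, NoiseConfig(p_question=0.3, p_boundary_truncation=0.3, seed=4))
    report = run_filter_pipeline(noisy.triples, noisy.verifier_mentions, schema=schema)
    assert len(report.retained) + len(report.removed) == len(noisy.triples)
    assert set(report.removal_counts()) <= {
        "question_sentence",
        "verifier_missing",
        "attribute_mismatch",
        "schema_violation",
    }
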