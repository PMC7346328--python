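"""End-to-end behaviour of the attention BiLSTM-CRF tagger."""

from __future__ import annotations

import numpy as np
import pytest

from litkg.records import TaggedDocument
from litkg.schema import DEFAULT_VERIFIER_CONCEPTS
from litkg.ner import AttBiLstmCrf, NerConfig, bio_transition_mask, make_tagset
from litkg.synthetic import GenConfig, gen_gold

TINY = NerConfig(
    word_dim=8,
    char_dim=4,
    char_hidden=6,
    lstm_hidden=6,
    mlp_hidden=8,
    epochs=3,
    seed=0,
)


@pytest.fixture(scope="module")
def tiny_corpus():
    bundle = gen_gold(
        GenConfig(n_docs=12, sentences_per_doc=3, seed=5, concepts=DEFAULT_VERIFIER_CONCEPTS)
    )
    return bundle.documents


@pytest.fixture(scope="module")
def tiny_model(tiny_corpus):
    return AttBiLstmCrf(TINY).fit(tiny_corpus)


def test_emission_layer_zero_weights_give_zero_scores(tiny_corpus):
    model = AttBiLstmCrf(TINY)
    model._build_vocab(tiny_corpus)
    model._init_params(np.random.default_rng(0))
    for name in ("W1", "b1", "W2", "b2"):
        model.params[name][...] = 0.0
    tokens, _ = model._doc_tokens(tiny_corpus[0])
    emissions, _cache = model._encode(tokens)
    assert emissions.shape == (len(tokens), len(model.tags))
    assert np.all(emissions == 0.0)


def test_emission_hand_case_tanh_of_one():
    # 1 token, [h; g] = [1, 0], hidden and output weights of ones → tanh(1)
    hg = np.array([[1.0, 0.0]])
    w_hidden = np.array([[1.0, 0.0]])
    w_out = np.array([[1.0]])
    emission = np.tanh(hg @ w_hidden.T) @ w_out.T
    assert emission[0, 0] == pytest.approx(np.tanh(1.0), abs=1e-12)
    assert emission[0, 0] == pytest.approx(0.7616, abs=1e-4)


def test_bio_transition_mask_blocks_invalid_moves():
    tags = make_tagset(("gene", "drug"))
    mask = bio_transition_mask(tags)
    idx = {t: i for i, t in enumerate(tags)}
    assert mask[idx["O"], idx["I-gene"]] == -np.inf
    assert mask[idx["B-drug"], idx["I-gene"]] == -np.inf
    assert mask[idx["B-gene"], idx["I-gene"]] == 0.0
    assert mask[idx["I-gene"], idx["I-gene"]] == 0.0
    assert mask[idx["I-gene"], idx["B-drug"]] == 0.0


def test_training_is_deterministic_for_a_seed(tiny_corpus):
    m1 = AttBiLstmCrf(TINY).fit(tiny_corpus)
    m2 = AttBiLstmCrf(TINY).fit(tiny_corpus)
    assert m1.history == m2.history
    for doc in tiny_corpus[:3]:
        assert m1.predict_labels(doc) == m2.predict_labels(doc)


def test_training_loss_decreases(tiny_model):
    h = tiny_model.history
    assert len(h) == TINY.epochs
    assert h[-1] < h[0]


def test_gradients_match_finite_differences(tiny_corpus):
    model = AttBiLstmCrf(TINY)
    model._build_vocab(tiny_corpus)
    model._init_params(np.random.default_rng(0))
    doc = tiny_corpus[0]
    _, grads = model._forward_backward(doc)
    rng = np.random.default_rng(1)
    eps = 1e-6
    for name in list(model.params) + ["attW"]:
        arr = model.attention.W if name == "attW" else model.params[name]
        flat = arr.reshape(-1)
        gflat = np.asarray(grads[name]).reshape(-1)
        for i in rng.choice(flat.size, size=min(4, flat.size), replace=False):
            orig = flat[i]
            flat[i] = orig + eps
            lp, _ = model._forward_backward(doc)
            flat[i] = orig - eps
            lm, _ = model._forward_backward(doc)
            flat[i] = orig
            numeric = (lp - lm) / (2 * eps)
            assert gflat[i] == pytest.approx(numeric, abs=2e-6), name


def test_predictions_are_bio_valid_and_typed(tiny_model, tiny_corpus):
    from litkg.records import validate_bio

    for doc in tiny_corpus:
        for labs in tiny_model.predict_labels(doc):
            assert validate_bio(labs) == []
            for lab in labs:
                if lab != "O":
                    assert lab[2:] in tiny_model.config.concepts


def test_tag_document_reconstructs_mentions(tiny_model, tiny_corpus):
    for doc in tiny_corpus[:5]:
        for mention in tiny_model.tag_document(doc):
            mention.validate()  # substring/offset invariant
            assert mention.entity_type in tiny_model.config.concepts


def test_tag_document_span_reconstruction_example(tiny_model, monkeypatch):
    doc = TaggedDocument(
        doc_id="PMID7",
        sentences=[["p53", "gene", "therapy"]],
        labels=[["O", "O", "O"]],
        char_offsets=[[(0, 2), (4, 7), (9, 15)]],
        source="literature",
    )
    monkeypatch.setattr(
        tiny_model, "predict_labels", lambda d: [["B-gene", "I-gene", "O"]]
    )
    (mention,) = tiny_model.tag_document(doc)
    assert mention.text_name == "p53 gene"
    assert (mention.start_index, mention.end_index) == (0, 7)
    assert mention.entity_type == "gene"


def test_tag_document_all_outside_yields_nothing(tiny_model, monkeypatch):
    doc = TaggedDocument(
        "d", [["alpha", "beta"]], [["O", "O"]], [[(0, 4), (6, 9)]]
    )
    monkeypatch.setattr(tiny_model, "predict_labels", lambda d: [["O", "O"]])
    assert tiny_model.tag_document(doc) == []


def test_adjacent_b_tags_make_two_mentions(tiny_model, monkeypatch):
    doc = TaggedDocument(
        "d", [["sorafenib", "cisplatin"]], [["O", "O"]], [[(0, 8), (10, 18)]]
    )
    monkeypatch.setattr(
        tiny_model, "predict_labels", lambda d: [["B-drug", "B-drug"]]
    )
    m1, m2 = tiny_model.tag_document(doc)
    assert (m1.text_name, m2.text_name) == ("sorafenib", "cisplatin")
    assert m1.entity_type == m2.entity_type == "drug"


def test_empty_document_tags_to_empty_list(tiny_model):
    doc = TaggedDocument("d", [], [], [])
    assert tiny_model.tag_document(doc) == []


def test_save_load_preserves_predictions(tiny_model, tiny_corpus, tmp_path):
    path = tmp_path / "model.json"
    tiny_model.save(path)
    loaded = AttBiLstmCrf.load(path)
    for doc in tiny_corpus[:4]:
        assert loaded.predict_labels(doc) == tiny_model.predict_labels(doc)


def test_unknown_labels_rejected(tiny_corpus):
    model = AttBiLstmCrf(NerConfig(concepts=("gene",), epochs=1))
    with pytest.raises(ValueError, match="outside the tag set"):
        model.fit(tiny_corpus)


def test_empty_corpus_rejected():
    with pytest.raises(ValueError, match="empty"):
        AttBiLstmCrf(TINY).fit([])
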