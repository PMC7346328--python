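"""Document-level attention BiLSTM-CRF named entity recognizer.

The model tags whole documents: token vectors (word embedding concatenated
with a recurrent character encoding) feed a BiLSTM whose per-token context
vectors H span all sentences of the document; a document-level attention
layer turns H into global vectors G = A·H; the concatenation [h_t; g_t]
passes through a tanh hidden layer and a linear projection to per-tag
emission scores; a linear-chain CRF with structurally enforced BIO
transition constraints decodes the best tag path.

Everything is plain numpy with hand-derived backpropagation and plain SGD,
sized for deterministic desk-scale training; the gradients are verified
against finite differences in the test suite.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from ..records import EntityMention, SentenceRecord, TaggedDocument, bio_spans
from ..schema import DEFAULT_VERIFIER_CONCEPTS
from .attention import (
    AttentionParams,
    attention_matrix,
    attention_matrix_backward,
    global_vectors,
    init_attention_params,
    score_matrix,
    score_matrix_backward,
)
from .crf import crf_marginals, crf_negative_log_likelihood, viterbi_decode

__all__ = ["NerConfig", "AttBiLstmCrf", "make_tagset", "bio_transition_mask", "span_prf"]

UNK = "<unk>"


@dataclass(frozen=True)
class NerConfig:
    """Hyperparameters of the recognizer.

    ``concepts`` is the entity-type inventory the tagger can produce (the
    verifier subset of the schema by default), giving a tag set of size
    2·|concepts| + 1.  ``attention_window``, when set, caps the attention
    scope to tokens within that distance; the default attends over the
    whole document.
    """

    concepts: Tuple[str, ...] = DEFAULT_VERIFIER_CONCEPTS
    variant: str = "perceptron"
    word_dim: int = 24
    char_dim: int = 8
    char_hidden: int = 16
    lstm_hidden: int = 24  # per direction; d_h = 2 · lstm_hidden
    mlp_hidden: int = 32
    lr: float = 0.5
    epochs: int = 30
    clip: float = 5.0
    seed: int = 0
    attention_window: Optional[int] = None


def make_tagset(concepts: Sequence[str]) -> List[str]:
    tags = ["O"]
    for c in concepts:
        tags += [f"B-{c}", f"I-{c}"]
    return tags


def bio_transition_mask(tags: Sequence[str]) -> np.ndarray:
    """Additive mask: −inf where a transition would break BIO validity."""
    k = len(tags)
    mask = np.zeros((k, k))
    for j, to in enumerate(tags):
        if not to.startswith("I-"):
            continue
        typ = to[2:]
        for i, frm in enumerate(tags):
            if frm[2:] != typ or frm == "O":
                mask[i, j] = -np.inf
    return mask


def _start_mask(tags: Sequence[str]) -> np.ndarray:
    """Additive mask on the first emission row: a span cannot open with I-."""
    return np.array([-np.inf if t.startswith("I-") else 0.0 for t in tags])


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


class AttBiLstmCrf:
    """Trainable document-level attention BiLSTM-CRF tagger."""

    def __init__(self, config: NerConfig | None = None) -> None:
        self.config = config or NerConfig()
        self.tags = make_tagset(self.config.concepts)
        self.vocab: Dict[str, int] = {UNK: 0}
        self.char_vocab: Dict[str, int] = {UNK: 0}
        self.params: Dict[str, np.ndarray] = {}
        self.attention: Optional[AttentionParams] = None
        self.history: List[float] = []
        self._trans_mask = bio_transition_mask(self.tags)
        self._start = _start_mask(self.tags)

    # ------------------------------------------------------------------
    # setup

    def _build_vocab(self, corpus: Sequence[TaggedDocument]) -> None:
        for doc in corpus:
            for sent in doc.sentences:
                for tok in sent:
                    self.vocab.setdefault(tok, len(self.vocab))
                    for ch in tok:
                        self.char_vocab.setdefault(ch, len(self.char_vocab))

    def _init_params(self, rng: np.random.Generator) -> None:
        c = self.config
        d_in = c.word_dim + c.char_hidden
        d_h = 2 * c.lstm_hidden
        k = len(self.tags)

        def u(*shape: int) -> np.ndarray:
            scale = 1.0 / np.sqrt(max(shape[-1], 1))
            return rng.uniform(-scale, scale, size=shape)

        p = {
            "Ew": u(len(self.vocab), c.word_dim),
            "Ec": u(len(self.char_vocab), c.char_dim),
            "Wc": u(c.char_hidden, c.char_dim),
            "Uc": u(c.char_hidden, c.char_hidden),
            "bc": np.zeros(c.char_hidden),
            "W1": u(c.mlp_hidden, 2 * d_h),
            "b1": np.zeros(c.mlp_hidden),
            "W2": u(k, c.mlp_hidden),
            "b2": np.zeros(k),
            "trans": np.zeros((k, k)),
        }
        for direction in ("f", "b"):
            p[f"Wl_{direction}"] = u(4 * c.lstm_hidden, d_in)
            p[f"Ul_{direction}"] = u(4 * c.lstm_hidden, c.lstm_hidden)
            bias = np.zeros(4 * c.lstm_hidden)
            bias[c.lstm_hidden : 2 * c.lstm_hidden] = 1.0  # forget-gate bias
            p[f"bl_{direction}"] = bias
        self.params = p
        self.attention = init_attention_params(c.variant, d_h, rng)

    # ------------------------------------------------------------------
    # encoding

    def _doc_tokens(self, doc: TaggedDocument) -> Tuple[List[str], List[int]]:
        """Flatten tokens across sentences; return tokens + sentence lengths."""
        toks: List[str] = []
        lengths: List[int] = []
        for sent in doc.sentences:
            toks.extend(sent)
            lengths.append(len(sent))
        return toks, lengths

    def _char_forward(self, tokens: Sequence[str]) -> Tuple[np.ndarray, dict]:
        p = self.params
        n = len(tokens)
        length = max(len(t) for t in tokens)
        ids = -np.ones((n, length), dtype=int)
        for i, tok in enumerate(tokens):
            for j, ch in enumerate(tok):
                ids[i, j] = self.char_vocab.get(ch, 0)
        mask = (ids >= 0).astype(float)
        emb = p["Ec"][ids.clip(0)]  # (n, L, dc)
        h = np.zeros((n, self.config.char_hidden))
        hs, hns = [], []
        for t in range(length):
            pre = emb[:, t] @ p["Wc"].T + h @ p["Uc"].T + p["bc"]
            hn = np.tanh(pre)
            m = mask[:, t : t + 1]
            hs.append(h)
            hns.append(hn)
            h = m * hn + (1.0 - m) * h
        cache = {"ids": ids, "mask": mask, "emb": emb, "hs": hs, "hns": hns}
        return h, cache

    def _char_backward(self, dh: np.ndarray, cache: dict, grads: dict) -> None:
        p = self.params
        ids, mask, emb = cache["ids"], cache["mask"], cache["emb"]
        hs, hns = cache["hs"], cache["hns"]
        demb = np.zeros_like(emb)
        for t in range(ids.shape[1] - 1, -1, -1):
            m = mask[:, t : t + 1]
            dhn = dh * m
            dh_pass = dh * (1.0 - m)
            dpre = dhn * (1.0 - hns[t] ** 2)
            grads["Wc"] += dpre.T @ emb[:, t]
            grads["Uc"] += dpre.T @ hs[t]
            grads["bc"] += dpre.sum(axis=0)
            demb[:, t] = dpre @ p["Wc"]
            dh = dpre @ p["Uc"] + dh_pass
        valid = ids >= 0
        np.add.at(grads["Ec"], ids[valid], demb[valid])

    def _lstm_forward(
        self, x: np.ndarray, direction: str
    ) -> Tuple[np.ndarray, dict]:
        p = self.params
        d = self.config.lstm_hidden
        W, U, b = p[f"Wl_{direction}"], p[f"Ul_{direction}"], p[f"bl_{direction}"]
        n = x.shape[0]
        order = range(n) if direction == "f" else range(n - 1, -1, -1)
        h = np.zeros(d)
        c = np.zeros(d)
        H = np.zeros((n, d))
        cache: List[tuple] = [()] * n
        for t in order:
            z = W @ x[t] + U @ h + b
            i = _sigmoid(z[:d])
            f = _sigmoid(z[d : 2 * d])
            o = _sigmoid(z[2 * d : 3 * d])
            g = np.tanh(z[3 * d :])
            c_new = f * c + i * g
            hc = np.tanh(c_new)
            h_new = o * hc
            cache[t] = (x[t], h, c, i, f, o, g, c_new, hc)
            h, c = h_new, c_new
            H[t] = h
        return H, {"cache": cache, "order": list(order)}

    def _lstm_backward(
        self, dH: np.ndarray, state: dict, direction: str, grads: dict
    ) -> np.ndarray:
        p = self.params
        d = self.config.lstm_hidden
        W, U = p[f"Wl_{direction}"], p[f"Ul_{direction}"]
        dx = np.zeros((dH.shape[0], W.shape[1]))
        dh_next = np.zeros(d)
        dc_next = np.zeros(d)
        for t in reversed(state["order"]):
            x_t, h_prev, c_prev, i, f, o, g, c_new, hc = state["cache"][t]
            dh = dH[t] + dh_next
            do = dh * hc
            dc = dh * o * (1.0 - hc**2) + dc_next
            df = dc * c_prev
            di = dc * g
            dg = dc * i
            dc_next = dc * f
            dz = np.concatenate(
                [
                    di * i * (1.0 - i),
                    df * f * (1.0 - f),
                    do * o * (1.0 - o),
                    dg * (1.0 - g**2),
                ]
            )
            grads[f"Wl_{direction}"] += np.outer(dz, x_t)
            grads[f"Ul_{direction}"] += np.outer(dz, h_prev)
            grads[f"bl_{direction}"] += dz
            dx[t] = W.T @ dz
            dh_next = U.T @ dz
        return dx

    def _encode(self, tokens: Sequence[str]) -> Tuple[np.ndarray, dict]:
        p = self.params
        word_ids = np.array([self.vocab.get(t, 0) for t in tokens])
        char_feat, char_cache = self._char_forward(tokens)
        x = np.concatenate([p["Ew"][word_ids], char_feat], axis=1)
        Hf, sf = self._lstm_forward(x, "f")
        Hb, sb = self._lstm_forward(x, "b")
        H = np.concatenate([Hf, Hb], axis=1)
        S = score_matrix(H, self.attention)
        if self.config.attention_window is not None:
            n = H.shape[0]
            idx = np.arange(n)
            outside = np.abs(idx[:, None] - idx[None, :]) > self.config.attention_window
            S = S + np.where(outside, -1e30, 0.0)
        A = attention_matrix(S)
        G = global_vectors(A, H)
        hg = np.concatenate([H, G], axis=1)
        pre1 = hg @ p["W1"].T + p["b1"]
        a1 = np.tanh(pre1)
        emissions = a1 @ p["W2"].T + p["b2"]
        cache = {
            "word_ids": word_ids,
            "char_cache": char_cache,
            "x": x,
            "sf": sf,
            "sb": sb,
            "H": H,
            "S": S,
            "A": A,
            "G": G,
            "hg": hg,
            "a1": a1,
        }
        return emissions, cache

    # ------------------------------------------------------------------
    # loss and gradients

    def _forward_backward(
        self, doc: TaggedDocument
    ) -> Tuple[float, Dict[str, np.ndarray]]:
        """Per-token-normalized NLL and gradients for one document."""
        tokens, _ = self._doc_tokens(doc)
        gold = [
            self.tags.index(lab) if lab in self.tags else -1
            for labs in doc.labels
            for lab in labs
        ]
        if any(y < 0 for y in gold):
            unknown = sorted(
                {lab for labs in doc.labels for lab in labs if lab not in self.tags}
            )
            raise ValueError(f"corpus labels outside the tag set: {unknown}")
        n = len(tokens)
        emissions, cache = self._encode(tokens)
        trans_eff = self.params["trans"] + self._trans_mask
        emis_eff = emissions.copy()
        emis_eff[0] = emis_eff[0] + self._start
        loss = crf_negative_log_likelihood(emis_eff, trans_eff, gold) / n
        unary, pairwise, _ = crf_marginals(emis_eff, trans_eff)

        grads: Dict[str, np.ndarray] = {
            k: np.zeros_like(v) for k, v in self.params.items()
        }
        grads["attW"] = np.zeros_like(self.attention.W)

        demis = unary.copy()
        demis[np.arange(n), gold] -= 1.0
        demis /= n
        dtrans = pairwise.copy()
        for t in range(1, n):
            dtrans[gold[t - 1], gold[t]] -= 1.0
        grads["trans"] += dtrans / n

        p = self.params
        a1, hg, H, A, S, G = (
            cache["a1"],
            cache["hg"],
            cache["H"],
            cache["A"],
            cache["S"],
            cache["G"],
        )
        grads["W2"] += demis.T @ a1
        grads["b2"] += demis.sum(axis=0)
        da1 = demis @ p["W2"]
        dpre1 = da1 * (1.0 - a1**2)
        grads["W1"] += dpre1.T @ hg
        grads["b1"] += dpre1.sum(axis=0)
        dhg = dpre1 @ p["W1"]
        d_h = H.shape[1]
        dH = dhg[:, :d_h].copy()
        dG = dhg[:, d_h:]
        dA = dG @ H.T
        dH += A.T @ dG
        dS = attention_matrix_backward(A, dA)
        dH_s, dWa = score_matrix_backward(H, self.attention, S, dS)
        dH += dH_s
        grads["attW"] += dWa

        d = self.config.lstm_hidden
        dx = self._lstm_backward(dH[:, :d], cache["sf"], "f", grads)
        dx += self._lstm_backward(dH[:, d:], cache["sb"], "b", grads)
        dw = self.config.word_dim
        np.add.at(grads["Ew"], cache["word_ids"], dx[:, :dw])
        self._char_backward(dx[:, dw:], cache["char_cache"], grads)
        return loss, grads

    def _apply(self, grads: Dict[str, np.ndarray]) -> None:
        total = np.sqrt(sum(float((g**2).sum()) for g in grads.values()))
        scale = self.config.clip / total if total > self.config.clip else 1.0
        lr = self.config.lr
        for k, g in grads.items():
            if k == "attW":
                self.attention.W = self.attention.W - lr * scale * g
            else:
                self.params[k] -= lr * scale * g

    # ------------------------------------------------------------------
    # public API

    def fit(self, corpus: Sequence[TaggedDocument]) -> "AttBiLstmCrf":
        """Train with plain SGD; deterministic for a fixed config seed."""
        if not corpus:
            raise ValueError("training corpus is empty")
        rng = np.random.default_rng(self.config.seed)
        self._build_vocab(corpus)
        self._init_params(rng)
        for _epoch in range(self.config.epochs):
            order = rng.permutation(len(corpus))
            total = 0.0
            for idx in order:
                loss, grads = self._forward_backward(corpus[idx])
                self._apply(grads)
                total += loss
            self.history.append(total / len(corpus))
        return self

    def predict_labels(self, doc: TaggedDocument) -> List[List[str]]:
        """Decode BIO labels for a document; output is BIO-valid."""
        tokens, lengths = self._doc_tokens(doc)
        if not tokens:
            return [[] for _ in doc.sentences]
        emissions, _ = self._encode(tokens)
        trans_eff = self.params["trans"] + self._trans_mask
        emissions[0] = emissions[0] + self._start
        path, _score = viterbi_decode(emissions, trans_eff)
        labels = [self.tags[i] for i in path]
        out: List[List[str]] = []
        pos = 0
        for length in lengths:
            out.append(labels[pos : pos + length])
            pos += length
        return out

    def tag_document(
        self, doc: TaggedDocument, source: Optional[str] = None
    ) -> List[EntityMention]:
        """Decode a document into entity mentions with character offsets."""
        mentions: List[EntityMention] = []
        predicted = self.predict_labels(doc)
        for s, labs in enumerate(predicted):
            if not labs:
                continue
            text = doc.sentence_text(s)
            record = SentenceRecord(
                doc_id=doc.doc_id,
                source=source or doc.source,
                text=text,
                index=s,
            )
            offs = doc.char_offsets[s]
            for first, last, typ in bio_spans(labs):
                a, b = offs[first][0], offs[last][1]
                mention = EntityMention(
                    text_name=text[a : b + 1],
                    standard_name=text[a : b + 1],
                    entity_id="",
                    entity_type=typ,
                    start_index=a,
                    end_index=b,
                    sentence=record,
                )
                mention.validate()
                mentions.append(mention)
        return mentions

    # ------------------------------------------------------------------
    # persistence

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "format": "litkg-ner-v1",
            "config": asdict(self.config),
            "tags": self.tags,
            "vocab": self.vocab,
            "char_vocab": self.char_vocab,
            "history": self.history,
            "attention_W": self.attention.W.tolist(),
            "params": {k: v.tolist() for k, v in self.params.items()},
        }
        path.write_text(json.dumps(payload), encoding="utf-8")
        return path

    @classmethod
    def load(cls, path: str | Path) -> "AttBiLstmCrf":
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
        if payload.get("format") != "litkg-ner-v1":
            raise ValueError(f"unrecognized model file format in {path}")
        cfg = payload["config"]
        cfg["concepts"] = tuple(cfg["concepts"])
        model = cls(NerConfig(**cfg))
        model.tags = list(payload["tags"])
        model.vocab = dict(payload["vocab"])
        model.char_vocab = dict(payload["char_vocab"])
        model.history = list(payload["history"])
        model.params = {
            k: np.asarray(v, dtype=float) for k, v in payload["params"].items()
        }
        model.attention = AttentionParams(
            model.config.variant, np.asarray(payload["attention_W"], dtype=float)
        )
        model._trans_mask = bio_transition_mask(model.tags)
        model._start = _start_mask(model.tags)
        return model


# ----------------------------------------------------------------------
# span-level scoring


def _spans(doc: TaggedDocument, labels: Sequence[Sequence[str]]) -> set:
    out = set()
    for s, labs in enumerate(labels):
        for first, last, typ in bio_spans(labs):
            out.add((doc.doc_id, s, first, last, typ))
    return out


def span_prf(
    model: AttBiLstmCrf, docs: Sequence[TaggedDocument]
) -> Tuple[float, float, float]:
    """Entity-level (exact span + type) precision/recall/F1 in [0, 1]."""
    tp = fp = fn = 0
    for doc in docs:
        gold = _spans(doc, doc.labels)
        pred = _spans(doc, model.predict_labels(doc))
        tp += len(gold & pred)
        fp += len(pred - gold)
        fn += len(gold - pred)
    p = tp / (tp + fp) if tp + fp else 0.0
    r = tp / (tp + fn) if tp + fn else 0.0
    f = 2 * p * r / (p + r) if p + r else 0.0
    return p, r, f
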