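"""Document-level attention over BiLSTM context vectors.

For a document of N tokens with encoder output H (N × d_h), a pairwise
score s_ij measures the similarity of tokens i and j under one of four
variants (manhattan, euclidean, cosine, perceptron).  Rowwise softmax of
the score matrix gives a row-stochastic attention matrix A, and G = A·H
is the matrix of document-level global context vectors.  Attending over
the whole document lets distant occurrences of the same entity surface
share evidence, which is what makes tag assignments consistent across
sentences.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Tuple

import numpy as np

__all__ = [
    "VARIANTS",
    "AttentionParams",
    "init_attention_params",
    "score_pair",
    "score_matrix",
    "score_matrix_backward",
    "attention_matrix",
    "attention_matrix_backward",
    "global_vectors",
]

VARIANTS = ("manhattan", "euclidean", "cosine", "perceptron")


@dataclass
class AttentionParams:
    """Variant name plus its weight parameter.

    Shapes: manhattan → (d_h,); euclidean, cosine → scalar ();
    perceptron → (2·d_h,), interpreted as [w1; w2] acting on [x_i; x_j].
    """

    variant: str
    W: np.ndarray

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown attention variant {self.variant!r}")
        self.W = np.asarray(self.W, dtype=float)

    def check_dim(self, d_h: int) -> None:
        expected = {
            "manhattan": (d_h,),
            "euclidean": (),
            "cosine": (),
            "perceptron": (2 * d_h,),
        }[self.variant]
        if self.W.shape != expected:
            raise ValueError(
                f"{self.variant} weights must have shape {expected}, "
                f"got {self.W.shape}"
            )


def init_attention_params(
    variant: str, d_h: int, rng: np.random.Generator
) -> AttentionParams:
    scale = 1.0 / np.sqrt(d_h)
    if variant == "manhattan":
        w = rng.uniform(-scale, scale, size=d_h)
    elif variant in ("euclidean", "cosine"):
        w = np.asarray(rng.uniform(-scale, scale))
    elif variant == "perceptron":
        w = rng.uniform(-scale, scale, size=2 * d_h)
    else:
        raise ValueError(f"unknown attention variant {variant!r}")
    return AttentionParams(variant, w)


def score_pair(x_i: np.ndarray, x_j: np.ndarray, params: AttentionParams) -> float:
    """Similarity score of one token pair under the configured variant.

    manhattan: W·|x_i − x_j|; euclidean: W·(x_i − x_j)ᵀ(x_i − x_j);
    cosine: W·cos(x_i, x_j) with a zero-norm vector scoring 0;
    perceptron: tanh(W·[x_i; x_j]).
    """
    x_i = np.asarray(x_i, dtype=float)
    x_j = np.asarray(x_j, dtype=float)
    params.check_dim(x_i.shape[0])
    if params.variant == "manhattan":
        return float(params.W @ np.abs(x_i - x_j))
    if params.variant == "euclidean":
        d = x_i - x_j
        return float(params.W * (d @ d))
    if params.variant == "cosine":
        ni, nj = np.linalg.norm(x_i), np.linalg.norm(x_j)
        if ni == 0.0 or nj == 0.0:
            return 0.0
        return float(params.W * (x_i @ x_j) / (ni * nj))
    # perceptron
    return float(np.tanh(params.W @ np.concatenate([x_i, x_j])))


def score_matrix(H: np.ndarray, params: AttentionParams) -> np.ndarray:
    """All-pairs scores, vectorized; agrees entrywise with score_pair."""
    H = np.asarray(H, dtype=float)
    params.check_dim(H.shape[1])
    if params.variant == "manhattan":
        D = np.abs(H[:, None, :] - H[None, :, :])
        return D @ params.W
    if params.variant == "euclidean":
        sq = np.sum((H[:, None, :] - H[None, :, :]) ** 2, axis=2)
        return params.W * sq
    if params.variant == "cosine":
        norms = np.linalg.norm(H, axis=1)
        safe = np.where(norms == 0.0, 1.0, norms)
        C = (H @ H.T) / np.outer(safe, safe)
        C[norms == 0.0, :] = 0.0
        C[:, norms == 0.0] = 0.0
        return params.W * C
    d_h = H.shape[1]
    u = H @ params.W[:d_h]
    v = H @ params.W[d_h:]
    return np.tanh(u[:, None] + v[None, :])


def score_matrix_backward(
    H: np.ndarray, params: AttentionParams, S: np.ndarray, dS: np.ndarray
) -> Tuple[np.ndarray, np.ndarray]:
    """Gradients of a scalar loss w.r.t. H and W given dLoss/dS.

    Returns ``(dH, dW)``.  ``S`` must be the matrix produced by
    :func:`score_matrix` for the same inputs.
    """
    H = np.asarray(H, dtype=float)
    N, d_h = H.shape
    if params.variant == "manhattan":
        D = H[:, None, :] - H[None, :, :]
        sgn = np.sign(D)
        # s_ij = sum_k w_k |h_ik − h_jk|
        dD = dS[:, :, None] * sgn * params.W[None, None, :]
        dH = dD.sum(axis=1) - dD.sum(axis=0)
        dW = (np.abs(D) * dS[:, :, None]).sum(axis=(0, 1))
        return dH, dW
    if params.variant == "euclidean":
        D = H[:, None, :] - H[None, :, :]
        sq = np.sum(D**2, axis=2)
        dsq = dS * float(params.W)
        dD = 2.0 * dsq[:, :, None] * D
        dH = dD.sum(axis=1) - dD.sum(axis=0)
        dW = np.asarray((dS * sq).sum())
        return dH, dW
    if params.variant == "cosine":
        norms = np.linalg.norm(H, axis=1)
        safe = np.where(norms == 0.0, 1.0, norms)
        Hn = H / safe[:, None]
        C = Hn @ Hn.T
        zero = norms == 0.0
        C[zero, :] = 0.0
        C[:, zero] = 0.0
        dC = dS * float(params.W)
        dC = dC.copy()
        dC[zero, :] = 0.0
        dC[:, zero] = 0.0
        # d cos(h_i, h_j)/d h_i = (h_j/|h_j| − cos·h_i/|h_i|)/|h_i|
        M = dC + dC.T  # cos is symmetric in (i, j) roles
        dHn = M @ Hn  # contribution through the "other" vector
        rowdot = (M * C).sum(axis=1)
        dH = (dHn - rowdot[:, None] * Hn) / safe[:, None]
        dH[zero, :] = 0.0
        dW = np.asarray((dS * C).sum())
        return dH, dW
    # perceptron
    u = H @ params.W[:d_h]
    v = H @ params.W[d_h:]
    dpre = dS * (1.0 - S**2)
    du = dpre.sum(axis=1)
    dv = dpre.sum(axis=0)
    dH = np.outer(du, params.W[:d_h]) + np.outer(dv, params.W[d_h:])
    dW = np.concatenate([H.T @ du, H.T @ dv])
    return dH, dW


def attention_matrix(scores: np.ndarray) -> np.ndarray:
    """Rowwise softmax of a finite score matrix; rows sum to 1."""
    scores = np.asarray(scores, dtype=float)
    if scores.ndim != 2 or scores.shape[0] != scores.shape[1]:
        raise ValueError("score matrix must be square")
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    z = scores - scores.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def attention_matrix_backward(A: np.ndarray, dA: np.ndarray) -> np.ndarray:
    """dLoss/dScores for a rowwise softmax with output A and dLoss/dA."""
    inner = (dA * A).sum(axis=1, keepdims=True)
    return A * (dA - inner)


def global_vectors(A: np.ndarray, H: np.ndarray) -> np.ndarray:
    """Document-level context vectors G = A·H."""
    A = np.asarray(A, dtype=float)
    H = np.asarray(H, dtype=float)
    if A.shape[1] != H.shape[0]:
        raise ValueError(
            f"shape mismatch: A is {A.shape}, H is {H.shape}"
        )
    return A @ H
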