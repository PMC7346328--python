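"""Linear-chain CRF: Viterbi decoding, log-partition, loss and marginals.

A path y over N tokens scores Σ_t emissions[t, y_t] + Σ_t transitions[
y_{t−1}, y_t].  Decoding maximizes the path score over all |T|^N paths;
training minimizes the negative log-likelihood log Z − score(gold).
Transitions may contain −inf entries (structurally forbidden moves);
log-sum-exp handles them exactly.
"""

from __future__ import annotations

from typing import List, Sequence, Tuple

import numpy as np
from scipy.special import logsumexp

__all__ = [
    "viterbi_decode",
    "forward_log_partition",
    "crf_negative_log_likelihood",
    "crf_marginals",
    "path_score",
]


def _check(emissions: np.ndarray) -> np.ndarray:
    emissions = np.asarray(emissions, dtype=float)
    if emissions.ndim != 2 or emissions.shape[0] < 1:
        raise ValueError("emissions must be a non-empty N×|T| matrix")
    return emissions


def path_score(
    emissions: np.ndarray, transitions: np.ndarray, path: Sequence[int]
) -> float:
    emissions = _check(emissions)
    transitions = np.asarray(transitions, dtype=float)
    score = emissions[0, path[0]]
    for t in range(1, len(path)):
        score += transitions[path[t - 1], path[t]] + emissions[t, path[t]]
    return float(score)


def viterbi_decode(
    emissions: np.ndarray, transitions: np.ndarray
) -> Tuple[List[int], float]:
    """Best tag path and its score; ties break toward the lowest tag index."""
    emissions = _check(emissions)
    transitions = np.asarray(transitions, dtype=float)
    n, k = emissions.shape
    delta = emissions[0].copy()
    back = np.zeros((n, k), dtype=int)
    for t in range(1, n):
        cand = delta[:, None] + transitions  # cand[i, j]: best-to-i then i→j
        back[t] = np.argmax(cand, axis=0)  # argmax returns lowest index on ties
        delta = cand[back[t], np.arange(k)] + emissions[t]
    last = int(np.argmax(delta))
    best = float(delta[last])
    path = [last]
    for t in range(n - 1, 0, -1):
        last = int(back[t, last])
        path.append(last)
    path.reverse()
    return path, best


def forward_log_partition(emissions: np.ndarray, transitions: np.ndarray) -> float:
    """log Z = log Σ_paths exp(score) by the forward algorithm."""
    emissions = _check(emissions)
    transitions = np.asarray(transitions, dtype=float)
    alpha = emissions[0].copy()
    for t in range(1, emissions.shape[0]):
        alpha = logsumexp(alpha[:, None] + transitions, axis=0) + emissions[t]
    return float(logsumexp(alpha))


def crf_negative_log_likelihood(
    emissions: np.ndarray, transitions: np.ndarray, gold: Sequence[int]
) -> float:
    """log Z − score(gold); non-negative."""
    emissions = _check(emissions)
    k = emissions.shape[1]
    if len(gold) != emissions.shape[0]:
        raise ValueError("gold path length must equal the number of tokens")
    if any(not 0 <= y < k for y in gold):
        raise ValueError("gold tag outside the tag set")
    return forward_log_partition(emissions, transitions) - path_score(
        emissions, transitions, gold
    )


def crf_marginals(
    emissions: np.ndarray, transitions: np.ndarray
) -> Tuple[np.ndarray, np.ndarray, float]:
    """Posterior tag marginals and expected transition counts.

    Returns ``(unary, pairwise, logZ)`` where ``unary[t, j] = P(y_t = j)``
    and ``pairwise[i, j] = Σ_t P(y_{t−1} = i, y_t = j)``; these are the
    sufficient statistics for the NLL gradient (expected minus observed).
    """
    emissions = _check(emissions)
    transitions = np.asarray(transitions, dtype=float)
    n, k = emissions.shape
    alpha = np.zeros((n, k))
    alpha[0] = emissions[0]
    for t in range(1, n):
        alpha[t] = logsumexp(alpha[t - 1][:, None] + transitions, axis=0) + emissions[t]
    beta = np.zeros((n, k))
    for t in range(n - 2, -1, -1):
        beta[t] = logsumexp(transitions + emissions[t + 1] + beta[t + 1], axis=1)
    log_z = float(logsumexp(alpha[-1]))
    unary = np.exp(alpha + beta - log_z)
    pairwise = np.zeros((k, k))
    for t in range(1, n):
        log_pair = (
            alpha[t - 1][:, None] + transitions + emissions[t] + beta[t] - log_z
        )
        pairwise += np.exp(log_pair)
    return unary, pairwise, log_z
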