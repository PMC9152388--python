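"""Linear-chain conditional random field over BIO label sequences.

Given per-character emission scores ``P`` (``P[i, j]`` scores character ``i``
taking label ``j``) and a transition matrix ``W`` augmented with START and
STOP boundary states, a label sequence ``y`` scores

    S(X, y) = sum_i P[i, y_i] + W[START, y_1]
              + sum_i W[y_i, y_{i+1}] + W[y_n, STOP]

and the sequence distribution is ``P(y|X) = exp S(X, y) / sum_y' exp S(X, y')``.
Training minimizes the negative log-likelihood, whose partition function is
computed by the forward algorithm in log space; decoding uses the Viterbi
algorithm.  Ties in Viterbi break toward the lowest label index at the
latest differing position, so an all-zero score matrix decodes to all-``O``
(label 0).

Hard BIO transition constraints (an ``I-X`` cannot follow anything but
``B-X``/``I-X``) can be imposed at decode time by adding a large negative
penalty (:data:`HARD_CONSTRAINT`) to illegal transitions; training uses the
unconstrained, learned ``W``.
"""

from __future__ import annotations

import numpy as np

from .tagging import TagSchema, legal_start, legal_transition

#: Additive penalty standing in for -inf on forbidden transitions.
HARD_CONSTRAINT = -1e4


def n_states(n_labels: int) -> int:
    return n_labels + 2


def start_index(n_labels: int) -> int:
    return n_labels


def stop_index(n_labels: int) -> int:
    return n_labels + 1


def _logsumexp(a: np.ndarray, axis: int = -1) -> np.ndarray:
    m = a.max(axis=axis, keepdims=True)
    return (m + np.log(np.exp(a - m).sum(axis=axis, keepdims=True))).squeeze(axis)


def _split(W: np.ndarray):
    """Split augmented (L+2, L+2) W into (trans, start_row, stop_col)."""
    L = W.shape[0] - 2
    return W[:L, :L], W[start_index(L), :L], W[:L, stop_index(L)]


def sequence_score(P: np.ndarray, W: np.ndarray, y) -> float:
    """Score of label sequence ``y`` under emissions ``P`` and transitions ``W``."""
    y = np.asarray(y, dtype=int)
    n = P.shape[0]
    if y.shape[0] != n:
        raise ValueError(f"label sequence length {y.shape[0]} != {n}")
    trans, start_row, stop_col = _split(W)
    s = P[np.arange(n), y].sum() + start_row[y[0]] + stop_col[y[-1]]
    if n > 1:
        s += trans[y[:-1], y[1:]].sum()
    return float(s)


def log_partition(P: np.ndarray, W: np.ndarray) -> float:
    """log sum over all label sequences of exp(score), via the forward pass."""
    trans, start_row, stop_col = _split(W)
    alpha = start_row + P[0]
    for t in range(1, P.shape[0]):
        alpha = _logsumexp(alpha[:, None] + trans, axis=0) + P[t]
    return float(_logsumexp(alpha + stop_col, axis=0))


def neg_log_likelihood(P: np.ndarray, W: np.ndarray, y) -> float:
    """-log P(y|X) = log_partition - sequence_score; always >= 0."""
    return log_partition(P, W) - sequence_score(P, W, y)


def crf_marginals(P: np.ndarray, W: np.ndarray):
    """Forward-backward pass.

    Returns ``(unary, pairwise, start_marg, stop_marg, logZ)`` where
    ``unary[t, j] = P(y_t = j | X)`` and
    ``pairwise[t, i, j] = P(y_t = i, y_{t+1} = j | X)``.
    """
    trans, start_row, stop_col = _split(W)
    n, L = P.shape
    alpha = np.empty((n, L))
    alpha[0] = start_row + P[0]
    for t in range(1, n):
        alpha[t] = _logsumexp(alpha[t - 1][:, None] + trans, axis=0) + P[t]
    beta = np.empty((n, L))
    beta[n - 1] = stop_col
    for t in range(n - 2, -1, -1):
        beta[t] = _logsumexp(trans + (P[t + 1] + beta[t + 1])[None, :], axis=1)
    logZ = _logsumexp(alpha[n - 1] + stop_col, axis=0)
    unary = np.exp(alpha + beta - logZ)
    pairwise = np.exp(
        alpha[:-1, :, None]
        + trans[None]
        + (P[1:] + beta[1:])[:, None, :]
        - logZ
    )
    return unary, pairwise, unary[0], unary[n - 1], float(logZ)


def nll_gradients(P: np.ndarray, W: np.ndarray, y):
    """Analytic gradients of :func:`neg_log_likelihood` w.r.t. ``P`` and ``W``.

    dNLL/dP = marginals - onehot(y); dNLL/dW = expected transition counts
    minus observed counts (boundary rows included).
    """
    y = np.asarray(y, dtype=int)
    n, L = P.shape
    unary, pairwise, m_start, m_stop, _ = crf_marginals(P, W)
    dP = unary.copy()
    dP[np.arange(n), y] -= 1.0
    dW = np.zeros_like(W)
    S, E = start_index(L), stop_index(L)
    dW[:L, :L] = pairwise.sum(axis=0)
    dW[S, :L] = m_start
    dW[:L, E] = m_stop
    dW[S, y[0]] -= 1.0
    dW[y[-1], E] -= 1.0
    if n > 1:
        np.add.at(dW, (y[:-1], y[1:]), -1.0)
    return dP, dW


def constraint_penalties(schema: TagSchema) -> np.ndarray:
    """Additive (L+2, L+2) matrix: :data:`HARD_CONSTRAINT` on transitions
    forbidden by BIO semantics, 0 elsewhere."""
    L = schema.n_tags
    pen = np.zeros((n_states(L), n_states(L)))
    S, E = start_index(L), stop_index(L)
    for i, ti in enumerate(schema.tags):
        for j, tj in enumerate(schema.tags):
            if not legal_transition(ti, tj, schema):
                pen[i, j] = HARD_CONSTRAINT
    for j, tj in enumerate(schema.tags):
        if not legal_start(tj, schema):
            pen[S, j] = HARD_CONSTRAINT
    pen[:, S] = HARD_CONSTRAINT  # nothing enters START
    pen[E, :] = HARD_CONSTRAINT  # nothing leaves STOP
    return pen


def viterbi_decode(P: np.ndarray, W: np.ndarray) -> tuple[list[int], float]:
    """Highest-scoring label sequence and its score.

    Ties break toward the lowest label index at the latest differing
    position (``argmax`` keeps the first maximizer at every step).
    """
    trans, start_row, stop_col = _split(W)
    n, L = P.shape
    delta = start_row + P[0]
    back = np.empty((n, L), dtype=int)
    for t in range(1, n):
        scores = delta[:, None] + trans
        back[t] = scores.argmax(axis=0)
        delta = scores[back[t], np.arange(L)] + P[t]
    final = delta + stop_col
    best = int(final.argmax())
    path = [best]
    for t in range(n - 1, 0, -1):
        best = int(back[t, best])
        path.append(best)
    path.reverse()
    return path, float(final[path[-1]])


class LinearChainCrf:
    """Trainable CRF layer with batched NLL and decoding.

    Holds the augmented transition matrix ``W``; batches are ``(B, T, L)``
    emission tensors with a ``(B, T)`` mask of real positions (each sentence
    occupies a prefix of its row).
    """

    def __init__(self, n_labels: int, rng: np.random.Generator):
        self.n_labels = n_labels
        self.params = {"W": rng.normal(0.0, 0.01, size=(n_states(n_labels),) * 2)}
        self.grads: dict[str, np.ndarray] = {}
        self._cache: dict | None = None

    def nll(self, P: np.ndarray, y: np.ndarray, mask: np.ndarray) -> float:
        """Mean per-sentence negative log-likelihood over the batch."""
        self._cache = {"P": P, "y": y, "mask": mask}
        W = self.params["W"]
        total = 0.0
        for b in range(P.shape[0]):
            n = int(mask[b].sum())
            total += neg_log_likelihood(P[b, :n], W, y[b, :n])
        return total / P.shape[0]

    def backward(self) -> np.ndarray:
        """Gradient of the mean NLL w.r.t. the emission tensor; fills
        ``grads['W']``."""
        c = self._cache
        P, y, mask = c["P"], c["y"], c["mask"]
        B = P.shape[0]
        W = self.params["W"]
        dP = np.zeros_like(P)
        dW = np.zeros_like(W)
        for b in range(B):
            n = int(mask[b].sum())
            dPb, dWb = nll_gradients(P[b, :n], W, y[b, :n])
            dP[b, :n] = dPb / B
            dW += dWb / B
        self.grads = {"W": dW}
        return dP

    def decode(
        self,
        P: np.ndarray,
        mask: np.ndarray,
        schema: TagSchema | None = None,
    ) -> list[list[int]]:
        """Viterbi decode each sentence; when ``schema`` is given, hard BIO
        constraints are applied to the transition matrix."""
        W = self.params["W"]
        if schema is not None:
            W = W + constraint_penalties(schema)
        out = []
        for b in range(P.shape[0]):
            n = int(mask[b].sum())
            path, _ = viterbi_decode(P[b, :n], W)
            out.append(path)
        return out
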