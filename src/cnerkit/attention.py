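"""Multi-head scaled dot-product self-attention.

Entities in a clinical record depend on one another across long character
distances (a disease mention and the operation that treats it, for example),
so the encoder output is reweighted by attention:

    Attention(Q, K, V) = softmax(Q K^T / sqrt(d_k)) V
    head_i = Attention(Y W_i^Q, Y W_i^K, Y W_i^V)
    MHA(Y) = concat(head_1, ..., head_h) W^O

with Q = K = V = Y for self-attention.  Padding keys receive a large negative
logit (:data:`MASK_LOGIT`) before the softmax; padding-query outputs are
defined as zero vectors.  No residual connection or layer normalization is
added by default (``residual=True`` enables a plain additive skip).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Additive logit applied to masked keys; softmax(-1e9) underflows to 0.
MASK_LOGIT = -1e9


@dataclass(frozen=True)
class MhaConfig:
    d_model: int
    heads: int = 4
    residual: bool = False

    def __post_init__(self) -> None:
        if self.heads < 1:
            raise ValueError("heads must be >= 1")
        if self.d_model % self.heads:
            raise ValueError(
                f"d_model {self.d_model} not divisible by heads {self.heads}"
            )

    @property
    def d_k(self) -> int:
        return self.d_model // self.heads


def _softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def scaled_dot_attention(
    Q: np.ndarray,
    K: np.ndarray,
    V: np.ndarray,
    mask: np.ndarray | None = None,
    return_weights: bool = False,
):
    """Scaled dot-product attention for one sequence (or one head).

    ``Q`` is ``(Tq, d_k)``, ``K``/``V`` are ``(Tk, d_k)``/``(Tk, d_v)``;
    ``mask`` marks real keys (1) vs padding (0).  Each output row is a convex
    combination of the real value rows.
    """
    Q, K, V = (np.asarray(a, dtype=float) for a in (Q, K, V))
    d_k = Q.shape[-1]
    logits = Q @ K.T / np.sqrt(d_k)
    if mask is not None:
        mask = np.asarray(mask, dtype=float)
        if not mask.any():
            raise ValueError("all keys are masked: softmax is degenerate")
        logits = logits + MASK_LOGIT * (1.0 - mask)[None, :]
    weights = _softmax(logits, axis=-1)
    out = weights @ V
    return (out, weights) if return_weights else out


class MultiHeadAttention:
    """Trainable multi-head self-attention layer over ``(B, T, d_model)``."""

    def __init__(self, config: MhaConfig, rng: np.random.Generator):
        self.config = config
        d, h, dk = config.d_model, config.heads, config.d_k
        scale = 1.0 / np.sqrt(d)
        self.params: dict[str, np.ndarray] = {
            "Wq": rng.normal(0.0, scale, size=(h, d, dk)),
            "Wk": rng.normal(0.0, scale, size=(h, d, dk)),
            "Wv": rng.normal(0.0, scale, size=(h, d, dk)),
            "Wo": rng.normal(0.0, 1.0 / np.sqrt(h * dk), size=(h * dk, d)),
        }
        self.grads: dict[str, np.ndarray] = {}
        self._cache: dict | None = None

    def forward(
        self, Y: np.ndarray, mask: np.ndarray, train: bool = False
    ) -> np.ndarray:
        h, dk = self.config.heads, self.config.d_k
        B, T, d = Y.shape
        # (B, h, T, dk)
        Q = np.einsum("btd,hde->bhte", Y, self.params["Wq"])
        K = np.einsum("btd,hde->bhte", Y, self.params["Wk"])
        V = np.einsum("btd,hde->bhte", Y, self.params["Wv"])
        logits = Q @ K.transpose(0, 1, 3, 2) / np.sqrt(dk)
        logits = logits + MASK_LOGIT * (1.0 - mask)[:, None, None, :]
        weights = _softmax(logits, axis=-1)
        ctx = weights @ V  # (B, h, T, dk)
        concat = ctx.transpose(0, 2, 1, 3).reshape(B, T, h * dk)
        out = (concat @ self.params["Wo"]) * mask[:, :, None]
        if self.config.residual:
            out = out + Y * mask[:, :, None]
        self._cache = {
            "Y": Y, "mask": mask, "Q": Q, "K": K, "V": V,
            "weights": weights, "concat": concat,
        }
        return out

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        c = self._cache
        h, dk = self.config.heads, self.config.d_k
        Y, mask = c["Y"], c["mask"]
        B, T, d = Y.shape
        g = grad_out * mask[:, :, None]
        grad_Y = g.copy() if self.config.residual else np.zeros_like(Y)
        self.grads = {"Wo": c["concat"].reshape(-1, h * dk).T @ g.reshape(-1, d)}
        g_concat = g @ self.params["Wo"].T
        g_ctx = g_concat.reshape(B, T, h, dk).transpose(0, 2, 1, 3)
        W = c["weights"]
        g_V = W.transpose(0, 1, 3, 2) @ g_ctx
        g_W = g_ctx @ c["V"].transpose(0, 1, 3, 2)
        # softmax backward per row
        g_logits = W * (g_W - (g_W * W).sum(axis=-1, keepdims=True))
        g_logits /= np.sqrt(dk)
        g_Q = g_logits @ c["K"]
        g_K = g_logits.transpose(0, 1, 3, 2) @ c["Q"]
        for name, gh in (("Wq", g_Q), ("Wk", g_K), ("Wv", g_V)):
            self.grads[name] = np.einsum("btd,bhte->hde", Y, gh)
            grad_Y += np.einsum("bhte,hde->btd", gh, self.params[name])
        return grad_Y


def multi_head_attention(
    Y: np.ndarray,
    config: MhaConfig,
    params: dict[str, np.ndarray],
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Functional multi-head self-attention with explicit parameters.

    ``Y`` is ``(T, d_model)`` or ``(B, T, d_model)``.
    """
    single = Y.ndim == 2
    if single:
        Y = Y[None]
    if mask is None:
        mask = np.ones(Y.shape[:2])
    expected = {
        "Wq": (config.heads, config.d_model, config.d_k),
        "Wk": (config.heads, config.d_model, config.d_k),
        "Wv": (config.heads, config.d_model, config.d_k),
        "Wo": (config.heads * config.d_k, config.d_model),
    }
    for name, shape in expected.items():
        if params[name].shape != shape:
            raise ValueError(
                f"parameter {name} has shape {params[name].shape}, expected {shape}"
            )
    layer = object.__new__(MultiHeadAttention)
    layer.config = config
    layer.params = params
    layer.grads = {}
    out = MultiHeadAttention.forward(layer, Y, mask)
    return out[0] if single else out
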