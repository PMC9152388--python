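"""Iterated dilated 1-D convolutions over character sequences.

A dilated convolution spaces its kernel taps ``dilation`` positions apart,
enlarging the receptive field without pooling.  The encoder applies one block
of three dilated layers (dilation widths 1, 1, 2 by default) ``iterations``
times (default 4), feeding each iteration's output to the next and sharing
the block's parameters across iterations, so the parameter count is
independent of the iteration count while the receptive field grows linearly
in it.

The 1-D receptive field of the stack is

    r = 1 + iterations * sum_layers (kernel_size - 1) * dilation_layer

so with K=3, dilations (1, 1, 2) and 4 iterations, r = 33.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

_ACTIVATIONS = {
    "relu": (lambda z: np.maximum(z, 0.0), lambda z: (z > 0).astype(float)),
    "linear": (lambda z: z, lambda z: np.ones_like(z)),
    "tanh": (np.tanh, lambda z: 1.0 - np.tanh(z) ** 2),
}


@dataclass(frozen=True)
class IdcnnConfig:
    filters: int = 128
    kernel_size: int = 3
    dilations: tuple[int, ...] = (1, 1, 2)
    iterations: int = 4
    activation: str = "relu"

    def __post_init__(self) -> None:
        if self.kernel_size % 2 == 0:
            raise ValueError("kernel_size must be odd")
        if any(d < 1 for d in self.dilations):
            raise ValueError("dilations must be >= 1")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.activation not in _ACTIVATIONS:
            raise ValueError(f"unknown activation {self.activation!r}")
        object.__setattr__(self, "dilations", tuple(self.dilations))


def receptive_field_1d(
    kernel_size: int, dilations: Sequence[int], iterations: int
) -> int:
    """Receptive field (in characters) of the iterated dilated stack."""
    per_block = sum((kernel_size - 1) * d for d in dilations)
    return 1 + iterations * per_block


def image_receptive_field(i: int) -> int:
    """Reference calculator for the 2-D exponential receptive-field formula
    ``F_{i+1} = (2^{i+2} - 1) x (2^{i+2} - 1)`` sometimes quoted for dilated
    convolutions on images.  It does not apply to 1-D text encoders; use
    :func:`receptive_field_1d` for those.
    """
    side = 2 ** (i + 2) - 1
    return side * side


def dilated_conv_layer(
    x: np.ndarray,
    dilation: int,
    kernel: np.ndarray,
    bias: np.ndarray,
    mask: np.ndarray | None = None,
    activation: str = "relu",
) -> np.ndarray:
    """One dilated convolution with "same" zero padding.

    ``x`` is ``(B, T, C_in)``; ``kernel`` is ``(K, C_in, C_out)``; output is
    ``activation(sum_k kernel[k] . x[t + (k - K//2) * dilation] + bias)`` with
    positions outside the sequence treated as zero and padding positions
    (``mask == 0``) forced to zero.
    """
    act, _ = _ACTIVATIONS[activation]
    out = _conv_linear(x, dilation, kernel, bias)
    out = act(out)
    if mask is not None:
        out = out * mask[:, :, None]
    return out


def _conv_linear(x, dilation, kernel, bias):
    K = kernel.shape[0]
    half = K // 2
    B, T, _ = x.shape
    pad = half * dilation
    xp = np.pad(x, ((0, 0), (pad, pad), (0, 0)))
    out = np.tile(bias, (B, T, 1)).astype(float)
    for k in range(K):
        out += xp[:, k * dilation : k * dilation + T, :] @ kernel[k]
    return out


class IdcnnEncoder:
    """Input projection followed by the shared iterated dilation block.

    Forward maps ``(B, T, d_in)`` to ``(B, T, filters)``.  Backward
    accumulates gradients for the shared block parameters across all
    iterations (backpropagation through the unrolled composition).
    """

    def __init__(self, d_in: int, config: IdcnnConfig, rng: np.random.Generator):
        self.config = config
        C, K = config.filters, config.kernel_size
        self.params: dict[str, np.ndarray] = {
            "W_in": rng.normal(0.0, np.sqrt(2.0 / d_in), size=(d_in, C)),
            "b_in": np.zeros(C),
        }
        for l, _ in enumerate(config.dilations):
            self.params[f"W_{l}"] = rng.normal(
                0.0, np.sqrt(2.0 / (K * C)), size=(K, C, C)
            )
            self.params[f"b_{l}"] = np.zeros(C)
        self.grads: dict[str, np.ndarray] = {}
        self._cache: dict | None = None

    def forward(
        self, x: np.ndarray, mask: np.ndarray, train: bool = False
    ) -> np.ndarray:
        cfg = self.config
        act, _ = _ACTIVATIONS[cfg.activation]
        m = mask[:, :, None]
        h = (x @ self.params["W_in"] + self.params["b_in"]) * m
        inputs: list[list[np.ndarray]] = []  # per iteration, per layer: input
        pres: list[list[np.ndarray]] = []  # pre-activation
        for _ in range(cfg.iterations):
            it_in, it_pre = [], []
            for l, d in enumerate(cfg.dilations):
                it_in.append(h)
                z = _conv_linear(h, d, self.params[f"W_{l}"], self.params[f"b_{l}"])
                it_pre.append(z)
                h = act(z) * m
            inputs.append(it_in)
            pres.append(it_pre)
        self._cache = {"x": x, "mask": mask, "inputs": inputs, "pres": pres}
        return h

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        cfg = self.config
        _, dact = _ACTIVATIONS[cfg.activation]
        cache = self._cache
        mask = cache["mask"][:, :, None]
        K = cfg.kernel_size
        half = K // 2
        T = grad_out.shape[1]
        grads = {name: np.zeros_like(p) for name, p in self.params.items()}
        g = grad_out
        for it in reversed(range(cfg.iterations)):
            for l in reversed(range(len(cfg.dilations))):
                d = cfg.dilations[l]
                z = cache["pres"][it][l]
                h_in = cache["inputs"][it][l]
                gz = g * mask * dact(z)
                grads[f"b_{l}"] += gz.sum(axis=(0, 1))
                pad = half * d
                hp = np.pad(h_in, ((0, 0), (pad, pad), (0, 0)))
                gxp = np.zeros_like(hp)
                W = self.params[f"W_{l}"]
                for k in range(K):
                    sl = slice(k * d, k * d + T)
                    grads[f"W_{l}"][k] += np.einsum("btc,btd->cd", hp[:, sl], gz)
                    gxp[:, sl] += gz @ W[k].T
                g = gxp[:, pad : pad + T] if pad else gxp
        g = g * mask
        grads["W_in"] += np.einsum("btc,btd->cd", cache["x"], g)
        grads["b_in"] += g.sum(axis=(0, 1))
        grad_x = g @ self.params["W_in"].T
        self.grads = grads
        return grad_x


def idcnn_encode(
    x: np.ndarray,
    config: IdcnnConfig,
    params: dict[str, np.ndarray],
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Functional forward pass with explicit parameters (shared across
    iterations); ``x`` is ``(B, T, d_in)`` or ``(T, d_in)``."""
    single = x.ndim == 2
    if single:
        x = x[None]
    if mask is None:
        mask = np.ones(x.shape[:2])
    enc = object.__new__(IdcnnEncoder)
    enc.config = config
    enc.params = params
    enc.grads = {}
    out = IdcnnEncoder.forward(enc, x, mask)
    return out[0] if single else out
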