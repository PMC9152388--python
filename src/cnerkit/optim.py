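"""First-order optimizers for the sequence tagger.

Adagrad, RMSprop, Adam and RAdam follow their standard published update
rules; Lookahead is the slow/fast-weights wrapper (every ``k`` inner steps,
the slow weights move a fraction ``alpha`` toward the fast weights and the
fast weights are reset to them).  With ``k=1`` and ``alpha=1`` Lookahead
reduces to its inner optimizer step-for-step.

All optimizers operate on a list of NumPy parameter arrays updated in place.
"""

from __future__ import annotations

import numpy as np


class Optimizer:
    def __init__(self, lr: float):
        self.lr = lr
        self.t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        self._update(params, grads)

    def _update(self, params, grads):  # pragma: no cover - abstract
        raise NotImplementedError


class Adagrad(Optimizer):
    def __init__(self, lr: float = 0.01, eps: float = 1e-8):
        super().__init__(lr)
        self.eps = eps
        self._acc: list[np.ndarray] | None = None

    def _update(self, params, grads):
        if self._acc is None:
            self._acc = [np.zeros_like(p) for p in params]
        for p, g, a in zip(params, grads, self._acc):
            a += g * g
            p -= self.lr * g / (np.sqrt(a) + self.eps)


class RMSprop(Optimizer):
    def __init__(self, lr: float = 0.001, rho: float = 0.9, eps: float = 1e-8):
        super().__init__(lr)
        self.rho = rho
        self.eps = eps
        self._acc: list[np.ndarray] | None = None

    def _update(self, params, grads):
        if self._acc is None:
            self._acc = [np.zeros_like(p) for p in params]
        for p, g, a in zip(params, grads, self._acc):
            a *= self.rho
            a += (1.0 - self.rho) * g * g
            p -= self.lr * g / (np.sqrt(a) + self.eps)


class Adam(Optimizer):
    def __init__(
        self,
        lr: float = 0.001,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ):
        super().__init__(lr)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self._m: list[np.ndarray] | None = None
        self._v: list[np.ndarray] | None = None

    def _moments(self, params, grads):
        if self._m is None:
            self._m = [np.zeros_like(p) for p in params]
            self._v = [np.zeros_like(p) for p in params]
        for m, v, g in zip(self._m, self._v, grads):
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * g * g

    def _update(self, params, grads):
        self._moments(params, grads)
        bc1 = 1.0 - self.beta1 ** self.t
        bc2 = 1.0 - self.beta2 ** self.t
        for p, m, v in zip(params, self._m, self._v):
            p -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


class RAdam(Adam):
    """Rectified Adam: the adaptive step is rectified by the estimated
    variance of the second moment, giving an automatic warm-up (small early
    steps fall back to momentum-only SGD)."""

    def _update(self, params, grads):
        self._moments(params, grads)
        t = self.t
        beta2_t = self.beta2 ** t
        rho_inf = 2.0 / (1.0 - self.beta2) - 1.0
        rho_t = rho_inf - 2.0 * t * beta2_t / (1.0 - beta2_t)
        bc1 = 1.0 - self.beta1 ** t
        for p, m, v in zip(params, self._m, self._v):
            m_hat = m / bc1
            if rho_t > 4.0:
                v_hat = np.sqrt(v / (1.0 - beta2_t))
                r = np.sqrt(
                    ((rho_t - 4.0) * (rho_t - 2.0) * rho_inf)
                    / ((rho_inf - 4.0) * (rho_inf - 2.0) * rho_t)
                )
                p -= self.lr * r * m_hat / (v_hat + self.eps)
            else:
                p -= self.lr * m_hat


class Lookahead(Optimizer):
    """Slow-weights wrapper around an inner optimizer."""

    def __init__(self, inner: Optimizer, k: int = 5, alpha: float = 0.5):
        super().__init__(inner.lr)
        if k < 1 or not 0.0 < alpha <= 1.0:
            raise ValueError("require k >= 1 and 0 < alpha <= 1")
        self.inner = inner
        self.k = k
        self.alpha = alpha
        self._slow: list[np.ndarray] | None = None

    def step(self, params, grads):
        self.t += 1
        if self._slow is None:
            self._slow = [p.copy() for p in params]
        self.inner.step(params, grads)
        if self.t % self.k == 0:
            for p, s in zip(params, self._slow):
                s += self.alpha * (p - s)
                p[...] = s


_FACTORY = {
    "adagrad": lambda lr: Adagrad(lr),
    "rmsprop": lambda lr: RMSprop(lr),
    "adam": lambda lr: Adam(lr),
    "radam": lambda lr: RAdam(lr),
    "lookahead_adam": lambda lr: Lookahead(Adam(lr)),
}

OPTIMIZERS = tuple(_FACTORY)


def create_optimizer(name: str, lr: float) -> Optimizer:
    try:
        return _FACTORY[name](lr)
    except KeyError:
        raise ValueError(
            f"unknown optimizer {name!r}; choose from {OPTIMIZERS}"
        ) from None
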