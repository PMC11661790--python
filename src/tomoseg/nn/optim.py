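"""Adam optimiser and the sigmoid/binary-cross-entropy training couple."""

from __future__ import annotations

import numpy as np

from .net import sigmoid

__all__ = ["Adam", "bce_with_logits"]


class Adam:
    def __init__(self, params, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params  # [(weight, grad)] — updated in place
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(w) for w, _ in params]
        self.v = [np.zeros_like(w) for w, _ in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for (w, g), m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            w -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


def bce_with_logits(logits: np.ndarray, targets: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean pixel-wise binary cross-entropy and its gradient w.r.t. logits.

    Uses log(1 + exp(-|z|)) for stability; the gradient is
    (sigmoid(z) - y) / n.
    """
    z, y = logits, targets
    loss = np.mean(np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z))))
    grad = (sigmoid(z) - y) / z.size
    return float(loss), grad.astype(np.float32)
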