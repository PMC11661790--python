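"""Network graphs: a plain layer stack and a small U-Net with skips.

All networks take and return (N, H, W, C) channels-last batches.

Networks output *logits*; :func:`sigmoid` squashes them to [0, 1].  Training
couples the sigmoid with binary cross-entropy for numerical stability, so
``backward`` expects the gradient with respect to the logits.
"""

from __future__ import annotations

import numpy as np

from .layers import Conv2D, Layer, MaxPool2, ReLU, Upsample2

__all__ = ["sigmoid", "Network", "Sequential", "UNet"]


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class Network:
    """Common interface: logits forward/backward, probability prediction."""

    downsample: int = 1  # input H, W must be multiples of this

    def forward_logits(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> None:  # pragma: no cover
        raise NotImplementedError

    def params(self) -> list[tuple[np.ndarray, np.ndarray]]:  # pragma: no cover
        raise NotImplementedError

    def predict(self, x: np.ndarray) -> np.ndarray:
        return sigmoid(self.forward_logits(x))

    def n_parameters(self) -> int:
        return int(sum(w.size for w, _ in self.params()))

    def get_weights(self) -> list[np.ndarray]:
        return [w.copy() for w, _ in self.params()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        own = self.params()
        if len(own) != len(weights):
            raise ValueError(f"expected {len(own)} weight arrays, got {len(weights)}")
        for (w, _), new in zip(own, weights):
            if w.shape != new.shape:
                raise ValueError(f"weight shape mismatch: {w.shape} vs {new.shape}")
            w[:] = new


class Sequential(Network):
    def __init__(self, layers: list[Layer], downsample: int = 1):
        self.layers = layers
        self.downsample = downsample

    def forward_logits(self, x):
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)

    def params(self):
        return [p for layer in self.layers for p in layer.params()]


class _ConvBlock:
    """Two 3x3 conv+ReLU pairs."""

    def __init__(self, c_in, c_mid, rng):
        self.ops = [Conv2D(c_in, c_mid, 3, rng), ReLU(), Conv2D(c_mid, c_mid, 3, rng), ReLU()]

    def forward(self, x):
        for op in self.ops:
            x = op.forward(x)
        return x

    def backward(self, g):
        for op in reversed(self.ops):
            g = op.backward(g)
        return g

    def params(self):
        return [p for op in self.ops for p in op.params()]


class UNet(Network):
    """Depth-2 U-Net: encoder 8/16, bottleneck 32, skip-concat decoder."""

    downsample = 4

    def __init__(self, rng: np.random.Generator, base: int = 8):
        b = base
        self.enc1 = _ConvBlock(1, b, rng)
        self.pool1 = MaxPool2()
        self.enc2 = _ConvBlock(b, 2 * b, rng)
        self.pool2 = MaxPool2()
        self.bott = _ConvBlock(2 * b, 4 * b, rng)
        self.up2 = Upsample2()
        self.dec2 = _ConvBlock(4 * b + 2 * b, 2 * b, rng)
        self.up1 = Upsample2()
        self.dec1 = _ConvBlock(2 * b + b, b, rng)
        self.head = Conv2D(b, 1, 1, rng)
        self._b = b

    def forward_logits(self, x):
        e1 = self.enc1.forward(x)
        e2 = self.enc2.forward(self.pool1.forward(e1))
        z = self.bott.forward(self.pool2.forward(e2))
        d2 = self.dec2.forward(np.concatenate([self.up2.forward(z), e2], axis=-1))
        d1 = self.dec1.forward(np.concatenate([self.up1.forward(d2), e1], axis=-1))
        return self.head.forward(d1)

    def backward(self, grad):
        b = self._b
        g = self.head.backward(grad)
        g = self.dec1.backward(g)
        g_up1, g_e1_skip = g[..., : 2 * b], g[..., 2 * b :]
        g = self.up1.backward(g_up1)
        g = self.dec2.backward(g)
        g_up2, g_e2_skip = g[..., : 4 * b], g[..., 4 * b :]
        g = self.up2.backward(g_up2)
        g = self.bott.backward(g)
        g = self.pool2.backward(g)
        g = self.enc2.backward(g + g_e2_skip)
        g = self.pool1.backward(g)
        self.enc1.backward(g + g_e1_skip)

    def params(self):
        blocks = [self.enc1, self.enc2, self.bott, self.dec2, self.dec1, self.head]
        return [p for blk in blocks for p in blk.params()]
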