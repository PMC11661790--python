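"""Differentiable layers operating on (N, H, W, C) float32 batches.

Channels-last layout keeps the innermost dimension contiguous for the
shift-and-matmul convolution: a stride-1 'same' convolution is evaluated as
a sum over the k*k kernel offsets of (spatially shifted input) @ (per-offset
channel matrix), which runs as a short series of BLAS sgemm calls without
materialising an im2col matrix.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Layer", "Conv2D", "ReLU", "LeakyReLU", "MaxPool2", "Upsample2"]


class Layer:
    """Base: forward caches what backward needs; grads accumulate on the layer."""

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def params(self) -> list[tuple[np.ndarray, np.ndarray]]:
        """(weight, gradient) pairs; gradients are overwritten each backward."""
        return []


class Conv2D(Layer):
    """Stride-1 'same' convolution with odd kernel size and bias.

    Kernel tensor is (k, k, c_in, c_out); He-normal initialisation scaled
    for the ReLU family.
    """

    def __init__(self, c_in: int, c_out: int, k: int = 3, rng: np.random.Generator | None = None):
        if k % 2 == 0:
            raise ValueError("kernel size must be odd")
        rng = rng or np.random.default_rng()
        scale = np.sqrt(2.0 / (k * k * c_in))
        self.W = (rng.standard_normal((k, k, c_in, c_out)) * scale).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)
        self.k, self.c_in, self.c_out = k, c_in, c_out
        self._xp = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        k, p = self.k, self.k // 2
        n, h, w, _ = x.shape
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        out = np.broadcast_to(self.b, (n, h, w, self.c_out)).astype(np.float32).copy()
        for dy in range(k):
            for dx in range(k):
                out += xp[:, dy : dy + h, dx : dx + w, :] @ self.W[dy, dx]
        self._xp = xp
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        k, p = self.k, self.k // 2
        n, h, w, _ = grad.shape
        xp = self._xp
        gmat = grad.reshape(-1, self.c_out)
        self.gb[:] = gmat.sum(axis=0)
        for dy in range(k):
            for dx in range(k):
                patch = np.ascontiguousarray(xp[:, dy : dy + h, dx : dx + w, :])
                self.gW[dy, dx] = patch.reshape(-1, self.c_in).T @ gmat
        # Input gradient: 'same' convolution of grad with the spatially
        # flipped, channel-transposed kernel (exact for stride 1, odd k).
        gp = np.pad(grad, ((0, 0), (p, p), (p, p), (0, 0)))
        gx = np.zeros((n, h, w, self.c_in), dtype=np.float32)
        for dy in range(k):
            for dx in range(k):
                gx += gp[:, dy : dy + h, dx : dx + w, :] @ self.W[k - 1 - dy, k - 1 - dx].T
        return gx

    def params(self):
        return [(self.W, self.gW), (self.b, self.gb)]


class ReLU(Layer):
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class LeakyReLU(Layer):
    def __init__(self, alpha: float = 0.1):
        self.alpha = alpha

    def forward(self, x):
        self._mask = x > 0
        return np.where(self._mask, x, self.alpha * x)

    def backward(self, grad):
        return np.where(self._mask, grad, self.alpha * grad)


class MaxPool2(Layer):
    """2x2 max pooling; input H and W must be even."""

    def forward(self, x):
        n, h, w, c = x.shape
        blocks = x.reshape(n, h // 2, 2, w // 2, 2, c).transpose(0, 1, 3, 5, 2, 4)
        flat = np.ascontiguousarray(blocks).reshape(n, h // 2, w // 2, c, 4)
        self._argmax = flat.argmax(axis=-1)
        self._shape = x.shape
        return flat.max(axis=-1)

    def backward(self, grad):
        n, h, w, c = self._shape
        out = np.zeros((n, h // 2, w // 2, c, 4), dtype=grad.dtype)
        np.put_along_axis(out, self._argmax[..., None], grad[..., None], axis=-1)
        return (
            out.reshape(n, h // 2, w // 2, c, 2, 2)
            .transpose(0, 1, 4, 2, 5, 3)
            .reshape(n, h, w, c)
        )


class Upsample2(Layer):
    """Nearest-neighbour 2x upsampling."""

    def forward(self, x):
        return x.repeat(2, axis=1).repeat(2, axis=2)

    def backward(self, grad):
        n, h, w, c = grad.shape
        return grad.reshape(n, h // 2, 2, w // 2, 2, c).sum(axis=(2, 4))
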