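"""A small, fully deterministic convolutional-network engine in NumPy.

The classifier operates on per-cell crop tensors a few tens of pixels across,
so a compact CNN trained on the CPU is sufficient; implementing the engine
directly in NumPy keeps every forward/backward pass bitwise reproducible for
a given seed and exposes the backward pass for guided backpropagation (the
saliency rule that propagates a gradient through a rectifier only where both
the forward activation and the incoming gradient are positive).

Convolutions are 3x3, stride 1, zero-padded, evaluated as im2col matrix
products; the input gradient is computed as a convolution with the spatially
flipped kernels, so no scatter-add is needed and everything runs through BLAS.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Adam", "SmallCNN", "softmax", "softmax_cross_entropy"]


def _im2col(x: np.ndarray) -> np.ndarray:
    """(N, C, H, W) -> (N*H*W, C*9) patches for a padded 3x3 convolution."""
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    win = sliding_window_view(xp, (3, 3), axis=(2, 3))  # (N, C, H, W, 3, 3)
    return win.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w, c * 9)


class Conv3x3:
    """3x3 same-padding convolution."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator) -> None:
        scale = np.sqrt(2.0 / (c_in * 9))
        self.w = (rng.standard_normal((c_out, c_in, 3, 3)) * scale).astype(np.float64)
        self.b = np.zeros(c_out)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self._cols: np.ndarray | None = None
        self._shape: tuple[int, ...] | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        cols = _im2col(x)
        self._cols, self._shape = cols, x.shape
        wmat = self.w.reshape(self.w.shape[0], -1).T  # (C*9, F)
        out = cols @ wmat + self.b
        return out.reshape(n, h, w, -1).transpose(0, 3, 1, 2)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, f, h, w = grad.shape
        gmat = grad.transpose(0, 2, 3, 1).reshape(n * h * w, f)
        self.dw += (gmat.T @ self._cols).reshape(self.w.shape)
        self.db += gmat.sum(axis=0)
        # input gradient = convolution of grad with the flipped kernels
        wback = self.w[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)  # (C_in, F, 3, 3)
        gcols = _im2col(grad)
        dx = gcols @ wback.reshape(wback.shape[0], -1).T
        return dx.reshape(n, h, w, -1).transpose(0, 3, 1, 2)

    def params(self):
        return [("w", self.w, self.dw), ("b", self.b, self.db)]


class ReLU:
    def __init__(self) -> None:
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, grad: np.ndarray, guided: bool = False) -> np.ndarray:
        out = np.where(self._mask, grad, 0.0)
        if guided:
            out = np.where(out > 0, out, 0.0)
        return out

    def params(self):
        return []


class MaxPool2:
    def __init__(self) -> None:
        self._idx: np.ndarray | None = None
        self._shape: tuple[int, ...] | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        self._shape = x.shape
        xr = (
            x.reshape(n, c, h // 2, 2, w // 2, 2)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(n, c, h // 2, w // 2, 4)
        )
        self._idx = xr.argmax(axis=-1)  # first maximum on ties
        return np.take_along_axis(xr, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        dxr = np.zeros((n, c, h // 2, w // 2, 4))
        np.put_along_axis(dxr, self._idx[..., None], grad[..., None], axis=-1)
        return (
            dxr.reshape(n, c, h // 2, w // 2, 2, 2)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(n, c, h, w)
        )

    def params(self):
        return []


class GlobalAvgPool:
    def __init__(self) -> None:
        self._shape: tuple[int, ...] | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        return np.broadcast_to(grad[:, :, None, None], (n, c, h, w)) / (h * w)

    def params(self):
        return []


class Dense:
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator) -> None:
        scale = np.sqrt(2.0 / d_in)
        self.w = (rng.standard_normal((d_in, d_out)) * scale).astype(np.float64)
        self.b = np.zeros(d_out)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.w + self.b

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.dw += self._x.T @ grad
        self.db += grad.sum(axis=0)
        return grad @ self.w.T

    def params(self):
        return [("w", self.w, self.dw), ("b", self.b, self.db)]


class SmallCNN:
    """Three conv blocks (16/32/64 filters), global average pooling, linear head.

    Sized for crop tensors of side 16-64 px on a CPU; the receptive field after
    three blocks covers the central cell and its immediate neighborhood.
    """

    def __init__(self, in_channels: int, n_classes: int, rng: np.random.Generator,
                 widths: tuple[int, int, int] = (16, 32, 64)) -> None:
        self.in_channels = in_channels
        self.n_classes = n_classes
        self.widths = widths
        w1, w2, w3 = widths
        self.layers = [
            Conv3x3(in_channels, w1, rng), ReLU(), MaxPool2(),
            Conv3x3(w1, w2, rng), ReLU(), MaxPool2(),
            Conv3x3(w2, w3, rng), ReLU(),
            GlobalAvgPool(),
            Dense(w3, n_classes, rng),
        ]

    def forward(self, x: np.ndarray) -> np.ndarray:
        out = np.asarray(x, dtype=np.float64)
        for layer in self.layers:
            out = layer.forward(out)
        return out

    def backward(self, dlogits: np.ndarray, guided: bool = False) -> np.ndarray:
        grad = dlogits
        for layer in reversed(self.layers):
            if isinstance(layer, ReLU):
                grad = layer.backward(grad, guided=guided)
            else:
                grad = layer.backward(grad)
        return grad

    def zero_grad(self) -> None:
        for layer in self.layers:
            for _, _, g in layer.params():
                g[...] = 0.0

    def parameters(self):
        out = []
        for i, layer in enumerate(self.layers):
            for name, p, g in layer.params():
                out.append((f"layer{i}.{name}", p, g))
        return out

    def predict_proba(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Class probabilities in inference mode (deterministic)."""
        chunks = []
        for i in range(0, len(x), batch_size):
            chunks.append(softmax(self.forward(x[i : i + batch_size])))
        return np.concatenate(chunks) if chunks else np.zeros((0, self.n_classes))

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.copy() for name, p, _ in self.parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for name, p, _ in self.parameters():
            p[...] = state[name]


class Adam:
    """Adam optimizer with the standard bias correction."""

    def __init__(self, model: SmallCNN, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.model = model
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = {name: np.zeros_like(p) for name, p, _ in model.parameters()}
        self.v = {name: np.zeros_like(p) for name, p, _ in model.parameters()}

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.beta1 ** self.t
        b2t = 1 - self.beta2 ** self.t
        for name, p, g in self.model.parameters():
            m = self.m[name]
            v = self.v[name]
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, targets: np.ndarray
                          ) -> tuple[float, np.ndarray]:
    """Mean cross-entropy and its gradient with respect to the logits."""
    probs = softmax(logits)
    n = len(targets)
    loss = float(-np.log(np.maximum(probs[np.arange(n), targets], 1e-12)).mean())
    grad = probs.copy()
    grad[np.arange(n), targets] -= 1.0
    return loss, grad / n
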