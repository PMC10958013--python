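"""Minimal deterministic neural-network primitives on numpy.

Just enough machinery for the Siamese perception network: strided 2-D
convolution, ReLU, fully connected layers, log-softmax with NLL loss, and
Adam.  Everything is float32, channels-last (NHWC), and seeded through
explicit generators; inference is bitwise deterministic.

Convolution is computed by im2col (one strided window view reshaped into a
patch matrix) followed by a single GEMM, the layout that keeps a lone CPU
core busy with one large BLAS call per layer.  Layers cache what their
backward pass needs; no gradient ever flows below the first trainable
layer, because the frozen random front-end is the bottom of the network.

Weight matrices also expose a data-dependent ``rescale`` used at training
start to normalize activation magnitudes (scene images are sparse — a few
bright squares on a zero background — so fan-in-only initialization leaves
early activations tiny and Adam crawling).
"""

from __future__ import annotations

import numpy as np


class Conv2d:
    """Valid-mode strided convolution, channels-last, He-initialized."""

    def __init__(self, c_in: int, c_out: int, k: int, stride: int,
                 rng: np.random.Generator, trainable: bool = True):
        self.c_in, self.c_out, self.k, self.stride = c_in, c_out, k, stride
        self.trainable = trainable
        scale = np.sqrt(2.0 / (c_in * k * k))
        self.W = (rng.standard_normal((k, k, c_in, c_out)) * scale).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.dW = self.db = None
        self._x = None

    def out_size(self, h: int) -> int:
        return (h - self.k) // self.stride + 1

    def forward(self, x: np.ndarray, cache: bool) -> np.ndarray:
        # x: (N, H, W, c_in) -> (N, Ho, Wo, c_out); im2col + one GEMM
        from numpy.lib.stride_tricks import sliding_window_view

        n, h, w, _ = x.shape
        ho, wo = self.out_size(h), self.out_size(w)
        win = sliding_window_view(x, (self.k, self.k), axis=(1, 2))[
            :, ::self.stride, ::self.stride]          # (N, Ho, Wo, C, k, k)
        cols = np.ascontiguousarray(win.transpose(0, 1, 2, 4, 5, 3)).reshape(
            n * ho * wo, self.k * self.k * self.c_in)
        y = cols @ self.W.reshape(-1, self.c_out) + self.b
        if cache:
            self._x = (cols, x.shape)
        return y.reshape(n, ho, wo, self.c_out)

    def backward(self, dy: np.ndarray, need_dx: bool = True) -> np.ndarray | None:
        cols, x_shape = self._x
        self._x = None
        n, h, w, _ = x_shape
        ho, wo = self.out_size(h), self.out_size(w)
        dyf = dy.reshape(-1, self.c_out)
        self.dW = (cols.T @ dyf).reshape(self.W.shape)
        self.db = dyf.sum(axis=0)
        if not need_dx:
            return None
        dcols = (dyf @ self.W.reshape(-1, self.c_out).T).reshape(
            n, ho, wo, self.k, self.k, self.c_in)
        dx = np.zeros(x_shape, dtype=np.float32)
        s = self.stride
        for ki in range(self.k):
            for kj in range(self.k):
                dx[:, ki:ki + s * (ho - 1) + 1:s, kj:kj + s * (wo - 1) + 1:s, :] += \
                    dcols[:, :, :, ki, kj, :]
        return dx

    def rescale(self, factor: float) -> None:
        self.W *= factor
        self.b *= factor

    def params(self):
        return [("W", self), ("b", self)] if self.trainable else []


class Linear:
    """Fully connected layer y = x W^T + b."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / n_in)
        self.W = (rng.standard_normal((n_out, n_in)) * scale).astype(np.float32)
        self.b = np.zeros(n_out, dtype=np.float32)
        self.trainable = True
        self.dW = self.db = None
        self._x = None

    def forward(self, x: np.ndarray, cache: bool) -> np.ndarray:
        if cache:
            self._x = x
        return x @ self.W.T + self.b

    def backward(self, dy: np.ndarray, need_dx: bool = True) -> np.ndarray | None:
        self.dW = dy.T @ self._x
        self.db = dy.sum(axis=0)
        self._x = None
        return dy @ self.W if need_dx else None

    def rescale(self, factor: float) -> None:
        self.W *= factor
        self.b *= factor

    def params(self):
        return [("W", self), ("b", self)]


class ReLU:
    def __init__(self):
        self.trainable = False
        self._mask = None

    def forward(self, x: np.ndarray, cache: bool) -> np.ndarray:
        y = np.maximum(x, 0.0)
        if cache:
            self._mask = x > 0
        return y

    def backward(self, dy: np.ndarray, need_dx: bool = True) -> np.ndarray:
        dx = dy * self._mask
        self._mask = None
        return dx

    def params(self):
        return []


class Flatten:
    def __init__(self):
        self.trainable = False
        self._shape = None

    def forward(self, x: np.ndarray, cache: bool) -> np.ndarray:
        if cache:
            self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy: np.ndarray, need_dx: bool = True) -> np.ndarray:
        return dy.reshape(self._shape)

    def params(self):
        return []


class Sequential:
    def __init__(self, layers):
        self.layers = list(layers)

    def forward(self, x: np.ndarray, cache: bool) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, cache)
        return x

    def backward(self, dy: np.ndarray, need_dx: bool = False):
        """Backprop through the stack; the first layer's dx is computed only
        when ``need_dx`` is set (the trunk sits on a frozen front-end)."""
        for i in range(len(self.layers) - 1, -1, -1):
            want = need_dx or i > 0
            dy = self.layers[i].backward(dy, need_dx=want)
        return dy

    def calibrate(self, x: np.ndarray, target_std: float = 1.0) -> np.ndarray:
        """Rescale each weighted layer so its pre-activation std on the
        calibration batch is ``target_std`` (LSUV-style data-dependent
        initialization).  Returns the batch's final activations."""
        for layer in self.layers:
            x = layer.forward(x, False)
            if hasattr(layer, "rescale"):
                std = float(x.std())
                if std > 0:
                    layer.rescale(target_std / std)
                    x *= target_std / std
        return x

    def params(self):
        out = []
        for layer in self.layers:
            out.extend(layer.params())
        return out


def log_softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    return z - np.log(np.exp(z).sum(axis=1, keepdims=True))


def nll_loss_grad(logp: np.ndarray, targets: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean NLL of the correct class and its gradient w.r.t. the logits."""
    n = len(targets)
    loss = float(-logp[np.arange(n), targets].mean())
    grad = np.exp(logp)
    grad[np.arange(n), targets] -= 1.0
    return loss, (grad / n).astype(np.float32)


class Adam:
    """Adam with standard defaults (beta1 0.9, beta2 0.999, eps 1e-8)."""

    def __init__(self, modules, lr: float):
        self.lr = lr
        self.beta1, self.beta2, self.eps = 0.9, 0.999, 1e-8
        self.t = 0
        self.slots = []
        for mods in modules:
            for name, layer in mods.params():
                w = getattr(layer, name)
                self.slots.append((layer, name, np.zeros_like(w), np.zeros_like(w)))

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for layer, name, m, v in self.slots:
            g = getattr(layer, "d" + name)
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * g * g
            w = getattr(layer, name)
            w -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
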