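"""Minimal CPU neural-network layers with explicit forward/backward passes.

All tensors are ``float32`` arrays of shape ``(N, C, H, W)``. Each layer
caches what its backward pass needs during ``forward``; ``backward`` consumes
the gradient w.r.t. the layer output and returns the gradient w.r.t. its
input while accumulating parameter gradients in-place. Convolutions are
lowered to matrix multiplies (im2col) so the heavy lifting happens in BLAS.

The framework is deliberately small: stride-1 same-padded 3x3 / 1x1
convolutions, 2x2 transposed convolutions, 2x2 max pooling, ReLU, bilinear
resampling and channel concatenation are all an encoder-decoder segmentation
network needs.
"""

from __future__ import annotations

import numpy as np

F32 = np.float32

# When False, layers skip caching the intermediates their backward pass
# would need — inference then runs at a fraction of the memory.
_grad_enabled = True


class no_grad:
    """Context manager disabling backward caches during inference."""

    def __enter__(self):
        global _grad_enabled
        self._prev = _grad_enabled
        _grad_enabled = False

    def __exit__(self, *exc):
        global _grad_enabled
        _grad_enabled = self._prev
        return False


class Param:
    """A trainable tensor with an accumulated gradient."""

    __slots__ = ("data", "grad")

    def __init__(self, data: np.ndarray):
        self.data = np.ascontiguousarray(data, dtype=F32)
        self.grad = np.zeros_like(self.data)

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, gy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


def he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(F32)


class Conv2d(Layer):
    """Stride-1 convolution with 'same' zero padding (odd kernel)."""

    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator):
        if k % 2 != 1:
            raise ValueError("Conv2d requires an odd kernel size")
        self.cin, self.cout, self.k = cin, cout, k
        self.w = Param(he_init(rng, (cout, cin * k * k), cin * k * k))
        self.b = Param(np.zeros(cout, dtype=F32))
        self._cols: np.ndarray | None = None
        self._xshape: tuple[int, ...] | None = None

    def params(self) -> list[Param]:
        return [self.w, self.b]

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        k, p = self.k, self.k // 2
        if p:
            xp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=F32)
            xp[:, :, p:-p, p:-p] = x
        else:
            xp = x
        win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
        # (n, c, h, w, k, k) -> (n, h*w, c*k*k)
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n, h * w, c * k * k)
        return np.ascontiguousarray(cols)

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        if c != self.cin:
            raise ValueError(f"expected {self.cin} input channels, got {c}")
        cols = self._im2col(x)
        y = cols @ self.w.data.T + self.b.data
        if _grad_enabled:
            self._cols, self._xshape = cols, x.shape
        return y.reshape(n, h, w, self.cout).transpose(0, 3, 1, 2)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        n, c, h, w = self._xshape
        k, p = self.k, self.k // 2
        g = np.ascontiguousarray(gy.transpose(0, 2, 3, 1).reshape(n, h * w, self.cout))
        self.b.grad += g.sum(axis=(0, 1))
        ckk = self._cols.shape[-1]
        self.w.grad += g.reshape(-1, self.cout).T @ self._cols.reshape(-1, ckk)
        gcols = g @ self.w.data  # (n, h*w, cin*k*k)
        gcols = gcols.reshape(n, h, w, c, k, k)
        gxp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=F32)
        for i in range(k):
            for j in range(k):
                gxp[:, :, i : i + h, j : j + w] += gcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
        self._cols = None
        return gxp[:, :, p : p + h, p : p + w] if p else gxp


class ConvTranspose2x2(Layer):
    """2x2 stride-2 transposed convolution (doubles spatial resolution)."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        self.cin, self.cout = cin, cout
        self.w = Param(he_init(rng, (cin, cout * 4), cin))
        self.b = Param(np.zeros(cout, dtype=F32))
        self._x: np.ndarray | None = None

    def params(self) -> list[Param]:
        return [self.w, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        if c != self.cin:
            raise ValueError(f"expected {self.cin} input channels, got {c}")
        x2 = x.transpose(0, 2, 3, 1).reshape(n * h * w, c)
        y2 = x2 @ self.w.data  # (n*h*w, cout*4)
        y = y2.reshape(n, h, w, self.cout, 2, 2).transpose(0, 3, 1, 4, 2, 5)
        y = y.reshape(n, self.cout, 2 * h, 2 * w) + self.b.data[None, :, None, None]
        if _grad_enabled:
            self._x = x
        return np.ascontiguousarray(y)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        x = self._x
        n, c, h, w = x.shape
        g = gy.reshape(n, self.cout, h, 2, w, 2).transpose(0, 2, 4, 1, 3, 5)
        g2 = np.ascontiguousarray(g).reshape(n * h * w, self.cout * 4)
        x2 = x.transpose(0, 2, 3, 1).reshape(n * h * w, c)
        self.w.grad += x2.T @ g2
        self.b.grad += gy.sum(axis=(0, 2, 3))
        gx = (g2 @ self.w.data.T).reshape(n, h, w, c).transpose(0, 3, 1, 2)
        self._x = None
        return np.ascontiguousarray(gx)


class MaxPool2x2(Layer):
    def __init__(self) -> None:
        self._idx: np.ndarray | None = None
        self._xshape: tuple[int, ...] | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError("MaxPool2x2 requires even spatial dimensions")
        r = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        r = r.reshape(n, c, h // 2, w // 2, 4)
        idx = r.argmax(axis=-1)
        y = np.take_along_axis(r, idx[..., None], axis=-1)[..., 0]
        if _grad_enabled:
            self._idx, self._xshape = idx, x.shape
        return y

    def backward(self, gy: np.ndarray) -> np.ndarray:
        n, c, h, w = self._xshape
        gr = np.zeros((n, c, h // 2, w // 2, 4), dtype=F32)
        np.put_along_axis(gr, self._idx[..., None], gy[..., None], axis=-1)
        gx = gr.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        self._idx = None
        return gx.reshape(n, c, h, w)


class ReLU(Layer):
    def __init__(self) -> None:
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        mask = x > 0
        if _grad_enabled:
            self._mask = mask
        return np.where(mask, x, F32(0.0))

    def backward(self, gy: np.ndarray) -> np.ndarray:
        gx = np.where(self._mask, gy, F32(0.0))
        self._mask = None
        return gx


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def params(self) -> list[Param]:
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, gy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            gy = layer.backward(gy)
        return gy


def _resize_matrix(n_out: int, n_in: int) -> np.ndarray:
    """Dense 1-D bilinear interpolation matrix (pixel-center aligned)."""
    m = np.zeros((n_out, n_in), dtype=F32)
    if n_in == 1:
        m[:, 0] = 1.0
        return m
    src = (np.arange(n_out, dtype=np.float64) + 0.5) * n_in / n_out - 0.5
    src = np.clip(src, 0.0, n_in - 1.0)
    lo = np.floor(src).astype(int)
    hi = np.minimum(lo + 1, n_in - 1)
    frac = (src - lo).astype(F32)
    m[np.arange(n_out), lo] += 1.0 - frac
    m[np.arange(n_out), hi] += frac
    return m


class BilinearResize(Layer):
    """Differentiable separable bilinear resampling to a fixed output size."""

    def __init__(self, in_hw: tuple[int, int], out_hw: tuple[int, int]):
        self.in_hw, self.out_hw = in_hw, out_hw
        self._r = _resize_matrix(out_hw[0], in_hw[0])
        self._c = _resize_matrix(out_hw[1], in_hw[1])

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.shape[2:] != self.in_hw:
            raise ValueError(f"expected spatial shape {self.in_hw}, got {x.shape[2:]}")
        return self._r @ x @ self._c.T

    def backward(self, gy: np.ndarray) -> np.ndarray:
        return self._r.T @ gy @ self._c


def resize_bilinear(x: np.ndarray, out_hw: tuple[int, int]) -> np.ndarray:
    """One-shot bilinear resize of an (N, C, H, W) array (no gradient cache)."""
    r = _resize_matrix(out_hw[0], x.shape[2])
    c = _resize_matrix(out_hw[1], x.shape[3])
    return r @ x.astype(F32, copy=False) @ c.T


def resize_nearest(x: np.ndarray, out_hw: tuple[int, int]) -> np.ndarray:
    """Nearest-neighbour resize; preserves categorical/binary values."""
    h, w = x.shape[-2], x.shape[-1]
    ri = np.clip(((np.arange(out_hw[0]) + 0.5) * h / out_hw[0]).astype(int), 0, h - 1)
    ci = np.clip(((np.arange(out_hw[1]) + 0.5) * w / out_hw[1]).astype(int), 0, w - 1)
    return x[..., ri[:, None], ci[None, :]]


def softmax_channels(a: np.ndarray) -> np.ndarray:
    """Softmax over axis 1 of an (N, C, H, W) array."""
    m = a.max(axis=1, keepdims=True)
    e = np.exp(a - m)
    return e / e.sum(axis=1, keepdims=True)


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class SGD:
    """Stochastic gradient descent with classical momentum."""

    def __init__(self, params: list[Param], lr: float, momentum: float = 0.0):
        self.params = params
        self.lr = F32(lr)
        self.momentum = F32(momentum)
        self._vel = [np.zeros_like(p.data) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        for p, v in zip(self.params, self._vel):
            v *= self.momentum
            v += p.grad
            p.data -= self.lr * v
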