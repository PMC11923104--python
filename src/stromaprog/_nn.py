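"""Minimal trainable CNN layers in numpy (NHWC, float32).

Only what the valid-convolution U-Net needs: unpadded 3x3 convolution,
ReLU, channel-wise (spatial) dropout, 2x2 max pooling, 2x stride-2
transpose convolution, 1x1 convolution, center-crop concatenation, softmax
cross-entropy with an ignore label, and Adam.  Convolutions are im2col +
BLAS GEMM; backward passes are written out explicitly.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

F32 = np.float32


class Layer:
    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []


class Conv3x3(Layer):
    """Valid (unpadded) 3x3 convolution, optional fused ReLU."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator, relu: bool = True):
        scale = np.sqrt(2.0 / (9 * c_in))
        self.w = (rng.standard_normal((c_in * 9, c_out)) * scale).astype(F32)
        self.b = np.zeros(c_out, dtype=F32)
        self.relu = relu
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        n, h, w, c = x.shape
        win = sliding_window_view(x, (3, 3), axis=(1, 2))  # (n, h-2, w-2, c, 3, 3)
        patches = win.reshape(n, h - 2, w - 2, c * 9)
        self._patches = patches.reshape(-1, c * 9)
        self._in_shape = x.shape
        y = (self._patches @ self.w).reshape(n, h - 2, w - 2, -1) + self.b
        if self.relu:
            self._pre_relu_neg = y < 0
            np.maximum(y, 0, out=y)
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, h, w, c = self._in_shape
        if self.relu:
            dy = np.where(self._pre_relu_neg, F32(0), dy)
        dy_flat = dy.reshape(-1, dy.shape[-1])
        self.dw[...] = self._patches.T @ dy_flat
        self.db[...] = dy_flat.sum(axis=0)
        dpatch = (dy_flat @ self.w.T).reshape(n, h - 2, w - 2, c, 3, 3)
        dx = np.zeros((n, h, w, c), dtype=F32)
        for di in range(3):
            for dj in range(3):
                dx[:, di : di + h - 2, dj : dj + w - 2, :] += dpatch[..., di, dj]
        self._patches = None
        return dx

    def params(self):
        return [self.w, self.b]

    def grads(self):
        return [self.dw, self.db]


class SpatialDropout(Layer):
    """Drops whole feature channels with probability ``rate`` (inverted)."""

    def __init__(self, rate: float, rng: np.random.Generator):
        if not 0 <= rate < 1:
            raise ValueError("dropout rate must lie in [0, 1)")
        self.rate = rate
        self.rng = rng

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if not training or self.rate == 0:
            self._mask = None
            return x
        keep = (self.rng.random((x.shape[0], 1, 1, x.shape[3])) >= self.rate)
        self._mask = keep.astype(F32) / F32(1 - self.rate)
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy if self._mask is None else dy * self._mask


class MaxPool2(Layer):
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        n, h, w, c = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"odd spatial size before pooling: {(h, w)}")
        xr = (
            x.reshape(n, h // 2, 2, w // 2, 2, c)
            .transpose(0, 1, 3, 5, 2, 4)
            .reshape(n, h // 2, w // 2, c, 4)
        )
        self._idx = xr.argmax(axis=-1)
        self._in_shape = x.shape
        return np.take_along_axis(xr, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, h, w, c = self._in_shape
        dxr = np.zeros((n, h // 2, w // 2, c, 4), dtype=F32)
        np.put_along_axis(dxr, self._idx[..., None], dy[..., None], axis=-1)
        return (
            dxr.reshape(n, h // 2, w // 2, c, 2, 2)
            .transpose(0, 1, 4, 2, 5, 3)
            .reshape(n, h, w, c)
        )


class UpConv2(Layer):
    """2x2 stride-2 transpose convolution (learned upsampling)."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / c_in)
        self.w = (rng.standard_normal((c_in, c_out * 4)) * scale).astype(F32)
        self.b = np.zeros(c_out, dtype=F32)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        n, h, w, c = x.shape
        self._x = x
        c_out = self.b.shape[0]
        y = (x.reshape(-1, c) @ self.w).reshape(n, h, w, c_out, 2, 2)
        y = y.transpose(0, 1, 4, 2, 5, 3).reshape(n, 2 * h, 2 * w, c_out)
        return y + self.b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, h2, w2, c_out = dy.shape
        h, w = h2 // 2, w2 // 2
        self.db[...] = dy.sum(axis=(0, 1, 2))
        dyr = (
            dy.reshape(n, h, 2, w, 2, c_out)
            .transpose(0, 1, 3, 5, 2, 4)
            .reshape(-1, c_out * 4)
        )
        x_flat = self._x.reshape(-1, self._x.shape[-1])
        self.dw[...] = x_flat.T @ dyr
        dx = (dyr @ self.w.T).reshape(self._x.shape)
        self._x = None
        return dx

    def params(self):
        return [self.w, self.b]

    def grads(self):
        return [self.dw, self.db]


class Conv1x1(Layer):
    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / c_in)
        self.w = (rng.standard_normal((c_in, c_out)) * scale).astype(F32)
        self.b = np.zeros(c_out, dtype=F32)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._x = x
        return x @ self.w + self.b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x_flat = self._x.reshape(-1, self._x.shape[-1])
        self.dw[...] = x_flat.T @ dy.reshape(-1, dy.shape[-1])
        self.db[...] = dy.sum(axis=(0, 1, 2))
        dx = dy @ self.w.T
        self._x = None
        return dx

    def params(self):
        return [self.w, self.b]

    def grads(self):
        return [self.dw, self.db]


def center_crop(x: np.ndarray, target_hw: tuple[int, int]) -> np.ndarray:
    """Symmetric center crop of an NHWC tensor to the target spatial size."""
    h, w = x.shape[1:3]
    th, tw = target_hw
    dh, dw = h - th, w - tw
    if dh < 0 or dw < 0 or dh % 2 or dw % 2:
        raise ValueError(f"cannot center-crop {(h, w)} to {(th, tw)}")
    return x[:, dh // 2 : dh // 2 + th, dw // 2 : dw // 2 + tw, :]


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z, dtype=np.float64)
    return (e / e.sum(axis=-1, keepdims=True)).astype(F32)


def cross_entropy_ignore(
    logits: np.ndarray,
    labels: np.ndarray,
    ignore: int = 255,
    class_weights: np.ndarray | None = None,
) -> tuple[float, np.ndarray, int]:
    """Weighted mean CE over non-ignored pixels; returns (loss, dlogits, n_valid).

    ``class_weights`` (one weight per class) rebalances rare classes; the
    loss is the weighted mean with the weight mass as denominator, so equal
    weights reduce to the plain mean.
    """
    p = softmax(logits)
    valid = labels != ignore
    n_valid = int(valid.sum())
    if n_valid == 0:
        return 0.0, np.zeros_like(logits), 0
    lab = np.where(valid, labels, 0).astype(np.int64)
    picked = np.take_along_axis(p, lab[..., None], axis=-1)[..., 0]
    if class_weights is None:
        w = valid.astype(np.float64)
    else:
        w = np.asarray(class_weights, dtype=np.float64)[lab] * valid
    w_sum = w.sum()
    loss = float(-(w * np.log(np.maximum(picked, 1e-12))).sum() / w_sum)
    grad = p.copy()
    np.put_along_axis(
        grad, lab[..., None], np.take_along_axis(grad, lab[..., None], axis=-1) - 1, axis=-1
    )
    grad *= (w[..., None] / w_sum).astype(F32)
    return loss, grad, n_valid


class Adam:
    def __init__(self, params: list[np.ndarray], lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        corr1 = 1 - b1**self.t
        corr2 = 1 - b2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p -= (self.lr * (m / corr1) / (np.sqrt(v / corr2) + self.eps)).astype(p.dtype)
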