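"""Minimal NumPy neural-network layers with hand-derived backprop.

Implements exactly the operator set the 2.5D U-Net needs — 3x3/1x1
convolution (im2col + BLAS matmul), Group Normalization, ReLU, 2x2 max
pooling, 2x bilinear upsampling, channel concatenation and channel
softmax — each as a layer object with ``forward``/``backward`` and
parameter/gradient dictionaries, plus an AdamW optimizer and global
gradient-norm clipping.  Everything runs in float32 on arrays shaped
(B, C, H, W).  Gradient correctness is pinned by finite-difference tests.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Layer",
    "Conv2d",
    "GroupNorm",
    "ReLU",
    "MaxPool2",
    "BilinearUp2",
    "ChannelSoftmax",
    "AdamW",
    "clip_global_norm",
]


class Layer:
    """Base layer: optional params/grads, single-use cache per forward."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def zero_grad(self) -> None:
        for k in self.grads:
            self.grads[k][...] = 0.0


class Conv2d(Layer):
    """Same-padding convolution, kernel size 1 or 3, stride 1."""

    def __init__(self, cin: int, cout: int, ksize: int = 3,
                 rng: np.random.Generator | None = None) -> None:
        super().__init__()
        if ksize not in (1, 3):
            raise ValueError("ksize must be 1 or 3")
        rng = rng or np.random.default_rng(0)
        self.cin, self.cout, self.k = cin, cout, ksize
        fan_in = cin * ksize * ksize
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(cout, fan_in))
        self.params = {"W": w.astype(np.float32),
                       "b": np.zeros(cout, dtype=np.float32)}
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        b, c, h, w = x.shape
        if self.k == 1:
            return x.reshape(b, c, h * w)
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
        windows = np.lib.stride_tricks.sliding_window_view(xp, (3, 3), axis=(2, 3))
        # (B, C, H, W, 3, 3) -> (B, C*9, H*W)
        cols = windows.transpose(0, 1, 4, 5, 2, 3).reshape(b, c * 9, h * w)
        return np.ascontiguousarray(cols)

    def forward(self, x: np.ndarray) -> np.ndarray:
        b, c, h, w = x.shape
        cols = self._im2col(x)
        y = np.einsum("of,bfp->bop", self.params["W"], cols, optimize=True)
        y += self.params["b"][None, :, None]
        self._cache = (cols, x.shape)
        return y.reshape(b, self.cout, h, w)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        cols, x_shape = self._cache
        b, c, h, w = x_shape
        dyf = dy.reshape(b, self.cout, h * w)
        self.grads["W"] += np.einsum("bop,bfp->of", dyf, cols, optimize=True)
        self.grads["b"] += dyf.sum(axis=(0, 2))
        dcols = np.einsum("of,bop->bfp", self.params["W"], dyf, optimize=True)
        if self.k == 1:
            return dcols.reshape(x_shape)
        dcols = dcols.reshape(b, c, 3, 3, h, w)
        dxp = np.zeros((b, c, h + 2, w + 2), dtype=dy.dtype)
        for i in range(3):
            for j in range(3):
                dxp[:, :, i : i + h, j : j + w] += dcols[:, :, i, j]
        return dxp[:, :, 1 : 1 + h, 1 : 1 + w]


class GroupNorm(Layer):
    """Group Normalization with affine scale/shift (8 groups by default)."""

    def __init__(self, channels: int, groups: int = 8, eps: float = 1e-5) -> None:
        super().__init__()
        if channels % groups != 0:
            raise ValueError(f"{channels} channels not divisible by {groups} groups")
        self.groups, self.eps = groups, eps
        self.params = {"gamma": np.ones(channels, dtype=np.float32),
                       "beta": np.zeros(channels, dtype=np.float32)}
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def forward(self, x: np.ndarray) -> np.ndarray:
        b, c, h, w = x.shape
        g = self.groups
        xg = x.reshape(b, g, -1)
        mean = xg.mean(axis=2, keepdims=True)
        var = xg.var(axis=2, keepdims=True)
        inv_sd = 1.0 / np.sqrt(var + self.eps)
        xhat = ((xg - mean) * inv_sd).reshape(b, c, h, w)
        self._cache = (xhat, inv_sd)
        return self.params["gamma"][None, :, None, None] * xhat + (
            self.params["beta"][None, :, None, None]
        )

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv_sd = self._cache
        b, c, h, w = dy.shape
        g = self.groups
        self.grads["gamma"] += (dy * xhat).sum(axis=(0, 2, 3))
        self.grads["beta"] += dy.sum(axis=(0, 2, 3))
        dxhat = (dy * self.params["gamma"][None, :, None, None]).reshape(b, g, -1)
        xh = xhat.reshape(b, g, -1)
        m1 = dxhat.mean(axis=2, keepdims=True)
        m2 = (dxhat * xh).mean(axis=2, keepdims=True)
        dx = inv_sd * (dxhat - m1 - xh * m2)
        return dx.reshape(b, c, h, w).astype(dy.dtype)


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dy, 0.0)


class MaxPool2(Layer):
    """2x2 max pooling, stride 2 (spatial dims must be even)."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        b, c, h, w = x.shape
        win = x.reshape(b, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        win = win.reshape(b, c, h // 2, w // 2, 4)
        self._argmax = win.argmax(axis=-1)
        self._in_shape = x.shape
        return win.max(axis=-1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        b, c, h, w = self._in_shape
        scattered = np.zeros((b, c, h // 2, w // 2, 4), dtype=dy.dtype)
        np.put_along_axis(scattered, self._argmax[..., None], dy[..., None], axis=-1)
        scattered = scattered.reshape(b, c, h // 2, w // 2, 2, 2)
        return scattered.transpose(0, 1, 2, 4, 3, 5).reshape(b, c, h, w)


class BilinearUp2(Layer):
    """2x bilinear upsampling (half-pixel centers, edges clamped)."""

    @staticmethod
    def _coords(n_out: int, n_in: int):
        src = np.clip((np.arange(n_out) + 0.5) / 2.0 - 0.5, 0, n_in - 1)
        i0 = np.floor(src).astype(np.int64)
        i1 = np.minimum(i0 + 1, n_in - 1)
        w1 = (src - i0).astype(np.float32)
        return i0, i1, w1

    def forward(self, x: np.ndarray) -> np.ndarray:
        b, c, h, w = x.shape
        y0, y1, wy = self._coords(2 * h, h)
        x0, x1, wx = self._coords(2 * w, w)
        self._cache = (x.shape, y0, y1, wy, x0, x1, wx)
        rows = x[:, :, y0, :] * (1 - wy)[None, None, :, None] + (
            x[:, :, y1, :] * wy[None, None, :, None]
        )
        return rows[:, :, :, x0] * (1 - wx)[None, None, None, :] + (
            rows[:, :, :, x1] * wx[None, None, None, :]
        )

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x_shape, y0, y1, wy, x0, x1, wx = self._cache
        b, c, h, w = x_shape
        drows = np.zeros((b, c, 2 * h, w), dtype=dy.dtype)
        np.add.at(drows, (slice(None), slice(None), slice(None), x0),
                  dy * (1 - wx)[None, None, None, :])
        np.add.at(drows, (slice(None), slice(None), slice(None), x1),
                  dy * wx[None, None, None, :])
        dx = np.zeros(x_shape, dtype=dy.dtype)
        np.add.at(dx, (slice(None), slice(None), y0),
                  drows * (1 - wy)[None, None, :, None])
        np.add.at(dx, (slice(None), slice(None), y1),
                  drows * wy[None, None, :, None])
        return dx


class ChannelSoftmax(Layer):
    def forward(self, z: np.ndarray) -> np.ndarray:
        z = z - z.max(axis=1, keepdims=True)
        e = np.exp(z)
        self._p = e / e.sum(axis=1, keepdims=True)
        return self._p

    def backward(self, dp: np.ndarray) -> np.ndarray:
        p = self._p
        return p * (dp - (dp * p).sum(axis=1, keepdims=True))


def clip_global_norm(grads: dict[str, np.ndarray], max_norm: float) -> float:
    """Scale all gradients in place so their global L2 norm is <= max_norm."""
    total = float(np.sqrt(sum(float((g**2).sum()) for g in grads.values())))
    if total > max_norm and total > 0:
        scale = max_norm / total
        for g in grads.values():
            g *= scale
    return total


class AdamW:
    """AdamW with decoupled weight decay."""

    def __init__(self, params: dict[str, np.ndarray], lr: float = 1.5e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 1e-2) -> None:
        self.params = params
        self.lr, self.betas, self.eps, self.wd = lr, betas, eps, weight_decay
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: dict[str, np.ndarray], lr_scale: float = 1.0) -> None:
        self.t += 1
        b1, b2 = self.betas
        lr = self.lr * lr_scale
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for k, p in self.params.items():
            g = grads[k]
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / bc1
            vhat = self.v[k] / bc2
            p -= lr * (mhat / (np.sqrt(vhat) + self.eps) + self.wd * p)
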