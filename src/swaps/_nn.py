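"""Minimal NumPy convolutional-network stack.

Implements exactly the pieces the peak-selection and confidence-scoring
models need: 3x3 convolution (padding 1), batch normalization, ReLU, 2x2
max pooling, nearest-neighbour 2x upsampling with skip concatenation, a
1x1 output convolution, Adam with a one-cycle learning-rate schedule, and
the segmentation combo loss (binary cross-entropy + dice + focal).
Forward/backward passes are hand-written; convolutions are evaluated as
nine shifted tensor contractions so all heavy lifting is BLAS matmuls.

Everything is deterministic given the RNG passed at construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

_EPS = 1e-7


# ---------------------------------------------------------------- layers


class Layer:
    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params, self.grads = [], []

    @property
    def buffers(self) -> list[np.ndarray]:
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv3x3(Layer):
    """3x3 convolution, stride 1, zero padding 1."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        super().__init__()
        scale = math.sqrt(2.0 / (c_in * 9))
        self.W = rng.normal(0.0, scale, size=(c_out, c_in, 3, 3))
        self.b = np.zeros(c_out)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, c, h, w = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
        self._xp_shape = xp.shape
        self._xp = xp if train else None
        y = np.zeros((n, self.W.shape[0], h, w))
        for di in range(3):
            for dj in range(3):
                patch = xp[:, :, di:di + h, dj:dj + w]
                # (F,C) . (N,C,H,W) over C
                y += np.tensordot(patch, self.W[:, :, di, dj], axes=([1], [1])).transpose(0, 3, 1, 2)
        return y + self.b[None, :, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xp = self._xp
        n, f, h, w = dy.shape
        dxp = np.zeros(self._xp_shape)
        dW, db = self.grads
        db += dy.sum(axis=(0, 2, 3))
        for di in range(3):
            for dj in range(3):
                patch = xp[:, :, di:di + h, dj:dj + w]
                dW[:, :, di, dj] += np.tensordot(dy, patch, axes=([0, 2, 3], [0, 2, 3]))
                dxp[:, :, di:di + h, dj:dj + w] += np.tensordot(
                    dy, self.W[:, :, di, dj], axes=([1], [0])).transpose(0, 3, 1, 2)
        self._xp = None
        return dxp[:, :, 1:-1, 1:-1]


class Conv1x1(Layer):
    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        super().__init__()
        self.W = rng.normal(0.0, math.sqrt(2.0 / c_in), size=(c_out, c_in))
        self.b = np.zeros(c_out)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._x = x if train else None
        return np.tensordot(x, self.W, axes=([1], [1])).transpose(0, 3, 1, 2) + self.b[None, :, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dW, db = self.grads
        db += dy.sum(axis=(0, 2, 3))
        dW += np.tensordot(dy, self._x, axes=([0, 2, 3], [0, 2, 3]))
        dx = np.tensordot(dy, self.W, axes=([1], [0])).transpose(0, 3, 1, 2)
        self._x = None
        return dx


class BatchNorm(Layer):
    def __init__(self, c: int, momentum: float = 0.9):
        super().__init__()
        self.gamma = np.ones(c)
        self.beta = np.zeros(c)
        self.params = [self.gamma, self.beta]
        self.grads = [np.zeros_like(self.gamma), np.zeros_like(self.beta)]
        self.running_mean = np.zeros(c)
        self.running_var = np.ones(c)
        self.momentum = momentum

    @property
    def buffers(self) -> list[np.ndarray]:
        return [self.running_mean, self.running_var]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean[...] = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var[...] = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + 1e-5)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        if train:
            self._xhat, self._inv, self._m = xhat, inv, x.shape[0] * x.shape[2] * x.shape[3]
        return self.gamma[None, :, None, None] * xhat + self.beta[None, :, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv, m = self._xhat, self._inv, self._m
        dgamma, dbeta = self.grads
        dgamma += (dy * xhat).sum(axis=(0, 2, 3))
        dbeta += dy.sum(axis=(0, 2, 3))
        dxhat = dy * self.gamma[None, :, None, None]
        t1 = dxhat.sum(axis=(0, 2, 3), keepdims=True).transpose(1, 0, 2, 3).reshape(1, -1, 1, 1)
        t2 = (dxhat * xhat).sum(axis=(0, 2, 3), keepdims=True).transpose(1, 0, 2, 3).reshape(1, -1, 1, 1)
        dx = (dxhat - t1 / m - xhat * t2 / m) * inv[None, :, None, None]
        self._xhat = None
        return dx


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        mask = x > 0
        if train:
            self._mask = mask
        return x * mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dy = dy * self._mask
        self._mask = None
        return dy


def maxpool2(x: np.ndarray) -> tuple[np.ndarray, tuple]:
    """2x2 max pooling; odd trailing rows/cols are padded with -inf."""
    n, c, h, w = x.shape
    ph, pw = (h + 1) // 2 * 2, (w + 1) // 2 * 2
    if (ph, pw) != (h, w):
        xpad = np.full((n, c, ph, pw), -np.inf)
        xpad[:, :, :h, :w] = x
    else:
        xpad = x
    r = xpad.reshape(n, c, ph // 2, 2, pw // 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, ph // 2, pw // 2, 4)
    idx = r.argmax(axis=-1)
    y = np.take_along_axis(r, idx[..., None], axis=-1)[..., 0]
    return y, (idx, (n, c, h, w, ph, pw))


def maxpool2_backward(dy: np.ndarray, ctx: tuple) -> np.ndarray:
    idx, (n, c, h, w, ph, pw) = ctx
    dr = np.zeros((n, c, ph // 2, pw // 2, 4))
    np.put_along_axis(dr, idx[..., None], dy[..., None], axis=-1)
    dxpad = dr.reshape(n, c, ph // 2, pw // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, ph, pw)
    return dxpad[:, :, :h, :w]


def upsample2(x: np.ndarray, out_hw: tuple[int, int]) -> np.ndarray:
    """Nearest-neighbour 2x upsampling cropped to ``out_hw``."""
    y = x.repeat(2, axis=2).repeat(2, axis=3)
    return y[:, :, :out_hw[0], :out_hw[1]]


def upsample2_backward(dy: np.ndarray, in_hw: tuple[int, int]) -> np.ndarray:
    h2, w2 = in_hw[0] * 2, in_hw[1] * 2
    full = np.zeros((dy.shape[0], dy.shape[1], h2, w2))
    full[:, :, :dy.shape[2], :dy.shape[3]] = dy
    return full.reshape(dy.shape[0], dy.shape[1], in_hw[0], 2, in_hw[1], 2).sum(axis=(3, 5))


class ConvBlock:
    """conv 3x3 -> batch norm -> ReLU."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        self.layers = [Conv3x3(c_in, c_out, rng), BatchNorm(c_out), ReLU()]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    @property
    def params(self):
        return [p for l in self.layers for p in l.params]

    @property
    def grads(self):
        return [g for l in self.layers for g in l.grads]

    @property
    def buffers(self):
        return [b for l in self.layers for b in l.buffers]


class UNetEncoder:
    """Contracting path: depth blocks with channel doubling, pooling between."""

    def __init__(self, c_in: int, base: int, depth: int, rng: np.random.Generator):
        self.depth = depth
        self.blocks = []
        c = c_in
        for i in range(depth):
            c_out = base * (2 ** i)
            self.blocks.append(ConvBlock(c, c_out, rng))
            c = c_out
        self.out_channels = c

    def forward(self, x: np.ndarray, train: bool) -> tuple[np.ndarray, list]:
        skips, pools = [], []
        for i, block in enumerate(self.blocks):
            x = block.forward(x, train)
            if i < self.depth - 1:
                skips.append(x)
                x, ctx = maxpool2(x)
                pools.append(ctx)
        self._pools = pools
        return x, skips

    def backward(self, dy: np.ndarray, dskips: list) -> np.ndarray:
        for i in range(self.depth - 1, -1, -1):
            if i < self.depth - 1:
                dy = maxpool2_backward(dy, self._pools[i])
                if dskips[i] is not None:
                    dy = dy + dskips[i]
            dy = self.blocks[i].backward(dy)
        return dy

    @property
    def params(self):
        return [p for b in self.blocks for p in b.params]

    @property
    def grads(self):
        return [g for b in self.blocks for g in b.grads]

    @property
    def buffers(self):
        return [x for b in self.blocks for x in b.buffers]


class UNet:
    """Encoder-decoder with skip connections; logit output map."""

    def __init__(self, c_in: int, base: int = 32, depth: int = 6,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.encoder = UNetEncoder(c_in, base, depth, rng)
        self.depth = depth
        self.dec_blocks = []
        c = self.encoder.out_channels
        for i in range(depth - 2, -1, -1):
            skip_c = base * (2 ** i)
            self.dec_blocks.append(ConvBlock(c + skip_c, skip_c, rng))
            c = skip_c
        self.head = Conv1x1(c, 1, rng)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        y, skips = self.encoder.forward(x, train)
        self._dec_ctx = []
        for k, block in enumerate(self.dec_blocks):
            skip = skips[self.depth - 2 - k]
            in_hw = (y.shape[2], y.shape[3])
            y = upsample2(y, (skip.shape[2], skip.shape[3]))
            cat = np.concatenate([y, skip], axis=1)
            self._dec_ctx.append((in_hw, y.shape[1]))
            y = block.forward(cat, train)
        return self.head.forward(y, train)[:, 0]

    def backward(self, dlogits: np.ndarray) -> None:
        dy = self.head.backward(dlogits[:, None])
        dskips: list = [None] * (self.depth - 1)
        for k in range(len(self.dec_blocks) - 1, -1, -1):
            in_hw, up_c = self._dec_ctx[k]
            dcat = self.dec_blocks[k].backward(dy)
            dup, dskip = dcat[:, :up_c], dcat[:, up_c:]
            dskips[self.depth - 2 - k] = dskip
            dy = upsample2_backward(dup, in_hw)
        self.encoder.backward(dy, dskips)

    @property
    def params(self):
        return self.encoder.params + [p for b in self.dec_blocks for p in b.params] + self.head.params

    @property
    def grads(self):
        return self.encoder.grads + [g for b in self.dec_blocks for g in b.grads] + self.head.grads

    @property
    def buffers(self):
        return self.encoder.buffers + [x for b in self.dec_blocks for x in b.buffers]

    @property
    def state(self):
        return self.params + self.buffers


class EncoderClassifier:
    """UNet encoder + adaptive average pooling + linear head -> scalar logit."""

    def __init__(self, c_in: int, base: int = 32, depth: int = 6,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.encoder = UNetEncoder(c_in, base, depth, rng)
        c = self.encoder.out_channels
        self.w = rng.normal(0.0, 1.0 / math.sqrt(c), size=c)
        self.b = np.zeros(1)
        self._wgrad = np.zeros_like(self.w)
        self._bgrad = np.zeros_like(self.b)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        y, _ = self.encoder.forward(x, train)
        pooled = y.mean(axis=(2, 3))          # adaptive average pool to 1x1
        if train:
            self._pooled, self._hw = pooled, (y.shape[2], y.shape[3])
        return pooled @ self.w + self.b[0]

    def backward(self, dlogit: np.ndarray) -> None:
        self._wgrad += dlogit @ self._pooled
        self._bgrad += dlogit.sum(keepdims=True)
        dpooled = np.outer(dlogit, self.w)
        h, w = self._hw
        dy = dpooled[:, :, None, None] / (h * w) * np.ones((1, 1, h, w))
        self.encoder.backward(dy, [None] * (self.encoder.depth - 1))

    @property
    def params(self):
        return self.encoder.params + [self.w, self.b]

    @property
    def grads(self):
        return self.encoder.grads + [self._wgrad, self._bgrad]

    @property
    def buffers(self):
        return self.encoder.buffers

    @property
    def state(self):
        return self.params + self.buffers


# ------------------------------------------------------------- optimizer


class Adam:
    def __init__(self, params: Sequence[np.ndarray], grads: Sequence[np.ndarray],
                 lr: float = 1e-3, betas: tuple[float, float] = (0.9, 0.999)):
        self.params, self.grads = list(params), list(grads)
        self.lr = lr
        self.b1, self.b2 = betas
        self.m = [np.zeros_like(p) for p in self.params]
        self.v = [np.zeros_like(p) for p in self.params]
        self.t = 0

    def zero_grad(self) -> None:
        for g in self.grads:
            g[...] = 0.0

    def step(self) -> None:
        self.t += 1
        for p, g, m, v in zip(self.params, self.grads, self.m, self.v):
            m[...] = self.b1 * m + (1 - self.b1) * g
            v[...] = self.b2 * v + (1 - self.b2) * g * g
            mhat = m / (1 - self.b1 ** self.t)
            vhat = v / (1 - self.b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + 1e-8)


def one_cycle_lr(step: int, total_steps: int, max_lr: float,
                 warmup_frac: float = 0.3, min_frac: float = 0.04) -> float:
    """One-cycle schedule: linear warmup then cosine annealing."""
    total_steps = max(total_steps, 1)
    warm = max(int(total_steps * warmup_frac), 1)
    if step < warm:
        return max_lr * (step + 1) / warm
    prog = (step - warm) / max(total_steps - warm, 1)
    return max_lr * (min_frac + (1 - min_frac) * 0.5 * (1 + math.cos(math.pi * prog)))


# ----------------------------------------------------------------- losses


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_with_logits(z: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy; returns (loss, dloss/dz)."""
    p = sigmoid(z)
    pc = np.clip(p, _EPS, 1 - _EPS)
    loss = float(-(y * np.log(pc) + (1 - y) * np.log(1 - pc)).mean())
    return loss, (p - y) / z.size


def dice_loss(z: np.ndarray, y: np.ndarray, smooth: float = 1.0) -> tuple[float, np.ndarray]:
    """Soft dice per sample, averaged; returns (loss, dloss/dz)."""
    p = sigmoid(z)
    axes = tuple(range(1, z.ndim))
    inter = (p * y).sum(axis=axes)
    denom = p.sum(axis=axes) + y.sum(axis=axes) + smooth
    dice = (2 * inter + smooth) / denom
    loss = float((1 - dice).mean())
    # d(1-dice)/dp = -(2y*denom - (2*inter+smooth)) / denom^2
    dd = -(2 * y * denom.reshape(-1, *([1] * (z.ndim - 1)))
           - (2 * inter + smooth).reshape(-1, *([1] * (z.ndim - 1)))) \
        / denom.reshape(-1, *([1] * (z.ndim - 1))) ** 2
    dz = dd * p * (1 - p) / z.shape[0]
    return loss, dz


def focal_loss(z: np.ndarray, y: np.ndarray, gamma: float = 2.0,
               alpha: float = 0.5) -> tuple[float, np.ndarray]:
    """Mean focal loss; returns (loss, dloss/dz)."""
    p = np.clip(sigmoid(z), _EPS, 1 - _EPS)
    pt = np.where(y > 0.5, p, 1 - p)
    at = np.where(y > 0.5, alpha, 1 - alpha)
    loss = float((-at * (1 - pt) ** gamma * np.log(pt)).mean())
    # dL/dpt then chain: dpt/dz = pt(1-pt) * sign, sign=+1 for y=1, -1 for y=0
    dlpt = at * (gamma * (1 - pt) ** (gamma - 1) * np.log(pt) - (1 - pt) ** gamma / pt)
    sign = np.where(y > 0.5, 1.0, -1.0)
    dz = dlpt * pt * (1 - pt) * sign / z.size
    return loss, dz


def combo_loss(z: np.ndarray, y: np.ndarray,
               weights: tuple[float, float, float] = (1.0, 4.0, 1.0)) -> tuple[float, np.ndarray]:
    """Weighted BCE + dice + focal (the segmentation training loss)."""
    wb, wd, wf = weights
    lb, gb = bce_with_logits(z, y)
    ld, gd = dice_loss(z, y)
    lf, gf = focal_loss(z, y)
    return wb * lb + wd * ld + wf * lf, wb * gb + wd * gd + wf * gf
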