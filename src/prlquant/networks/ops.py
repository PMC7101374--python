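"""Minimal reverse-mode autodiff over numpy arrays (NCHW layout).

Provides exactly the operations the segmentation architectures need:
2-D convolution (im2col), ReLU, 2x2 max-pooling, nearest x2 upsampling,
channel concatenation, residual addition, inverted dropout, and a fused
binary-cross-entropy + soft-Dice loss on logits.  Float32 throughout.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Tensor:
    """Node in the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.ascontiguousarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple = ()
        self._backward = None

    @property
    def shape(self):
        return self.data.shape

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self) -> None:
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; graphs can be deep
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


def _accum(t: Tensor, g: np.ndarray) -> None:
    if t.grad is None:
        t.grad = g.astype(np.float32, copy=True)
    else:
        t.grad += g


def _make(data, parents, backward) -> Tensor:
    out = Tensor(data)
    out._parents = tuple(parents)
    out._backward = backward
    return out


def conv2d(x: Tensor, w: Tensor, b: Tensor, pad: int) -> Tensor:
    """Cross-correlation of (N,C,H,W) with (F,C,kh,kw) weights, zero padding."""
    n, c, h_in, w_in = x.data.shape
    f, c2, kh, kw = w.data.shape
    assert c == c2, f"channel mismatch: {c} vs {c2}"
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad))) if pad else x.data
    win = sliding_window_view(xp, (kh, kw), axis=(2, 3))  # (N,C,Ho,Wo,kh,kw)
    ho, wo = win.shape[2], win.shape[3]
    cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
        n * ho * wo, c * kh * kw
    )
    wmat = w.data.reshape(f, c * kh * kw)
    out = cols @ wmat.T + b.data  # (N*Ho*Wo, F)
    out = out.reshape(n, ho, wo, f).transpose(0, 3, 1, 2)

    def backward(g: np.ndarray) -> None:
        gm = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(n * ho * wo, f)
        _accum(w, (gm.T @ cols).reshape(w.data.shape))
        _accum(b, gm.sum(axis=0))
        dcols = (gm @ wmat).reshape(n, ho, wo, c, kh, kw)
        dxp = np.zeros((n, c, h_in + 2 * pad, w_in + 2 * pad), dtype=np.float32)
        for i in range(kh):
            for j in range(kw):
                dxp[:, :, i:i + ho, j:j + wo] += dcols[:, :, :, :, i, j].transpose(
                    0, 3, 1, 2
                )
        _accum(x, dxp[:, :, pad:pad + h_in, pad:pad + w_in])

    return _make(out, (x, w, b), backward)


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    out_data = x.data * mask

    def backward(g):
        _accum(x, g * mask)

    return _make(out_data, (x,), backward)


def maxpool2(x: Tensor) -> Tensor:
    n, c, h, w = x.data.shape
    assert h % 2 == 0 and w % 2 == 0, "maxpool2 needs even spatial dims"
    ho, wo = h // 2, w // 2
    windows = x.data.reshape(n, c, ho, 2, wo, 2).transpose(0, 1, 2, 4, 3, 5)
    flat = np.ascontiguousarray(windows).reshape(n, c, ho, wo, 4)
    idx = flat.argmax(axis=-1)
    out_data = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]

    def backward(g):
        dflat = np.zeros_like(flat)
        np.put_along_axis(dflat, idx[..., None], g[..., None], axis=-1)
        dx = dflat.reshape(n, c, ho, wo, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(
            n, c, h, w
        )
        _accum(x, dx)

    return _make(out_data, (x,), backward)


def upsample2(x: Tensor) -> Tensor:
    """Nearest-neighbour x2 upsampling."""
    out_data = x.data.repeat(2, axis=2).repeat(2, axis=3)
    n, c, h, w = x.data.shape

    def backward(g):
        _accum(x, g.reshape(n, c, h, 2, w, 2).sum(axis=(3, 5)))

    return _make(out_data, (x,), backward)


def concat(a: Tensor, b: Tensor) -> Tensor:
    ca = a.data.shape[1]
    out_data = np.concatenate([a.data, b.data], axis=1)

    def backward(g):
        _accum(a, g[:, :ca])
        _accum(b, g[:, ca:])

    return _make(out_data, (a, b), backward)


def add(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data + b.data

    def backward(g):
        _accum(a, g)
        _accum(b, g)

    return _make(out_data, (a, b), backward)


def dropout(x: Tensor, rate: float, rng: np.random.Generator,
            training: bool) -> Tensor:
    """Inverted dropout; identity when rate == 0 or in eval mode."""
    if not training or rate <= 0.0:
        return x
    keep = 1.0 - rate
    mask = (rng.random(x.data.shape) < keep).astype(np.float32) / keep
    out_data = x.data * mask

    def backward(g):
        _accum(x, g * mask)

    return _make(out_data, (x,), backward)


def sigmoid_np(z: np.ndarray) -> np.ndarray:
    """Numerically stable sigmoid on a plain array (inference path)."""
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_dice_with_logits(logits: Tensor, target: np.ndarray,
                         dice_weight: float = 1.0, eps: float = 1e-6) -> Tensor:
    """Mean binary cross-entropy on logits plus (1 - soft Dice), fused.

    Gradient w.r.t. logits is analytic:
    d(bce)/dz = (sigmoid(z) - y) / Npix;
    d(1-dice)/dz = -d(dice)/dp * p(1-p).
    """
    z = logits.data.astype(np.float64)
    y = np.asarray(target, dtype=np.float64)
    assert z.shape == y.shape, f"shape mismatch {z.shape} vs {y.shape}"
    npix = z.size

    bce = np.mean(np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z))))
    p = sigmoid_np(z)
    sp, sy, spy = p.sum(), y.sum(), (p * y).sum()
    denom = sp + sy + eps
    dice = (2.0 * spy + eps) / denom
    loss = bce + dice_weight * (1.0 - dice)

    def backward(g):
        gs = float(np.asarray(g).ravel()[0])  # scalar upstream gradient
        dz = (p - y) / npix
        ddice_dp = (2.0 * y * denom - (2.0 * spy + eps)) / (denom * denom)
        dz = dz - dice_weight * ddice_dp * p * (1.0 - p)
        _accum(logits, (gs * dz).astype(np.float32))

    return _make(np.float32(loss), (logits,), backward)


class Adam:
    """Adam optimizer over a list of parameter Tensors."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
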