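"""Minimal CPU autodiff for volumetric convolutional networks.

A small reverse-mode tape over numpy arrays, providing exactly the
operations the segmentation network needs: 3D convolution (arbitrary
kernel/stride, "same" or valid padding), 2×2×2 stride-2 transposed
convolution, leaky ReLU, sigmoid, channel concatenation, elementwise
sum, nearest-neighbour upsampling, spatial (whole-channel) dropout and
the soft-Dice loss.  Tensors are channels-first ``(C, D, H, W)`` with an
implicit batch of one; everything is float32.

Gradient correctness is covered by finite-difference tests.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Tensor", "Parameter", "conv3d", "conv_transpose3d_2x", "leaky_relu", "sigmoid",
           "add", "concat", "upsample2", "spatial_dropout", "soft_dice_loss", "Adam"]


class Tensor:
    """A node in the computation tape."""

    __slots__ = ("value", "grad", "parents", "_backward", "requires_grad", "name")

    def __init__(self, value, parents=(), backward=None, requires_grad=False, name=""):
        self.value = np.asarray(value, dtype=np.float32)
        self.grad = None
        self.parents = tuple(parents)
        self._backward = backward
        self.requires_grad = requires_grad or any(p.requires_grad for p in self.parents)
        self.name = name

    @property
    def shape(self):
        return self.value.shape

    def accumulate(self, g) -> None:
        if self.grad is None:
            self.grad = np.asarray(g, dtype=np.float32).copy()
        else:
            self.grad += g

    def backward(self) -> None:
        """Reverse-mode sweep from this (scalar) tensor."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node.parents:
                stack.append((p, False))
        self.grad = np.ones_like(self.value)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


class Parameter(Tensor):
    """A learnable tensor."""

    def __init__(self, value, name=""):
        super().__init__(value, requires_grad=True, name=name)


# ---------------------------------------------------------------------------
# convolution kernels (forward/backward as plain-array helpers)


def _conv3d_forward(x, w, stride, pad):
    xp = np.pad(x, ((0, 0),) + tuple((p, p) for p in pad)) if any(pad) else x
    win = sliding_window_view(xp, w.shape[2:], axis=(1, 2, 3))
    if stride > 1:
        win = win[:, ::stride, ::stride, ::stride]
    y = np.tensordot(w, win, axes=([1, 2, 3, 4], [0, 4, 5, 6]))
    return np.ascontiguousarray(y), xp


def _conv3d_backward(gy, xp, w, stride, pad, x_shape):
    win = sliding_window_view(xp, w.shape[2:], axis=(1, 2, 3))
    if stride > 1:
        win = win[:, ::stride, ::stride, ::stride]
    gw = np.tensordot(gy, win, axes=([1, 2, 3], [1, 2, 3]))
    gxp = np.zeros_like(xp)
    Do, Ho, Wo = gy.shape[1:]
    for i in range(w.shape[2]):
        for j in range(w.shape[3]):
            for k in range(w.shape[4]):
                t = np.tensordot(w[:, :, i, j, k], gy, axes=(0, 0))
                gxp[
                    :,
                    i : i + stride * Do : stride,
                    j : j + stride * Ho : stride,
                    k : k + stride * Wo : stride,
                ] += t
    if any(pad):
        sl = (slice(None),) + tuple(
            slice(p, p + n) for p, n in zip(pad, x_shape[1:])
        )
        gx = gxp[sl]
    else:
        gx = gxp
    return np.ascontiguousarray(gx), gw


def conv3d(x: Tensor, w: Parameter, b: Parameter, stride: int = 1, pad="same") -> Tensor:
    """3D convolution (cross-correlation); ``pad='same'`` keeps odd-kernel
    stride-1 outputs at the input size; stride-s with even kernels uses
    pad 0 (exact tiling)."""
    if pad == "same":
        pads = tuple(k // 2 for k in w.value.shape[2:])
    else:
        pads = tuple(pad) if hasattr(pad, "__len__") else (int(pad),) * 3
    y, xp = _conv3d_forward(x.value, w.value, stride, pads)
    y += b.value[:, None, None, None]

    def backward(gy):
        gx, gw = _conv3d_backward(gy, xp, w.value, stride, pads, x.value.shape)
        w.accumulate(gw)
        b.accumulate(gy.sum(axis=(1, 2, 3)))
        if x.requires_grad:
            x.accumulate(gx)

    return Tensor(y, (x, w, b), backward)


def conv_transpose3d_2x(x: Tensor, w: Parameter, b: Parameter) -> Tensor:
    """2×2×2 stride-2 transposed convolution (exact ×2 upsampling).

    ``w`` has shape (C_in, C_out, 2, 2, 2); output blocks do not overlap.
    """
    cin, cout = w.value.shape[:2]
    D, H, W = x.value.shape[1:]
    y = np.empty((cout, 2 * D, 2 * H, 2 * W), dtype=np.float32)
    for i in range(2):
        for j in range(2):
            for k in range(2):
                y[:, i::2, j::2, k::2] = np.tensordot(w.value[:, :, i, j, k], x.value, axes=(0, 0))
    y += b.value[:, None, None, None]

    def backward(gy):
        gw = np.empty_like(w.value)
        gx = np.zeros_like(x.value)
        for i in range(2):
            for j in range(2):
                for k in range(2):
                    sub = gy[:, i::2, j::2, k::2]
                    gw[:, :, i, j, k] = np.tensordot(x.value, sub, axes=([1, 2, 3], [1, 2, 3]))
                    gx += np.tensordot(w.value[:, :, i, j, k], sub, axes=(1, 0))
        w.accumulate(gw)
        b.accumulate(gy.sum(axis=(1, 2, 3)))
        if x.requires_grad:
            x.accumulate(gx)

    return Tensor(y, (x, w, b), backward)


# ---------------------------------------------------------------------------
# pointwise / structural ops


def leaky_relu(x: Tensor, slope: float = 0.01) -> Tensor:
    pos = x.value > 0
    y = np.where(pos, x.value, slope * x.value)

    def backward(gy):
        x.accumulate(np.where(pos, gy, slope * gy))

    return Tensor(y, (x,), backward)


def sigmoid(x: Tensor) -> Tensor:
    y = 1.0 / (1.0 + np.exp(-np.clip(x.value, -60, 60)))

    def backward(gy):
        x.accumulate(gy * y * (1.0 - y))

    return Tensor(y, (x,), backward)


def add(*xs: Tensor) -> Tensor:
    y = xs[0].value.copy()
    for t in xs[1:]:
        y += t.value

    def backward(gy):
        for t in xs:
            if t.requires_grad:
                t.accumulate(gy)

    return Tensor(y, xs, backward)


def concat(xs, axis: int = 0) -> Tensor:
    xs = tuple(xs)
    y = np.concatenate([t.value for t in xs], axis=axis)
    sizes = [t.value.shape[axis] for t in xs]

    def backward(gy):
        off = 0
        for t, n in zip(xs, sizes):
            if t.requires_grad:
                sl = [slice(None)] * gy.ndim
                sl[axis] = slice(off, off + n)
                t.accumulate(gy[tuple(sl)])
            off += n

    return Tensor(y, xs, backward)


def upsample2(x: Tensor) -> Tensor:
    """Nearest-neighbour ×2 upsampling along the three spatial axes."""
    y = x.value.repeat(2, axis=1).repeat(2, axis=2).repeat(2, axis=3)

    def backward(gy):
        C, D, H, W = x.value.shape
        g = gy.reshape(C, D, 2, H, 2, W, 2).sum(axis=(2, 4, 6))
        x.accumulate(g)

    return Tensor(y, (x,), backward)


def spatial_dropout(x: Tensor, rate: float, rng: np.random.Generator, train: bool) -> Tensor:
    """Drop whole feature-map channels (inverted scaling)."""
    if not train or rate <= 0.0:
        return x
    keep = (rng.random(x.value.shape[0]) >= rate).astype(np.float32) / (1.0 - rate)
    mask = keep[:, None, None, None]
    y = x.value * mask

    def backward(gy):
        x.accumulate(gy * mask)

    return Tensor(y, (x,), backward)


def soft_dice_loss(pred: Tensor, target: np.ndarray, eps: float = 1.0) -> Tensor:
    """1 − (2·Σpt + ε) / (Σp + Σt + ε), differentiable in ``pred``.

    ε (default 1.0, in voxel units) stabilizes the empty-mask case.
    """
    t = np.asarray(target, dtype=np.float32)
    if t.shape != pred.value.shape:
        raise ValueError(f"shape mismatch: pred {pred.value.shape} vs target {t.shape}")
    num = 2.0 * float((pred.value * t).sum()) + eps
    den = float(pred.value.sum()) + float(t.sum()) + eps
    loss = 1.0 - num / den

    def backward(gy):
        g = float(gy) * (num / den**2 - 2.0 * t / den)
        pred.accumulate(g)

    return Tensor(np.float32(loss), (pred,), backward)


# ---------------------------------------------------------------------------
# optimizer


class Adam:
    """Adaptive moment estimation.

    ``eps`` defaults to 0 (the training recipe); updates where the second
    moment is still exactly zero are skipped to keep 0/0 at 0.
    """

    def __init__(self, params, lr=5e-4, beta1=0.9, beta2=0.999, eps=0.0):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * g * g
            denom = np.sqrt(v / b2t) + self.eps
            upd = np.divide(m / b1t, denom, out=np.zeros_like(m), where=denom > 0)
            p.value -= self.lr * upd

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
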