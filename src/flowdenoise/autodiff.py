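"""Minimal reverse-mode autodiff over numpy arrays.

Just enough machinery for the small convolutional backbones used here:
dense layers, 3x3 same-padding convolutions, SiLU, 2x2 average pooling,
nearest-neighbour upsampling, channel concatenation, dropout and a squared
loss.  Convolutions are expressed as nine shifted einsums, so everything is
vectorized; no compiled code.  Gradient correctness is pinned down by
finite-difference tests.
"""

from __future__ import annotations

from typing import Callable, Optional

import numpy as np

__all__ = ["Tensor", "add", "matmul", "conv3x3", "silu", "avgpool2", "upsample2",
           "concat_channels", "dropout", "sum_squares", "scale"]


class Tensor:
    """Node in the computation graph: a value, an accumulated grad, a backward rule."""

    __slots__ = ("value", "grad", "parents", "backward_fn")

    def __init__(
        self,
        value: np.ndarray,
        parents: tuple = (),
        backward_fn: Optional[Callable[[np.ndarray], None]] = None,
    ):
        self.value = np.asarray(value, dtype=float)
        self.grad: Optional[np.ndarray] = None
        self.parents = parents
        self.backward_fn = backward_fn

    @property
    def shape(self):
        return self.value.shape

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(g, dtype=float)
        else:
            self.grad += g

    def backward(self) -> None:
        """Backpropagate from this (scalar) node through the graph."""
        if self.value.ndim != 0:
            raise ValueError("backward() must start from a scalar node")
        order: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node.parents:
                stack.append((p, False))
        self.grad = np.ones_like(self.value)
        for node in reversed(order):
            if node.backward_fn is not None and node.grad is not None:
                node.backward_fn(node.grad)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=float))


def add(a: Tensor, b: Tensor) -> Tensor:
    """Broadcasting addition; reduces gradients over broadcast axes."""
    a, b = _as_tensor(a), _as_tensor(b)
    out_val = a.value + b.value

    def backward(g: np.ndarray) -> None:
        a._accumulate(_unbroadcast(g, a.value.shape))
        b._accumulate(_unbroadcast(g, b.value.shape))

    return Tensor(out_val, (a, b), backward)


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``g`` down to ``shape`` (inverse of numpy broadcasting)."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


def scale(a: Tensor, s: float) -> Tensor:
    a = _as_tensor(a)

    def backward(g: np.ndarray) -> None:
        a._accumulate(g * s)

    return Tensor(a.value * s, (a,), backward)


def matmul(x: Tensor, w: Tensor) -> Tensor:
    """(B, F) @ (F, O)."""
    x, w = _as_tensor(x), _as_tensor(w)

    def backward(g: np.ndarray) -> None:
        x._accumulate(g @ w.value.T)
        w._accumulate(x.value.T @ g)

    return Tensor(x.value @ w.value, (x, w), backward)


def silu(x: Tensor) -> Tensor:
    x = _as_tensor(x)
    s = 1.0 / (1.0 + np.exp(-x.value))
    out_val = x.value * s

    def backward(g: np.ndarray) -> None:
        x._accumulate(g * s * (1.0 + x.value * (1.0 - s)))

    return Tensor(out_val, (x,), backward)


def conv3x3(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Same-padding 3x3 convolution: (B,C,H,W) x (O,C,3,3) -> (B,O,H,W).

    Implemented as nine shifted einsums; the backward pass mirrors them
    exactly, accumulating into a padded gradient buffer.
    """
    x, w, b = _as_tensor(x), _as_tensor(w), _as_tensor(b)
    B, C, H, W = x.value.shape
    O = w.value.shape[0]
    xp = np.pad(x.value, ((0, 0), (0, 0), (1, 1), (1, 1)))
    out_val = np.empty((B, O, H, W))
    out_val[:] = b.value[None, :, None, None]
    for dy in range(3):
        for dx in range(3):
            out_val += np.einsum(
                "bchw,oc->bohw",
                xp[:, :, dy : dy + H, dx : dx + W],
                w.value[:, :, dy, dx],
                optimize=True,
            )

    def backward(g: np.ndarray) -> None:
        gxp = np.zeros_like(xp)
        gw = np.empty_like(w.value)
        for dy in range(3):
            for dx in range(3):
                patch = xp[:, :, dy : dy + H, dx : dx + W]
                gw[:, :, dy, dx] = np.einsum("bohw,bchw->oc", g, patch, optimize=True)
                gxp[:, :, dy : dy + H, dx : dx + W] += np.einsum(
                    "bohw,oc->bchw", g, w.value[:, :, dy, dx], optimize=True
                )
        x._accumulate(gxp[:, :, 1 : 1 + H, 1 : 1 + W])
        w._accumulate(gw)
        b._accumulate(g.sum(axis=(0, 2, 3)))

    return Tensor(out_val, (x, w, b), backward)


def avgpool2(x: Tensor) -> Tensor:
    """2x2 average pooling with stride 2; H and W must be even."""
    x = _as_tensor(x)
    B, C, H, W = x.value.shape
    if H % 2 or W % 2:
        raise ValueError(f"avgpool2 needs even spatial dims, got {H}x{W}")
    v = x.value.reshape(B, C, H // 2, 2, W // 2, 2).mean(axis=(3, 5))

    def backward(g: np.ndarray) -> None:
        gx = np.repeat(np.repeat(g, 2, axis=2), 2, axis=3) / 4.0
        x._accumulate(gx)

    return Tensor(v, (x,), backward)


def upsample2(x: Tensor) -> Tensor:
    """Nearest-neighbour 2x upsampling."""
    x = _as_tensor(x)
    v = np.repeat(np.repeat(x.value, 2, axis=2), 2, axis=3)

    def backward(g: np.ndarray) -> None:
        B, C, H2, W2 = g.shape
        gx = g.reshape(B, C, H2 // 2, 2, W2 // 2, 2).sum(axis=(3, 5))
        x._accumulate(gx)

    return Tensor(v, (x,), backward)


def concat_channels(a: Tensor, b: Tensor) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    ca = a.value.shape[1]

    def backward(g: np.ndarray) -> None:
        a._accumulate(g[:, :ca])
        b._accumulate(g[:, ca:])

    return Tensor(np.concatenate([a.value, b.value], axis=1), (a, b), backward)


def dropout(x: Tensor, p: float, rng: np.random.Generator) -> Tensor:
    """Inverted dropout; identity when p == 0."""
    x = _as_tensor(x)
    if p <= 0.0:
        return x
    mask = (rng.random(x.value.shape) >= p) / (1.0 - p)

    def backward(g: np.ndarray) -> None:
        x._accumulate(g * mask)

    return Tensor(x.value * mask, (x,), backward)


def reshape(x: Tensor, shape: tuple) -> Tensor:
    x = _as_tensor(x)
    old = x.value.shape

    def backward(g: np.ndarray) -> None:
        x._accumulate(g.reshape(old))

    return Tensor(x.value.reshape(shape), (x,), backward)


def sum_squares(x: Tensor) -> Tensor:
    """Scalar sum of squared entries."""
    x = _as_tensor(x)

    def backward(g: np.ndarray) -> None:
        x._accumulate(2.0 * g * x.value)

    return Tensor(np.sum(x.value * x.value), (x,), backward)
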