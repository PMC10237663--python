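"""A minimal reverse-mode automatic-differentiation tape over numpy arrays.

Everything the network needs — broadcast arithmetic, matmul, 2-D
cross-correlation, max pooling, per-channel / per-position reductions,
ReLU, sigmoid, concatenation and a fused softmax cross-entropy — is a
:class:`Tensor` op with a hand-derived backward rule. Gradients are
accumulated by a topological sweep from the loss.

Feature maps are NHWC: ``(batch, height, width, channels)``. Convolution
kernels are ``(kh, kw, c_in, c_out)``. "Convolution" is cross-correlation
(no kernel flip), the deep-learning convention.

The tape is dtype-agnostic: float64 for oracle/gradient checks, float32
for training.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

Array = np.ndarray


class Tensor:
    """An array plus the bookkeeping needed to backpropagate through it."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward", "name")

    def __init__(
        self,
        data: Array | float,
        requires_grad: bool = False,
        parents: tuple["Tensor", ...] = (),
        backward: Callable[[Array], None] | None = None,
        name: str = "",
    ):
        self.data = np.asarray(data)
        self.grad: Array | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents
        self._backward = backward
        self.name = name

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def accumulate(self, g: Array) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data, dtype=self.data.dtype)
        self.grad += g

    def backward(self, seed: Array | None = None) -> None:
        """Backpropagate from this tensor (default seed: ones)."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen and p.requires_grad:
                    stack.append((p, False))
        self.accumulate(
            np.ones_like(self.data) if seed is None else np.asarray(seed, dtype=self.data.dtype)
        )
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, grad={self.requires_grad}, name={self.name!r})"


def as_tensor(x: Tensor | Array | float) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _unbroadcast(grad: Array, shape: tuple[int, ...]) -> Array:
    """Sum *grad* down to *shape* (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


# ---------------------------------------------------------------------------
# arithmetic
# ---------------------------------------------------------------------------


def add(a: Tensor, b: Tensor | float) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data + b.data

    def bwd(g: Array) -> None:
        if a.requires_grad:
            a.accumulate(_unbroadcast(g, a.shape))
        if b.requires_grad:
            b.accumulate(_unbroadcast(g, b.shape))

    return Tensor(out_data, parents=(a, b), backward=bwd)


def mul(a: Tensor, b: Tensor | float) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data * b.data

    def bwd(g: Array) -> None:
        if a.requires_grad:
            a.accumulate(_unbroadcast(g * b.data, a.shape))
        if b.requires_grad:
            b.accumulate(_unbroadcast(g * a.data, b.shape))

    return Tensor(out_data, parents=(a, b), backward=bwd)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data @ b.data

    def bwd(g: Array) -> None:
        if a.requires_grad:
            a.accumulate(g @ b.data.T)
        if b.requires_grad:
            b.accumulate(a.data.T @ g)

    return Tensor(out_data, parents=(a, b), backward=bwd)


def relu(x: Tensor) -> Tensor:
    x = as_tensor(x)
    mask = x.data > 0  # subgradient at 0 is 0
    out_data = np.where(mask, x.data, 0)

    def bwd(g: Array) -> None:
        if x.requires_grad:
            x.accumulate(g * mask)

    return Tensor(out_data, parents=(x,), backward=bwd)


def sigmoid(x: Tensor) -> Tensor:
    x = as_tensor(x)
    s = np.empty_like(x.data)
    pos = x.data >= 0
    s[pos] = 1.0 / (1.0 + np.exp(-x.data[pos]))
    ex = np.exp(x.data[~pos])
    s[~pos] = ex / (1.0 + ex)

    def bwd(g: Array) -> None:
        if x.requires_grad:
            x.accumulate(g * s * (1.0 - s))

    return Tensor(s, parents=(x,), backward=bwd)


def reshape(x: Tensor, shape: tuple[int, ...]) -> Tensor:
    x = as_tensor(x)
    out_data = x.data.reshape(shape)

    def bwd(g: Array) -> None:
        if x.requires_grad:
            x.accumulate(g.reshape(x.shape))

    return Tensor(out_data, parents=(x,), backward=bwd)


def concat(tensors: Sequence[Tensor], axis: int) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g: Array) -> None:
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(lo, hi)
                t.accumulate(g[tuple(idx)])

    return Tensor(out_data, parents=tuple(tensors), backward=bwd)


# ---------------------------------------------------------------------------
# convolution and pooling
# ---------------------------------------------------------------------------


def _pad_same(x: Array, kh: int, kw: int) -> tuple[Array, int, int]:
    ph, pw = kh // 2, kw // 2
    return np.pad(x, ((0, 0), (ph, ph), (pw, pw), (0, 0))), ph, pw


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, *,
           stride: int = 1, padding: str = "same") -> Tensor:
    """2-D cross-correlation, NHWC input, (kh,kw,Cin,Cout) kernel bank."""
    x, w = as_tensor(x), as_tensor(w)
    kh, kw, c_in, c_out = w.shape
    if x.shape[3] != c_in:
        raise ValueError(f"channel mismatch: input {x.shape[3]} vs kernel {c_in}")
    if padding == "same":
        if kh % 2 == 0 or kw % 2 == 0:
            raise ValueError("same-padding requires odd kernel sizes")
        xp, ph, pw = _pad_same(x.data, kh, kw)
    elif padding == "valid":
        xp, ph, pw = x.data, 0, 0
    else:
        raise ValueError(f"unknown padding {padding!r}")
    n, hp, wp, _ = xp.shape
    ho = (hp - kh) // stride + 1
    wo = (wp - kw) // stride + 1
    if ho < 1 or wo < 1:
        raise ValueError("kernel larger than (padded) input")
    dtype = np.result_type(x.data, w.data)
    # im2col in one pass: one big GEMM instead of k*k small ones
    windows = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(1, 2))
    windows = windows[:, ::stride, ::stride]  # (N, Ho, Wo, C, kh, kw) view
    cols = np.ascontiguousarray(windows.transpose(0, 1, 2, 4, 5, 3)).reshape(
        n * ho * wo, kh * kw * c_in
    )
    if cols.dtype != dtype:
        cols = cols.astype(dtype)
    w_flat = w.data.reshape(kh * kw * c_in, c_out)
    out_data = (cols @ w_flat).reshape(n, ho, wo, c_out)
    if b is not None:
        b = as_tensor(b)
        out_data = out_data + b.data

    parents = (x, w) if b is None else (x, w, b)

    def bwd(g: Array) -> None:
        g2 = g.reshape(-1, c_out)
        if b is not None and b.requires_grad:
            b.accumulate(g2.sum(axis=0).astype(b.data.dtype))
        if w.requires_grad:
            w.accumulate((cols.T @ g2).reshape(w.shape).astype(w.data.dtype))
        if x.requires_grad:
            dcols = (g2 @ w_flat.T).reshape(n, ho, wo, kh * kw * c_in)
            dxp = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    tap = slice((i * kw + j) * c_in, (i * kw + j + 1) * c_in)
                    dxp[:, i : i + ho * stride : stride, j : j + wo * stride : stride, :] += (
                        dcols[..., tap]
                    )
            if ph or pw:
                x.accumulate(dxp[:, ph : hp - ph, pw : wp - pw, :])
            else:
                x.accumulate(dxp)

    return Tensor(out_data, parents=parents, backward=bwd)


def maxpool2d(x: Tensor, k: int = 2, stride: int | None = None) -> Tensor:
    """Max pooling; window must tile the spatial extent exactly."""
    x = as_tensor(x)
    stride = k if stride is None else stride
    if stride != k:
        raise ValueError("tape maxpool supports stride == window only")
    n, h, w, c = x.shape
    if h % k or w % k:
        raise ValueError(f"window {k} does not tile {h}x{w}")
    ho, wo = h // k, w // k
    windows = (
        x.data.reshape(n, ho, k, wo, k, c).transpose(0, 1, 3, 5, 2, 4).reshape(n, ho, wo, c, k * k)
    )
    idx = windows.argmax(axis=-1)
    out_data = np.take_along_axis(windows, idx[..., None], axis=-1)[..., 0]

    def bwd(g: Array) -> None:
        if not x.requires_grad:
            return
        dwin = np.zeros_like(windows)
        np.put_along_axis(dwin, idx[..., None], g[..., None], axis=-1)
        dx = (
            dwin.reshape(n, ho, wo, c, k, k).transpose(0, 1, 4, 2, 5, 3).reshape(n, h, w, c)
        )
        x.accumulate(dx)

    return Tensor(out_data, parents=(x,), backward=bwd)


def spatial_mean(x: Tensor) -> Tensor:
    """Global average pool over H and W: (N,H,W,C) -> (N,C)."""
    x = as_tensor(x)
    n, h, w, c = x.shape
    out_data = x.data.mean(axis=(1, 2))

    def bwd(g: Array) -> None:
        if x.requires_grad:
            x.accumulate(np.broadcast_to(g[:, None, None, :] / (h * w), x.shape).copy())

    return Tensor(out_data, parents=(x,), backward=bwd)


def spatial_max(x: Tensor) -> Tensor:
    """Global max pool over H and W: (N,H,W,C) -> (N,C)."""
    x = as_tensor(x)
    n, h, w, c = x.shape
    flat = x.data.reshape(n, h * w, c)
    idx = flat.argmax(axis=1)
    out_data = np.take_along_axis(flat, idx[:, None, :], axis=1)[:, 0, :]

    def bwd(g: Array) -> None:
        if not x.requires_grad:
            return
        dflat = np.zeros_like(flat)
        np.put_along_axis(dflat, idx[:, None, :], g[:, None, :], axis=1)
        x.accumulate(dflat.reshape(x.shape))

    return Tensor(out_data, parents=(x,), backward=bwd)


def channel_mean(x: Tensor) -> Tensor:
    """Cross-channel mean: (N,H,W,C) -> (N,H,W,1)."""
    x = as_tensor(x)
    c = x.shape[3]
    out_data = x.data.mean(axis=3, keepdims=True)

    def bwd(g: Array) -> None:
        if x.requires_grad:
            x.accumulate(np.broadcast_to(g / c, x.shape).copy())

    return Tensor(out_data, parents=(x,), backward=bwd)


def channel_max(x: Tensor) -> Tensor:
    """Cross-channel max: (N,H,W,C) -> (N,H,W,1)."""
    x = as_tensor(x)
    idx = x.data.argmax(axis=3)
    out_data = np.take_along_axis(x.data, idx[..., None], axis=3)

    def bwd(g: Array) -> None:
        if not x.requires_grad:
            return
        dx = np.zeros_like(x.data)
        np.put_along_axis(dx, idx[..., None], g, axis=3)
        x.accumulate(dx)

    return Tensor(out_data, parents=(x,), backward=bwd)


# ---------------------------------------------------------------------------
# loss
# ---------------------------------------------------------------------------


def softmax_cross_entropy(logits: Tensor, labels: Array) -> Tensor:
    """Mean negative log softmax probability of the true class (fused, stable)."""
    logits = as_tensor(logits)
    labels = np.asarray(labels)
    n = logits.shape[0]
    shifted = logits.data - logits.data.max(axis=1, keepdims=True)
    exps = np.exp(shifted)
    probs = exps / exps.sum(axis=1, keepdims=True)
    eps = np.finfo(probs.dtype).tiny
    loss = -np.log(probs[np.arange(n), labels] + eps).mean()

    def bwd(g: Array) -> None:
        if logits.requires_grad:
            d = probs.copy()
            d[np.arange(n), labels] -= 1.0
            logits.accumulate(g * d / n)

    return Tensor(loss, parents=(logits,), backward=bwd)
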