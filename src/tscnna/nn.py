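"""Network primitives: convolution, pooling, dense layer, softmax, objective.

These are the forward building blocks expressed over single H×W×C feature
maps. The same arithmetic backs the trainable network through the tape in
:mod:`tscnna.autodiff`; here each primitive is exposed functionally so it can
be checked directly against brute-force oracles.

Pooling follows the general form ``x' = g(γ · down(x) + b)`` where ``down``
is a windowed max or mean; γ=1, b=0 and identity g recover plain pooling,
which is what the assembled model uses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from tscnna import autodiff as ad

Array = np.ndarray


@dataclass
class ConvKernelBank:
    """Weights (k×k×C_in×C_out), biases (C_out,), stride and padding mode."""

    weights: Array
    biases: Array
    stride: int = 1
    padding: str = "same"

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights)
        self.biases = np.asarray(self.biases)
        kh, kw, _, c_out = self.weights.shape
        if kh % 2 == 0 or kw % 2 == 0:
            raise ValueError("kernel sizes must be odd")
        if self.biases.shape != (c_out,):
            raise ValueError("bias shape must be (C_out,)")
        if not (np.isfinite(self.weights).all() and np.isfinite(self.biases).all()):
            raise ValueError("non-finite parameters")


@dataclass
class DenseParams:
    """A dense layer y = g(Q x + bias); Q is (out, in)."""

    Q: Array
    bias: Array

    def __post_init__(self) -> None:
        self.Q = np.asarray(self.Q)
        self.bias = np.asarray(self.bias)
        if self.Q.ndim != 2 or self.bias.shape != (self.Q.shape[0],):
            raise ValueError("inconsistent dense shapes")


@dataclass
class PoolSpec:
    mode: str = "max"  # "max" | "average"
    window: int = 2
    stride: int = 2
    gamma: float = 1.0
    bias: float = 0.0
    activation: Callable[[Array], Array] = field(default=lambda x: x)

    def __post_init__(self) -> None:
        if self.mode not in ("max", "average"):
            raise ValueError(f"unknown pooling mode {self.mode!r}")
        if self.window < 1 or self.stride < 1:
            raise ValueError("window and stride must be >= 1")


def _check_map(x: Array) -> Array:
    x = np.asarray(x)
    if x.ndim != 3:
        raise ValueError(f"feature map must be H×W×C, got shape {x.shape}")
    if not np.isfinite(x).all():
        raise ValueError("non-finite feature map")
    return x


def conv2d(x: Array, bank: ConvKernelBank) -> Array:
    """Cross-correlate an H×W×C_in map with a kernel bank -> H'×W'×C_out."""
    x = _check_map(x)
    out = ad.conv2d(
        ad.Tensor(x[None]),
        ad.Tensor(bank.weights),
        ad.Tensor(bank.biases),
        stride=bank.stride,
        padding=bank.padding,
    )
    return out.data[0]


def pool2d(x: Array, spec: PoolSpec) -> Array:
    """Windowed per-channel pooling with the affine/activation wrapper."""
    x = _check_map(x)
    h, w, c = x.shape
    k, s = spec.window, spec.stride
    if h < k or w < k:
        raise ValueError("pooling window does not fit")
    ho = (h - k) // s + 1
    wo = (w - k) // s + 1
    out = np.empty((ho, wo, c), dtype=x.dtype)
    reduce = np.max if spec.mode == "max" else np.mean
    for i in range(ho):
        for j in range(wo):
            out[i, j] = reduce(x[i * s : i * s + k, j * s : j * s + k, :], axis=(0, 1))
    return spec.activation(spec.gamma * out + spec.bias)


def dense(x: Array, params: DenseParams,
          activation: Callable[[Array], Array] | None = None) -> Array:
    x = np.asarray(x)
    if x.shape != (params.Q.shape[1],):
        raise ValueError(f"dense input length {x.shape} != {params.Q.shape[1]}")
    y = params.Q @ x + params.bias
    return y if activation is None else activation(y)


def softmax_probs(logits: Array) -> Array:
    """Stable softmax: shift by the max, exponentiate, normalize."""
    logits = np.asarray(logits, dtype=float)
    if not np.isfinite(logits).all():
        raise ValueError("non-finite logits")
    shifted = logits - logits.max()
    exps = np.exp(shifted)
    return exps / exps.sum()


def objective(probabilities: Array, labels: Array) -> float:
    """Mean cross-entropy J(W) = −(1/N) Σ_n log p_n[y_n] over N samples."""
    p = np.asarray(probabilities, dtype=float)
    labels = np.asarray(labels)
    if p.ndim != 2:
        raise ValueError("probabilities must be N×C")
    n, c = p.shape
    if np.any((labels < 0) | (labels >= c)):
        raise ValueError("label out of range")
    rows = p[np.arange(n), labels]
    return float(-np.log(rows).mean())


def relu(x: Array) -> Array:
    return np.maximum(x, 0)
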