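"""Channel/spatial attention and the second-order residual fusion.

Channel attention (CBAM convention): global average- and max-pool each
channel over all spatial positions (two C-vectors), push both through the
SAME two-layer perceptron (reduce to C/r, ReLU, expand to C, no biases),
add, sigmoid:

    M_C(F) = σ(MLP(Avgpool(F)) + MLP(Maxpool(F)))            (C weights)

Spatial attention: pool ACROSS channels (mean and max per position, two
H×W maps), stack as 2 channels, convolve with a single 7×7 kernel at same
padding, sigmoid:

    M_S(F) = σ(f7×7([Avgpool(F); Maxpool(F)]))               (H×W weights)

Application: F' = M_C ⊗ F (broadcast over positions),
F'' = M_S ⊗ F' (broadcast over channels).

Residual fusion between the third and fourth convolution outputs X, X':

    f = X + X' + ReLU(X) ⊙ ReLU(X') + ξ,     ξ = 0.0001 by default,

followed by the combination F''' = F'' + f. The ReLU factors realize the
non-negative processing of the multiplicative (second-order) term; ξ is a
small constant offset that keeps gradients away from exact zero plateaus.

When two maps to be fused disagree in shape, spatial mismatch is resolved
by bilinear interpolation to a fixed size and channel mismatch by a 1×1
projection; in the default architecture both maps already agree so neither
path triggers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from tscnna import autodiff as ad
from tscnna.autodiff import Tensor

Array = np.ndarray


@dataclass
class ChannelAttentionParams:
    """Shared bottleneck MLP: reduce (C/r × C), expand (C × C/r), ratio r."""

    reduce: Array
    expand: Array
    ratio: int

    def __post_init__(self) -> None:
        self.reduce = np.asarray(self.reduce)
        self.expand = np.asarray(self.expand)
        c = self.reduce.shape[1]
        if c % self.ratio != 0 or self.reduce.shape[0] != c // self.ratio:
            raise ValueError("reduction ratio must divide the channel count")
        if self.expand.shape != (c, c // self.ratio):
            raise ValueError("expand matrix shape mismatch")


@dataclass
class SpatialAttentionParams:
    """One 7×7 convolution mapping the stacked mean/max maps to one channel."""

    kernel: Array  # (7, 7, 2, 1)
    bias: float = 0.0

    def __post_init__(self) -> None:
        self.kernel = np.asarray(self.kernel)
        if self.kernel.shape != (7, 7, 2, 1):
            raise ValueError(f"spatial kernel must be 7×7×2×1, got {self.kernel.shape}")


@dataclass
class ResidualFusionParams:
    offset: float = 0.0001  # ξ
    projection: Array | None = None  # optional 1×1×Cin×Cout for channel harmonization

    def __post_init__(self) -> None:
        if self.offset <= 0:
            raise ValueError("offset ξ must be positive")


# ---------------------------------------------------------------------------
# tape-level blocks (batched NHWC tensors) — used by the assembled model
# ---------------------------------------------------------------------------


def channel_attention_t(x: Tensor, reduce_w: Tensor, expand_w: Tensor) -> Tensor:
    """M_C as an (N, C) tensor on the tape."""
    avg = ad.spatial_mean(x)  # (N, C)
    mx = ad.spatial_max(x)

    def mlp(v: Tensor) -> Tensor:
        hidden = ad.relu(ad.matmul(v, _transpose(reduce_w)))
        return ad.matmul(hidden, _transpose(expand_w))

    return ad.sigmoid(ad.add(mlp(avg), mlp(mx)))


def spatial_attention_t(x: Tensor, kernel: Tensor, bias: Tensor) -> Tensor:
    """M_S as an (N, H, W, 1) tensor on the tape."""
    stacked = ad.concat([ad.channel_mean(x), ad.channel_max(x)], axis=3)
    return ad.sigmoid(ad.conv2d(stacked, kernel, bias, padding="same"))


def apply_attention_t(
    x: Tensor, reduce_w: Tensor, expand_w: Tensor, kernel: Tensor, bias: Tensor
) -> tuple[Tensor, Tensor]:
    """F' = M_C ⊗ F, then F'' = M_S(F') ⊗ F'."""
    mc = channel_attention_t(x, reduce_w, expand_w)  # (N, C)
    n, c = mc.shape
    f1 = ad.mul(x, ad.reshape(mc, (n, 1, 1, c)))
    ms = spatial_attention_t(f1, kernel, bias)  # (N, H, W, 1)
    f2 = ad.mul(f1, ms)
    return f1, f2


def residual_fuse_t(x: Tensor, x2: Tensor, offset: float) -> Tensor:
    """f = X + X' + ReLU(X) ⊙ ReLU(X') + ξ on the tape."""
    second_order = ad.mul(ad.relu(x), ad.relu(x2))
    return ad.add(ad.add(ad.add(x, x2), second_order), Tensor(offset))


def _transpose(t: Tensor) -> Tensor:
    out = Tensor(t.data.T, parents=(t,))

    def bwd(g: Array) -> None:
        if t.requires_grad:
            t.accumulate(g.T)

    out._backward = bwd
    return out


# ---------------------------------------------------------------------------
# functional surface (single H×W×C maps)
# ---------------------------------------------------------------------------


def channel_pools(f: Array) -> tuple[Array, Array]:
    """Per-channel global mean and max over all H×W positions."""
    f = np.asarray(f)
    return f.mean(axis=(0, 1)), f.max(axis=(0, 1))


def channel_attention(f: Array, params: ChannelAttentionParams) -> Array:
    f = np.asarray(f)
    if f.shape[2] != params.reduce.shape[1]:
        raise ValueError("channel count does not match attention parameters")
    out = channel_attention_t(
        Tensor(f[None]), Tensor(params.reduce), Tensor(params.expand)
    )
    return out.data[0]


def spatial_attention(f: Array, params: SpatialAttentionParams) -> Array:
    f = np.asarray(f)
    out = spatial_attention_t(
        Tensor(f[None]), Tensor(params.kernel), Tensor(np.asarray([params.bias]))
    )
    return out.data[0, :, :, 0]


def apply_attention(
    f: Array, cp: ChannelAttentionParams, sp: SpatialAttentionParams
) -> tuple[Array, Array]:
    f1, f2 = apply_attention_t(
        Tensor(np.asarray(f)[None]),
        Tensor(cp.reduce),
        Tensor(cp.expand),
        Tensor(sp.kernel),
        Tensor(np.asarray([sp.bias])),
    )
    return f1.data[0], f2.data[0]


def residual_fuse(x: Array, x2: Array, params: ResidualFusionParams | None = None) -> Array:
    """f = X + X' + ReLU(X) ⊙ ReLU(X') + ξ, elementwise; ξ added everywhere."""
    params = params or ResidualFusionParams()
    x, x2 = np.asarray(x, dtype=float), np.asarray(x2, dtype=float)
    x, x2 = harmonize(x, x2, params)
    return x + x2 + np.maximum(x, 0) * np.maximum(x2, 0) + params.offset


def combine(f2: Array, f: Array) -> Array:
    """F''' = F'' + f (elementwise)."""
    f2, f = np.asarray(f2), np.asarray(f)
    if f2.shape != f.shape:
        raise ValueError(f"shape mismatch {f2.shape} vs {f.shape}")
    return f2 + f


def harmonize(x: Array, x2: Array, params: ResidualFusionParams) -> tuple[Array, Array]:
    """Resolve spatial mismatch by bilinear resize, channels by 1×1 projection."""
    if x.shape[:2] != x2.shape[:2]:
        x2 = bilinear_resize(x2, x.shape[0], x.shape[1])
    if x.shape[2] != x2.shape[2]:
        if params.projection is None:
            raise ValueError(
                f"channel mismatch {x.shape[2]} vs {x2.shape[2]} and no 1×1 projection"
            )
        proj = params.projection
        x2 = np.tensordot(x2, proj[0, 0], axes=([2], [0]))
    if x.shape != x2.shape:
        raise ValueError("shapes cannot be harmonized")
    return x, x2


def bilinear_resize(f: Array, out_h: int, out_w: int) -> Array:
    """Bilinear interpolation to a fixed size (align-corners-false).

    Output sample centres are mapped to source coordinates
    ``(i + 0.5) * H/H_out - 0.5`` and clamped to the valid range, so
    resizing to the same size is the identity and constants stay constant.
    """
    f = np.asarray(f, dtype=float)
    if out_h < 1 or out_w < 1:
        raise ValueError("target size must be positive")
    h, w = f.shape[:2]
    squeeze = f.ndim == 2
    if squeeze:
        f = f[:, :, None]

    def grid(n_out: int, n_in: int) -> tuple[Array, Array, Array]:
        src = (np.arange(n_out) + 0.5) * (n_in / n_out) - 0.5
        src = np.clip(src, 0, n_in - 1)
        lo = np.floor(src).astype(int)
        hi = np.minimum(lo + 1, n_in - 1)
        return lo, hi, src - lo

    ylo, yhi, wy = grid(out_h, h)
    xlo, xhi, wx = grid(out_w, w)
    wy = wy[:, None, None]
    wx = wx[None, :, None]
    top = f[ylo][:, xlo] * (1 - wx) + f[ylo][:, xhi] * wx
    bot = f[yhi][:, xlo] * (1 - wx) + f[yhi][:, xhi] * wx
    out = top * (1 - wy) + bot * wy
    return out[:, :, 0] if squeeze else out
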