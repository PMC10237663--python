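"""The assembled TSCNNA network.

Architecture (input side 32 by default)::

    input 32×32×3
      ├─ 3×3 conv (K ch) ─┐
      ├─ 5×5 conv (K ch) ─┼─ concat → ReLU          = F1   (32×32×3K)
      └─ 7×7 conv (K ch) ─┘
    3×3 conv (conv2) + ReLU                                 (32×32)
    2×2 max pool                                            (16×16)
    3×3 conv (conv3) + ReLU                          = F = X (16×16)
    channel attention → F' ; spatial attention → F''        (16×16)
    3×3 conv (conv4) + ReLU on F''                   = X'   (16×16)
    f = X + X' + ReLU(X)⊙ReLU(X') + ξ  ;  F''' = F'' + f    (16×16)
    2×2 max pool                                            (8×8)
    3×3 tail conv + ReLU                                    (8×8)
    2×2 max pool                                            (4×4)
    global average pool → dense → softmax                   (C_out,)

The tail plays the role of the VGG-style back end, with the fully
connected stack replaced by global average pooling; at a 32-pixel input
only one conv/pool stage fits after the fusion without exhausting the
spatial extent. The classifier has ``num_classes`` outputs plus an
optional background class so the same network drives both whole-image
classification and the sliding-window detector's pest/non-pest decision.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from tscnna import autodiff as ad
from tscnna.autodiff import Tensor
from tscnna.attention import apply_attention_t, residual_fuse_t

Array = np.ndarray

STEM_KERNELS = (3, 5, 7)

LAYER_NAMES = ("F1", "F", "F'", "F''", "X'", "f", "F'''", "tail", "gap", "logits")


@dataclass(frozen=True)
class ArchitectureConfig:
    input_side: int = 32
    stem_channels: int = 32  # K: channels per stem kernel; F1 has 3K
    conv2_channels: int = 64
    conv3_channels: int = 128
    conv4_channels: int = 128
    tail_channels: int = 256
    num_classes: int = 4
    include_background: bool = True
    attention_ratio: int = 8
    residual_offset: float = 0.0001

    def __post_init__(self) -> None:
        if self.conv3_channels != self.conv4_channels:
            raise ValueError("conv3 and conv4 widths must match for the residual fusion")
        if self.conv3_channels % self.attention_ratio != 0:
            raise ValueError("attention ratio must divide the conv3 width")
        if self.num_classes < 2:
            raise ValueError("need at least two classes")
        if self.input_side % 8 != 0:
            raise ValueError("input side must be divisible by 8 (three 2×2 pools)")

    @property
    def n_outputs(self) -> int:
        return self.num_classes + (1 if self.include_background else 0)

    @property
    def background_index(self) -> int:
        if not self.include_background:
            raise ValueError("architecture has no background class")
        return self.num_classes


class ModelParameters:
    """All learnable tensors of the assembled network, plus its architecture."""

    def __init__(self, config: ArchitectureConfig, tensors: dict[str, Array]):
        self.config = config
        self.tensors = tensors

    def parameter_count(self) -> int:
        return sum(int(t.size) for t in self.tensors.values())

    def astype(self, dtype) -> "ModelParameters":
        return ModelParameters(
            self.config, {k: v.astype(dtype) for k, v in self.tensors.items()}
        )

    def copy(self) -> "ModelParameters":
        return ModelParameters(self.config, {k: v.copy() for k, v in self.tensors.items()})

    def save(self, path: str | Path) -> None:
        path = Path(path)
        meta = json.dumps(
            {"format": "tscnna-model/1", "architecture": asdict(self.config)}
        )
        np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8), **self.tensors)

    @classmethod
    def load(cls, path: str | Path) -> "ModelParameters":
        with np.load(Path(path).with_suffix(".npz") if not str(path).endswith(".npz") else path) as z:
            meta = json.loads(bytes(z["__meta__"]).decode())
            if meta.get("format") != "tscnna-model/1":
                raise ValueError("unsupported model file format")
            config = ArchitectureConfig(**meta["architecture"])
            tensors = {k: z[k] for k in z.files if k != "__meta__"}
        return cls(config, tensors)


def build_model(
    config: ArchitectureConfig | None = None,
    seed: int = 0,
    dtype=np.float64,
) -> ModelParameters:
    """Variance-scaled (He) random initialization, zero biases, fixed seed."""
    config = config or ArchitectureConfig()
    rng = np.random.default_rng(seed)
    k_stem = config.stem_channels
    c1 = 3 * k_stem
    c2, c3, c4 = config.conv2_channels, config.conv3_channels, config.conv4_channels
    c5, n_out, r = config.tail_channels, config.n_outputs, config.attention_ratio

    def he(shape: tuple[int, ...], fan_in: int) -> Array:
        return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(dtype)

    t: dict[str, Array] = {}
    for k in STEM_KERNELS:
        t[f"stem{k}_w"] = he((k, k, 3, k_stem), k * k * 3)
        t[f"stem{k}_b"] = np.zeros(k_stem, dtype=dtype)
    t["conv2_w"] = he((3, 3, c1, c2), 9 * c1)
    t["conv2_b"] = np.zeros(c2, dtype=dtype)
    t["conv3_w"] = he((3, 3, c2, c3), 9 * c2)
    t["conv3_b"] = np.zeros(c3, dtype=dtype)
    t["ca_reduce"] = he((c3 // r, c3), c3)
    t["ca_expand"] = he((c3, c3 // r), c3 // r)
    t["sa_kernel"] = he((7, 7, 2, 1), 98)
    t["sa_bias"] = np.zeros(1, dtype=dtype)
    t["conv4_w"] = he((3, 3, c3, c4), 9 * c3)
    t["conv4_b"] = np.zeros(c4, dtype=dtype)
    t["tail_w"] = he((3, 3, c4, c5), 9 * c4)
    t["tail_b"] = np.zeros(c5, dtype=dtype)
    t["fc_w"] = he((c5, n_out), c5)
    t["fc_b"] = np.zeros(n_out, dtype=dtype)
    return ModelParameters(config, t)


# ---------------------------------------------------------------------------
# forward pass
# ---------------------------------------------------------------------------


def three_scale_stem(batch: Tensor, t: dict[str, Tensor]) -> Tensor:
    """F1 = ReLU(concat(F11, F12, F13)): parallel 3/5/7 convs of one input."""
    maps = [
        ad.conv2d(batch, t[f"stem{k}_w"], t[f"stem{k}_b"], padding="same")
        for k in STEM_KERNELS
    ]
    return ad.relu(ad.concat(maps, axis=3))


def forward_t(
    params: ModelParameters,
    batch: Array,
    train_params: dict[str, Tensor] | None = None,
) -> tuple[Tensor, dict[str, Tensor]]:
    """Tape forward pass: returns logits tensor and named intermediates.

    If *train_params* is given (name → Tensor with ``requires_grad``) those
    tensors are used so gradients can be taken; otherwise the stored arrays
    are wrapped as constants.
    """
    t = train_params or {k: Tensor(v) for k, v in params.tensors.items()}
    x = Tensor(np.asarray(batch))
    inter: dict[str, Tensor] = {}
    f1 = three_scale_stem(x, t)
    inter["F1"] = f1
    h = ad.relu(ad.conv2d(f1, t["conv2_w"], t["conv2_b"], padding="same"))
    h = ad.maxpool2d(h, 2)
    f = ad.relu(ad.conv2d(h, t["conv3_w"], t["conv3_b"], padding="same"))
    inter["F"] = f  # = X
    fp, fpp = apply_attention_t(f, t["ca_reduce"], t["ca_expand"], t["sa_kernel"], t["sa_bias"])
    inter["F'"], inter["F''"] = fp, fpp
    xp = ad.relu(ad.conv2d(fpp, t["conv4_w"], t["conv4_b"], padding="same"))
    inter["X'"] = xp
    fused = residual_fuse_t(f, xp, params.config.residual_offset)
    inter["f"] = fused
    f3 = ad.add(fpp, fused)
    inter["F'''"] = f3
    h = ad.maxpool2d(f3, 2)
    h = ad.relu(ad.conv2d(h, t["tail_w"], t["tail_b"], padding="same"))
    inter["tail"] = h
    h = ad.maxpool2d(h, 2)
    gap = ad.spatial_mean(h)
    inter["gap"] = gap
    logits = ad.add(ad.matmul(gap, t["fc_w"]), t["fc_b"])
    inter["logits"] = logits
    return logits, inter


def preprocess(images: Array) -> Array:
    """uint8 H×W×3 (or N×H×W×3) images → float maps in [0, 1]."""
    images = np.asarray(images)
    if images.ndim == 3:
        images = images[None]
    if images.dtype == np.uint8:
        images = images.astype(np.float32) / 255.0
    return images


def _softmax_rows(logits: Array) -> Array:
    shifted = logits - logits.max(axis=1, keepdims=True)
    exps = np.exp(shifted)
    return exps / exps.sum(axis=1, keepdims=True)


def forward(
    params: ModelParameters,
    batch: Array,
    return_intermediates: bool = False,
):
    """Class-probability rows for a batch of images (N×C_out, rows sum to 1)."""
    x = preprocess(batch).astype(params.tensors["fc_w"].dtype)
    logits, inter = forward_t(params, x)
    probs = _softmax_rows(logits.data)
    if not np.isfinite(probs).all():
        raise FloatingPointError("non-finite activations in forward pass")
    if return_intermediates:
        return probs, {k: v.data for k, v in inter.items()}
    return probs


def feature_map_dump(params: ModelParameters, image: Array, layer: str) -> Array:
    """Return a named intermediate map for a single image."""
    if layer not in LAYER_NAMES:
        raise KeyError(f"unknown layer {layer!r}; known: {LAYER_NAMES}")
    _, inter = forward(params, image, return_intermediates=True)
    out = inter[layer]
    return out[0]


def feature_map_to_image(fmap: Array) -> Array:
    """Normalize each channel of an H×W×C map to [0,255] and tile to a grid."""
    h, w, c = fmap.shape
    cols = int(np.ceil(np.sqrt(c)))
    rows = int(np.ceil(c / cols))
    grid = np.zeros((rows * h, cols * w), dtype=np.uint8)
    for i in range(c):
        ch = fmap[:, :, i]
        lo, hi = ch.min(), ch.max()
        norm = (ch - lo) / (hi - lo) if hi > lo else np.zeros_like(ch)
        r, col = divmod(i, cols)
        grid[r * h : (r + 1) * h, col * w : (col + 1) * w] = (norm * 255).astype(np.uint8)
    return np.repeat(grid[:, :, None], 3, axis=2)


def head_parameter_counts(config: ArchitectureConfig, dense_width: int = 4096) -> tuple[int, int]:
    """Enumerate classifier-head sizes: (GAP head, three-dense VGG-style head).

    The VGG-style head flattens the final 4×4 spatial map and applies three
    dense layers (two of *dense_width*, then the classifier).
    """
    c5, n_out = config.tail_channels, config.n_outputs
    gap_head = c5 * n_out + n_out
    flat = (config.input_side // 8) ** 2 * c5
    dense_head = (
        flat * dense_width + dense_width
        + dense_width * dense_width + dense_width
        + dense_width * n_out + n_out
    )
    return gap_head, dense_head
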