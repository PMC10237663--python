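"""Synthetic field-like pest scenes with known labels and boxes.

The generator emulates the statistical structure of small-pest field
photography — four visually distinct species rendered at varied color,
shape, pose and scale over cluttered green-vegetation backgrounds — so the
whole pipeline (augmentation, training, detection) is exercisable without
any external imagery. The four shape families are deliberate caricatures
(ellipse beetle, segmented larva chain, winged bilobe moth, elongated borer
strip), not biological models: what downstream stages need is four
learnable, mutually distinct classes of small objects on clutter.

Everything is a pure function of its seed: identical settings and seed
give byte-identical images, annotations and manifests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from tscnna.io import (
    BoundingBoxAnnotation,
    DatasetManifest,
    ManifestEntry,
    write_image,
    write_manifest,
    write_voc,
)

Array = np.ndarray

DEFAULT_CLASSES = ("corn_borer", "cabbage_night_moth", "moth_larvae", "cabbage_pest")


@dataclass(frozen=True)
class SpeciesTemplate:
    """Colour/shape/scale description of one synthetic species."""

    species: str
    base_color: tuple[float, float, float]  # RGB mean
    color_spread: float  # per-channel jitter (std, 0–255 scale)
    shape: str  # ellipse | chain | winged | strip
    scale_range: tuple[float, float]  # body length as fraction of image side
    texture_amplitude: float = 0.25

    def __post_init__(self) -> None:
        lo, hi = self.scale_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("scale range must lie within (0, 0.5]")
        if self.shape not in ("ellipse", "chain", "winged", "strip"):
            raise ValueError(f"unknown shape family {self.shape!r}")


DEFAULT_TEMPLATES: dict[str, SpeciesTemplate] = {
    # hue ORDERINGS are kept distinct (r>g>b, r≈g≫b, g>r>b, b>r≈g) so the
    # classes stay separable under multiplicative brightness augmentation
    "corn_borer": SpeciesTemplate(
        "corn_borer", (178, 112, 58), 16.0, "strip", (0.05, 0.25), 0.35
    ),
    "cabbage_night_moth": SpeciesTemplate(
        "cabbage_night_moth", (128, 96, 134), 14.0, "winged", (0.05, 0.25), 0.2
    ),
    "moth_larvae": SpeciesTemplate(
        "moth_larvae", (174, 214, 66), 16.0, "chain", (0.05, 0.25), 0.3
    ),
    "cabbage_pest": SpeciesTemplate(
        "cabbage_pest", (44, 52, 128), 12.0, "ellipse", (0.05, 0.25), 0.15
    ),
}


@dataclass(frozen=True)
class PestPlacement:
    species: str
    center: tuple[int, int]  # (x, y)
    scale: float
    rotation: float  # degrees, [0, 360)
    seed: int


@dataclass(frozen=True)
class SceneSpec:
    side: int
    pests: tuple[PestPlacement, ...]
    background_seed: int
    noise_level: float = 6.0


# ---------------------------------------------------------------------------
# background
# ---------------------------------------------------------------------------


def generate_background(side: int, seed: int) -> Array:
    """Green-dominated cluttered background: low-frequency blotches,
    vein-like streaks and speckle noise. Deterministic given *seed*."""
    if side < 16:
        raise ValueError(f"background side must be >= 16, got {side}")
    rng = np.random.default_rng(seed)
    base = np.empty((side, side, 3))
    centers = (58.0, 118.0, 46.0)
    for c, mean in enumerate(centers):
        coarse = rng.normal(mean, 26.0, size=(side // 8 + 2, side // 8 + 2))
        smooth = gaussian_filter(coarse, sigma=1.2)
        # upsample the coarse field to full resolution
        ys = np.linspace(0, smooth.shape[0] - 1, side)
        xs = np.linspace(0, smooth.shape[1] - 1, side)
        y0 = np.clip(ys.astype(int), 0, smooth.shape[0] - 2)
        x0 = np.clip(xs.astype(int), 0, smooth.shape[1] - 2)
        fy = (ys - y0)[:, None]
        fx = (xs - x0)[None, :]
        base[:, :, c] = (
            smooth[y0][:, x0] * (1 - fy) * (1 - fx)
            + smooth[y0][:, x0 + 1] * (1 - fy) * fx
            + smooth[y0 + 1][:, x0] * fy * (1 - fx)
            + smooth[y0 + 1][:, x0 + 1] * fy * fx
        )
    # vein-like streaks: dark/bright polylines
    yy, xx = np.mgrid[0:side, 0:side]
    for _ in range(max(3, side // 16)):
        x_a, y_a = rng.uniform(0, side, 2)
        angle = rng.uniform(0, np.pi)
        thickness = rng.uniform(0.7, 1.8)
        gain = rng.uniform(-28, 34)
        dist = np.abs(
            np.cos(angle) * (yy - y_a) - np.sin(angle) * (xx - x_a)
        )
        streak = np.exp(-(dist / thickness) ** 2)
        base[:, :, 1] += gain * streak
        base[:, :, 0] += 0.4 * gain * streak
    base += rng.normal(0, 6.0, size=base.shape)  # speckle
    return np.clip(base, 0, 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# pest sprites
# ---------------------------------------------------------------------------


def _shape_mask(shape: str, u: Array, v: Array, half_len: float, rng: np.random.Generator) -> Array:
    """Binary body mask evaluated on body-frame coordinates (u along the axis)."""
    a = half_len
    if shape == "ellipse":
        b = a * rng.uniform(0.6, 0.8)
        return (u / a) ** 2 + (v / b) ** 2 <= 1.0
    if shape == "strip":
        b = a * rng.uniform(0.22, 0.32)
        return (u / a) ** 2 + (v / b) ** 2 <= 1.0
    if shape == "chain":
        nseg = 4
        b = a * rng.uniform(0.28, 0.38)
        seg_r = a / nseg * 1.25
        mask = np.zeros(u.shape, dtype=bool)
        for i in range(nseg):
            cu = -a + (2 * i + 1) * a / nseg
            mask |= ((u - cu) / seg_r) ** 2 + (v / b) ** 2 <= 1.0
        return mask
    if shape == "winged":
        body_b = a * 0.28
        body = (u / (0.75 * a)) ** 2 + (v / body_b) ** 2 <= 1.0
        wing_a, wing_b = 0.62 * a, 0.42 * a
        off = 0.38 * a
        wing1 = ((u + 0.1 * a) / wing_a) ** 2 + ((v - off) / wing_b) ** 2 <= 1.0
        wing2 = ((u + 0.1 * a) / wing_a) ** 2 + ((v + off) / wing_b) ** 2 <= 1.0
        return body | wing1 | wing2
    raise ValueError(shape)


def render_pest(
    template: SpeciesTemplate,
    scale: float,
    rotation: float,
    seed: int,
    side: int = 96,
) -> tuple[Array, Array, tuple[int, int, int, int]]:
    """Render one pest sprite.

    Returns ``(rgb, alpha, (x_min, y_min, x_max, y_max))`` where the box is
    the tight extent of the binary body mask within the sprite canvas, in
    the internal 0-based half-open convention. The sprite canvas is square
    and large enough to hold the body at any rotation.
    """
    lo, hi = template.scale_range
    if not (lo <= scale <= hi):
        raise ValueError(f"scale {scale} outside template range {template.scale_range}")
    rotation = rotation % 360.0
    rng = np.random.default_rng(seed)
    body_len = max(4.0, scale * side)
    canvas = int(np.ceil(body_len * 1.6)) | 1  # odd canvas, rotation head-room
    half = canvas // 2
    yy, xx = np.mgrid[0:canvas, 0:canvas]
    x = xx - half + 0.0
    y = yy - half + 0.0
    theta = np.deg2rad(rotation)
    u = np.cos(theta) * x + np.sin(theta) * y
    v = -np.sin(theta) * x + np.cos(theta) * y
    mask = _shape_mask(template.shape, u, v, body_len / 2.0, rng)
    if not mask.any():
        mask[half, half] = True
    color = np.array(template.base_color) + rng.normal(0, template.color_spread, 3)
    rgb = np.broadcast_to(color, (canvas, canvas, 3)).copy()
    # banded texture along the body axis plus fine noise
    band = 1.0 + template.texture_amplitude * np.sin(u * (2 * np.pi / max(2.0, body_len / 3)))
    rgb *= band[:, :, None]
    rgb += rng.normal(0, 8.0, size=rgb.shape)
    rgb = np.clip(rgb, 0, 255)
    alpha = np.clip(gaussian_filter(mask.astype(float), 0.6), 0, 1)
    alpha[~mask & (alpha < 0.15)] = 0.0
    ys, xs = np.nonzero(mask)
    box = (int(xs.min()), int(ys.min()), int(xs.max()) + 1, int(ys.max()) + 1)
    return rgb, alpha, box


# ---------------------------------------------------------------------------
# scenes
# ---------------------------------------------------------------------------


def compose_scene(
    spec: SceneSpec,
    templates: dict[str, SpeciesTemplate] | None = None,
) -> tuple[Array, list[BoundingBoxAnnotation]]:
    """Composite the placed pests onto a background; one annotation per pest."""
    templates = templates or DEFAULT_TEMPLATES
    img = generate_background(spec.side, spec.background_seed).astype(float)
    annotations: list[BoundingBoxAnnotation] = []
    for pest in spec.pests:
        template = templates[pest.species]
        rgb, alpha, (bx0, by0, bx1, by1) = render_pest(
            template, pest.scale, pest.rotation, pest.seed, side=spec.side
        )
        canvas = rgb.shape[0]
        cx, cy = pest.center
        ox, oy = cx - canvas // 2, cy - canvas // 2
        x0, y0, x1, y1 = ox + bx0, oy + by0, ox + bx1, oy + by1
        if x0 < 0 or y0 < 0 or x1 > spec.side or y1 > spec.side:
            raise ValueError(
                f"pest at {pest.center} (box {(x0, y0, x1, y1)}) falls outside "
                f"the {spec.side}px scene"
            )
        sy0, sx0 = max(0, -oy), max(0, -ox)
        sy1 = min(canvas, spec.side - oy)
        sx1 = min(canvas, spec.side - ox)
        a = alpha[sy0:sy1, sx0:sx1, None]
        region = img[oy + sy0 : oy + sy1, ox + sx0 : ox + sx1]
        region[:] = region * (1 - a) + rgb[sy0:sy1, sx0:sx1] * a
        annotations.append(BoundingBoxAnnotation(pest.species, x0, y0, x1, y1))
    if spec.noise_level > 0:
        rng = np.random.default_rng(spec.background_seed + 1)
        img += rng.normal(0, spec.noise_level, size=img.shape)
    return np.clip(img, 0, 255).astype(np.uint8), annotations


def random_scene_spec(
    rng: np.random.Generator,
    side: int,
    classes: tuple[str, ...],
    n_pests: tuple[int, int] = (1, 3),
    templates: dict[str, SpeciesTemplate] | None = None,
    species: str | None = None,
) -> SceneSpec:
    """Draw a valid scene specification from the default distributions."""
    templates = templates or DEFAULT_TEMPLATES
    count = int(rng.integers(n_pests[0], n_pests[1] + 1))
    pests = []
    for _ in range(count):
        sp = species if species is not None else str(rng.choice(list(classes)))
        lo, hi = templates[sp].scale_range
        scale = float(rng.uniform(lo, hi))
        body = max(4.0, scale * side)
        margin = int(np.ceil(body * 0.85)) + 2  # canvas half-extent head-room
        margin = min(margin, side // 2 - 1)
        cx = int(rng.integers(margin, side - margin))
        cy = int(rng.integers(margin, side - margin))
        pests.append(
            PestPlacement(
                species=sp,
                center=(cx, cy),
                scale=scale,
                rotation=float(rng.uniform(0, 360)),
                seed=int(rng.integers(0, 2**31)),
            )
        )
    return SceneSpec(
        side=side,
        pests=tuple(pests),
        background_seed=int(rng.integers(0, 2**31)),
    )


# ---------------------------------------------------------------------------
# dataset generation
# ---------------------------------------------------------------------------


@dataclass
class GeneratorConfig:
    classes: tuple[str, ...] = DEFAULT_CLASSES
    per_class: int = 250
    side: int = 96
    seed: int = 0
    pests_per_scene: tuple[int, int] = (1, 1)  # single pest: classification set
    templates: dict[str, SpeciesTemplate] = field(
        default_factory=lambda: dict(DEFAULT_TEMPLATES)
    )

    def __post_init__(self) -> None:
        if self.per_class < 1:
            raise ValueError("per-class count must be >= 1")


def generate_dataset(out_dir: str | Path, config: GeneratorConfig | None = None) -> DatasetManifest:
    """Write ``per_class`` scenes per species (PNG + VOC XML) and a manifest.

    With the defaults this is 4 × 250 = 1000 original images. Fully
    deterministic given the seed.
    """
    config = config or GeneratorConfig()
    out_dir = Path(out_dir)
    if not out_dir.exists():
        raise FileNotFoundError(f"output directory does not exist: {out_dir}")
    rng = np.random.default_rng(config.seed)
    entries: list[ManifestEntry] = []
    for species in config.classes:
        for i in range(config.per_class):
            spec = random_scene_spec(
                rng, config.side, config.classes,
                n_pests=config.pests_per_scene,
                templates=config.templates, species=species,
            )
            image, boxes = compose_scene(spec, config.templates)
            stem = f"{species}_{i:04d}"
            write_image(out_dir / f"{stem}.png", image)
            write_voc(out_dir / f"{stem}.xml", boxes, config.side, config.side,
                      image_filename=f"{stem}.png")
            entries.append(
                ManifestEntry(
                    image_path=f"{stem}.png",
                    species=species,
                    boxes=tuple(boxes),
                    provenance="original",
                    source_id=stem,
                )
            )
    manifest = DatasetManifest(classes=config.classes, entries=entries, root=out_dir)
    write_manifest(out_dir / "manifest.json", manifest)
    return manifest


def class_separability(image: Array, boxes: list[BoundingBoxAnnotation]) -> float:
    """Euclidean distance between mean colour inside boxes and outside them."""
    img = np.asarray(image, dtype=float)
    mask = np.zeros(img.shape[:2], dtype=bool)
    for b in boxes:
        mask[b.y_min : b.y_max, b.x_min : b.x_max] = True
    if not mask.any() or mask.all():
        return 0.0
    inside = img[mask].mean(axis=0)
    outside = img[~mask].mean(axis=0)
    return float(np.linalg.norm(inside - outside))
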