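"""The seven-kind augmentation policy: exactly 20 variants per original.

Kinds: translation, rotation (multiples of 90°), mirroring, Gaussian blur,
brightness change, clipping (corner crops resized back), and zooming.
The fixed 20-recipe menu is:

* 3 rotations (90, 180, 270),
* 2 mirrors (horizontal, vertical),
* 4 translations (±10 % along each axis),
* 2 brightness factors (0.7, 1.3),
* 2 Gaussian blurs (σ = 1, σ = 2),
* 4 corner crops of 80 % area, resized back to the original size,
* 3 centre-anchored zooms (0.8, 1.1, 1.25).

Geometric transforms move the annotation boxes with the pixels; boxes are
clipped to the frame and dropped when less than 25 % of their original
area survives. Photometric transforms (blur, brightness) leave boxes
untouched. Every original yields exactly 20 augmented entries, so a
1000-image original set becomes a 21,000-image dataset (20 variants per
original, 5,000 augmented images per species at 250 originals each).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.transform import resize as _sk_resize

from tscnna.io import (
    BoundingBoxAnnotation,
    DatasetManifest,
    ManifestEntry,
    read_image,
    write_image,
    write_manifest,
    write_voc,
)

Array = np.ndarray

KINDS = ("translate", "rotate", "mirror", "blur", "brightness", "crop", "zoom")

MIN_BOX_AREA_FRACTION = 0.25


@dataclass(frozen=True)
class TransformSpec:
    kind: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown transform kind {self.kind!r}")
        p = self.params
        if self.kind == "rotate" and p.get("angle", 0) % 90 != 0:
            raise ValueError("rotation supports multiples of 90 degrees")
        if self.kind == "brightness" and not (0.5 <= p.get("factor", 1.0) <= 1.5):
            raise ValueError("brightness factor must be in [0.5, 1.5]")
        if self.kind == "zoom" and not (0.7 <= p.get("factor", 1.0) <= 1.4):
            raise ValueError("zoom factor must be in [0.7, 1.4]")
        if self.kind == "mirror" and p.get("axis") not in ("horizontal", "vertical"):
            raise ValueError("mirror axis must be horizontal or vertical")


def default_policy() -> list[TransformSpec]:
    """The fixed 20-recipe menu covering all seven kinds."""
    policy = [
        TransformSpec("rotate", {"angle": 90}),
        TransformSpec("rotate", {"angle": 180}),
        TransformSpec("rotate", {"angle": 270}),
        TransformSpec("mirror", {"axis": "horizontal"}),
        TransformSpec("mirror", {"axis": "vertical"}),
        TransformSpec("translate", {"dx": 0.1, "dy": 0.0}),
        TransformSpec("translate", {"dx": -0.1, "dy": 0.0}),
        TransformSpec("translate", {"dx": 0.0, "dy": 0.1}),
        TransformSpec("translate", {"dx": 0.0, "dy": -0.1}),
        TransformSpec("brightness", {"factor": 0.7}),
        TransformSpec("brightness", {"factor": 1.3}),
        TransformSpec("blur", {"sigma": 1.0}),
        TransformSpec("blur", {"sigma": 2.0}),
        TransformSpec("crop", {"corner": "tl", "area": 0.8}),
        TransformSpec("crop", {"corner": "tr", "area": 0.8}),
        TransformSpec("crop", {"corner": "bl", "area": 0.8}),
        TransformSpec("crop", {"corner": "br", "area": 0.8}),
        TransformSpec("zoom", {"factor": 0.8}),
        TransformSpec("zoom", {"factor": 1.1}),
        TransformSpec("zoom", {"factor": 1.25}),
    ]
    validate_policy(policy)
    return policy


def validate_policy(policy: Sequence[TransformSpec]) -> None:
    if len(policy) != 20:
        raise ValueError(f"policy must contain exactly 20 recipes, got {len(policy)}")
    present = {spec.kind for spec in policy}
    missing = set(KINDS) - present
    if missing:
        raise ValueError(f"policy missing transform kinds: {sorted(missing)}")


# ---------------------------------------------------------------------------
# box helpers
# ---------------------------------------------------------------------------


def _clip_box(
    species: str, x0: float, y0: float, x1: float, y1: float,
    width: int, height: int, original_area: float,
) -> BoundingBoxAnnotation | None:
    x0c, y0c = max(0.0, x0), max(0.0, y0)
    x1c, y1c = min(float(width), x1), min(float(height), y1)
    xi0, yi0 = int(round(x0c)), int(round(y0c))
    xi1, yi1 = int(round(x1c)), int(round(y1c))
    if xi1 <= xi0 or yi1 <= yi0:
        return None
    if (xi1 - xi0) * (yi1 - yi0) < MIN_BOX_AREA_FRACTION * original_area:
        return None
    return BoundingBoxAnnotation(species, xi0, yi0, xi1, yi1)


def _resize_uint8(image: Array, out_h: int, out_w: int) -> Array:
    out = _sk_resize(
        image.astype(float), (out_h, out_w), order=1,
        preserve_range=True, anti_aliasing=False,
    )
    return np.clip(np.round(out), 0, 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# single transforms
# ---------------------------------------------------------------------------


def apply_transform(
    image: Array,
    boxes: Sequence[BoundingBoxAnnotation],
    spec: TransformSpec,
) -> tuple[Array, list[BoundingBoxAnnotation]]:
    """Apply one transform to an image and its boxes."""
    image = np.asarray(image)
    h, w = image.shape[:2]
    kind, p = spec.kind, spec.params

    if kind == "brightness":
        out = np.clip(image.astype(float) * p["factor"], 0, 255).astype(np.uint8)
        return out, list(boxes)

    if kind == "blur":
        out = np.empty_like(image)
        for c in range(image.shape[2]):
            out[:, :, c] = np.clip(
                gaussian_filter(image[:, :, c].astype(float), p["sigma"]), 0, 255
            ).astype(np.uint8)
        return out, list(boxes)

    if kind == "mirror":
        if p["axis"] == "horizontal":  # flip left-right
            out = image[:, ::-1].copy()
            new = [
                BoundingBoxAnnotation(b.species, w - b.x_max, b.y_min, w - b.x_min, b.y_max)
                for b in boxes
            ]
        else:
            out = image[::-1].copy()
            new = [
                BoundingBoxAnnotation(b.species, b.x_min, h - b.y_max, b.x_max, h - b.y_min)
                for b in boxes
            ]
        return out, new

    if kind == "rotate":
        k = (p["angle"] // 90) % 4
        out = np.ascontiguousarray(np.rot90(image, k))
        new = list(boxes)
        hh, ww = h, w
        for _ in range(k):
            # one 90° CCW step on a ww×hh image: (x, y) -> (y, ww - x)
            new = [
                BoundingBoxAnnotation(b.species, b.y_min, ww - b.x_max, b.y_max, ww - b.x_min)
                for b in new
            ]
            hh, ww = ww, hh
        return out, new

    if kind == "translate":
        dx = int(round(p["dx"] * w)) if abs(p["dx"]) < 1 else int(p["dx"])
        dy = int(round(p["dy"] * h)) if abs(p["dy"]) < 1 else int(p["dy"])
        out = np.zeros_like(image)
        src_y = slice(max(0, -dy), min(h, h - dy))
        src_x = slice(max(0, -dx), min(w, w - dx))
        dst_y = slice(max(0, dy), min(h, h + dy))
        dst_x = slice(max(0, dx), min(w, w + dx))
        out[dst_y, dst_x] = image[src_y, src_x]
        # edge-replicate the exposed strips so no hard black border appears
        if dy > 0:
            out[:dy] = out[dy : dy + 1]
        elif dy < 0:
            out[h + dy :] = out[h + dy - 1 : h + dy]
        if dx > 0:
            out[:, :dx] = out[:, dx : dx + 1]
        elif dx < 0:
            out[:, w + dx :] = out[:, w + dx - 1 : w + dx]
        new = []
        for b in boxes:
            nb = _clip_box(
                b.species, b.x_min + dx, b.y_min + dy, b.x_max + dx, b.y_max + dy,
                w, h, b.area,
            )
            if nb is not None:
                new.append(nb)
        return out, new

    if kind == "crop":
        frac = float(np.sqrt(p.get("area", 0.8)))
        cw, ch = int(round(w * frac)), int(round(h * frac))
        corner = p["corner"]
        x_off = 0 if corner in ("tl", "bl") else w - cw
        y_off = 0 if corner in ("tl", "tr") else h - ch
        if cw < 1 or ch < 1 or x_off < 0 or y_off < 0:
            raise ValueError("crop window outside image")
        window = image[y_off : y_off + ch, x_off : x_off + cw]
        out = _resize_uint8(window, h, w)
        sx, sy = w / cw, h / ch
        new = []
        for b in boxes:
            nb = _clip_box(
                b.species,
                (b.x_min - x_off) * sx, (b.y_min - y_off) * sy,
                (b.x_max - x_off) * sx, (b.y_max - y_off) * sy,
                w, h, b.area * sx * sy,
            )
            if nb is not None:
                new.append(nb)
        return out, new

    if kind == "zoom":
        z = p["factor"]
        zh, zw = max(1, int(round(h * z))), max(1, int(round(w * z)))
        scaled = _resize_uint8(image, zh, zw)
        zy, zx = zh / h, zw / w  # effective factors after rounding
        if z >= 1.0:
            oy, ox = (zh - h) // 2, (zw - w) // 2
            out = scaled[oy : oy + h, ox : ox + w]
            shift_x, shift_y = -ox, -oy
        else:
            oy, ox = (h - zh) // 2, (w - zw) // 2
            out = np.zeros_like(image)
            out[oy : oy + zh, ox : ox + zw] = scaled
            out[:oy] = out[oy : oy + 1]
            out[oy + zh :] = out[oy + zh - 1 : oy + zh]
            out[:, :ox] = out[:, ox : ox + 1]
            out[:, ox + zw :] = out[:, ox + zw - 1 : ox + zw]
            shift_x, shift_y = ox, oy
        new = []
        for b in boxes:
            nb = _clip_box(
                b.species,
                b.x_min * zx + shift_x, b.y_min * zy + shift_y,
                b.x_max * zx + shift_x, b.y_max * zy + shift_y,
                w, h, b.area * zx * zy,
            )
            if nb is not None:
                new.append(nb)
        return np.ascontiguousarray(out), new

    raise ValueError(f"unknown transform kind {kind!r}")  # pragma: no cover


# ---------------------------------------------------------------------------
# per-image and per-dataset expansion
# ---------------------------------------------------------------------------


def augment_image(
    image: Array,
    boxes: Sequence[BoundingBoxAnnotation],
    policy: Sequence[TransformSpec] | None = None,
    seed: int = 0,
) -> list[tuple[Array, list[BoundingBoxAnnotation]]]:
    """Exactly 20 (image, boxes) variants; labels preserved; deterministic."""
    policy = list(policy) if policy is not None else default_policy()
    validate_policy(policy)
    return [apply_transform(image, boxes, spec) for spec in policy]


def augment_dataset(
    manifest: DatasetManifest,
    out_dir: str | Path,
    policy: Sequence[TransformSpec] | None = None,
    seed: int = 0,
) -> DatasetManifest:
    """Expand an all-original manifest 21-fold (originals ∪ 20 variants each).

    Augmented images and their VOC annotations are written under *out_dir*;
    each augmented entry records its source image's identifier so that
    cross-validation can split by source and keep augmented copies of a
    test image out of the training fold.
    """
    if any(e.provenance != "original" for e in manifest.entries):
        raise ValueError("manifest already contains augmented entries; refusing to expand twice")
    policy = list(policy) if policy is not None else default_policy()
    validate_policy(policy)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    new_entries: list[ManifestEntry] = list(manifest.entries)
    for entry in manifest.entries:
        image = read_image(manifest.root / entry.image_path)
        h, w = image.shape[:2]
        variants = augment_image(image, list(entry.boxes), policy, seed)
        stem = Path(entry.image_path).stem
        for vi, (vimg, vboxes) in enumerate(variants):
            vname = f"{stem}_aug{vi:02d}"
            vh, vw = vimg.shape[:2]
            write_image(out_dir / f"{vname}.png", vimg)
            write_voc(out_dir / f"{vname}.xml", vboxes, vw, vh,
                      image_filename=f"{vname}.png")
            rel = str((out_dir / f"{vname}.png").relative_to(manifest.root)) \
                if out_dir.is_relative_to(manifest.root) else str(out_dir / f"{vname}.png")
            new_entries.append(
                ManifestEntry(
                    image_path=rel,
                    species=entry.species,
                    boxes=tuple(vboxes),
                    provenance="augmented",
                    source_id=entry.source_id,
                )
            )
    out = DatasetManifest(manifest.classes, new_entries, manifest.root)
    out.validate()
    return out
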