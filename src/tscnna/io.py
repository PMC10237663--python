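"""Raster images, labelImg/Pascal-VOC annotations, and dataset manifests.

Coordinate conventions
----------------------
Internally every bounding box is 0-based and half-open: a box covers pixel
columns ``x_min .. x_max-1``, so ``width = x_max - x_min`` with no off-by-one.
Pascal VOC XML (the dialect labelImg writes) is 1-based and inclusive; the
conversion ``xmin_voc = x_min + 1, xmax_voc = x_max`` happens only at the
file boundary, in :func:`read_voc` / :func:`write_voc`.

The manifest is a single JSON document (schema version ``tscnna-manifest/1``)
so a generated or augmented dataset is self-describing: every entry records
its image path (relative to the manifest file), species label, boxes,
provenance (original vs augmented), the identifier of its source image, and
an optional cross-validation fold index.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from lxml import etree
from PIL import Image

logger = logging.getLogger("tscnna")

MANIFEST_FORMAT = "tscnna-manifest/1"


class AnnotationError(ValueError):
    """Raised for malformed or inconsistent annotations/manifests."""


# ---------------------------------------------------------------------------
# bounding boxes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BoundingBoxAnnotation:
    """A species label plus an axis-aligned box, 0-based half-open."""

    species: str
    x_min: int
    y_min: int
    x_max: int
    y_max: int

    def __post_init__(self) -> None:
        if not (self.x_min < self.x_max and self.y_min < self.y_max):
            raise AnnotationError(
                f"degenerate box {(self.x_min, self.y_min, self.x_max, self.y_max)}"
            )
        if self.x_min < 0 or self.y_min < 0:
            raise AnnotationError("box coordinates must be non-negative")

    @property
    def width(self) -> int:
        return self.x_max - self.x_min

    @property
    def height(self) -> int:
        return self.y_max - self.y_min

    @property
    def area(self) -> int:
        return self.width * self.height

    def validate_within(self, width: int, height: int) -> None:
        if self.x_max > width or self.y_max > height:
            raise AnnotationError(
                f"box {(self.x_min, self.y_min, self.x_max, self.y_max)} "
                f"exceeds image {width}x{height}"
            )


# ---------------------------------------------------------------------------
# raster image I/O
# ---------------------------------------------------------------------------


def _as_rgb_array(img: Image.Image, path: Path) -> np.ndarray:
    if img.mode in ("L", "I;16"):
        img = img.convert("L").convert("RGB")  # replicate grayscale
    elif img.mode != "RGB":
        try:
            img = img.convert("RGB")
        except Exception as exc:  # pragma: no cover - codec oddities
            raise AnnotationError(f"cannot convert {path} to 3-channel RGB") from exc
    arr = np.asarray(img, dtype=np.uint8)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise AnnotationError(f"{path}: expected 3-channel image, got shape {arr.shape}")
    return arr


def read_image(path: str | Path) -> np.ndarray:
    """Read a PNG/JPEG file as an H×W×3 uint8 array (grayscale replicated)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image file not found: {path}")
    try:
        with Image.open(path) as img:
            return _as_rgb_array(img, path)
    except FileNotFoundError:
        raise
    except AnnotationError:
        raise
    except Exception as exc:
        raise AnnotationError(f"cannot decode image {path}: {exc}") from exc


def write_image(path: str | Path, pixels: np.ndarray) -> None:
    """Write an H×W×3 uint8 array as PNG (lossless) or JPEG by extension."""
    path = Path(path)
    pixels = np.asarray(pixels)
    if pixels.ndim != 3 or pixels.shape[2] != 3 or pixels.dtype != np.uint8:
        raise AnnotationError(
            f"expected H×W×3 uint8 pixels for {path}, got {pixels.shape} {pixels.dtype}"
        )
    if not path.parent.exists():
        raise FileNotFoundError(f"output directory does not exist: {path.parent}")
    Image.fromarray(pixels).save(path)


# ---------------------------------------------------------------------------
# Pascal VOC XML (labelImg dialect)
# ---------------------------------------------------------------------------


def write_voc(
    path: str | Path,
    boxes: Sequence[BoundingBoxAnnotation],
    width: int,
    height: int,
    image_filename: str = "",
) -> None:
    """Write boxes as labelImg-style Pascal VOC XML (1-based inclusive)."""
    path = Path(path)
    root = etree.Element("annotation")
    etree.SubElement(root, "filename").text = image_filename or path.stem
    size = etree.SubElement(root, "size")
    etree.SubElement(size, "width").text = str(width)
    etree.SubElement(size, "height").text = str(height)
    etree.SubElement(size, "depth").text = "3"
    for box in boxes:
        box.validate_within(width, height)
        obj = etree.SubElement(root, "object")
        etree.SubElement(obj, "name").text = box.species
        bnd = etree.SubElement(obj, "bndbox")
        etree.SubElement(bnd, "xmin").text = str(box.x_min + 1)
        etree.SubElement(bnd, "ymin").text = str(box.y_min + 1)
        etree.SubElement(bnd, "xmax").text = str(box.x_max)
        etree.SubElement(bnd, "ymax").text = str(box.y_max)
    path.write_bytes(etree.tostring(root, pretty_print=True, xml_declaration=False))


def read_voc(
    path: str | Path,
    known_classes: Sequence[str] | None = None,
) -> tuple[list[BoundingBoxAnnotation], int, int]:
    """Read a Pascal VOC XML file.

    Returns ``(boxes, width, height)`` with boxes converted back to the
    internal 0-based half-open convention. If *known_classes* is given,
    an unknown ``object/name`` is rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"annotation file not found: {path}")
    try:
        root = etree.parse(str(path)).getroot()
    except etree.XMLSyntaxError as exc:
        raise AnnotationError(f"malformed XML in {path}: {exc}") from exc
    size = root.find("size")
    if size is None:
        raise AnnotationError(f"{path}: missing <size> element")
    width = int(size.findtext("width"))
    height = int(size.findtext("height"))
    boxes: list[BoundingBoxAnnotation] = []
    for obj in root.findall("object"):
        name = obj.findtext("name")
        if known_classes is not None and name not in known_classes:
            raise AnnotationError(f"{path}: unknown class {name!r}")
        bnd = obj.find("bndbox")
        xmin = int(round(float(bnd.findtext("xmin"))))
        ymin = int(round(float(bnd.findtext("ymin"))))
        xmax = int(round(float(bnd.findtext("xmax"))))
        ymax = int(round(float(bnd.findtext("ymax"))))
        box = BoundingBoxAnnotation(name, xmin - 1, ymin - 1, xmax, ymax)
        box.validate_within(width, height)
        boxes.append(box)
    return boxes, width, height


# ---------------------------------------------------------------------------
# dataset manifest
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ManifestEntry:
    image_path: str  # relative to the manifest location
    species: str
    boxes: tuple[BoundingBoxAnnotation, ...]
    provenance: str  # "original" | "augmented"
    source_id: str  # identifier of the source image (== own id for originals)
    fold: int | None = None

    def __post_init__(self) -> None:
        if self.provenance not in ("original", "augmented"):
            raise AnnotationError(f"bad provenance {self.provenance!r}")


@dataclass
class DatasetManifest:
    """Ordered record of a dataset: images, labels, boxes, provenance, folds."""

    classes: tuple[str, ...]
    entries: list[ManifestEntry] = field(default_factory=list)
    root: Path = Path(".")

    def validate(self) -> None:
        seen: set[str] = set()
        for e in self.entries:
            if e.image_path in seen:
                raise AnnotationError(f"duplicate image path {e.image_path!r}")
            seen.add(e.image_path)
            if e.species not in self.classes:
                raise AnnotationError(f"unknown species {e.species!r}")
            for b in e.boxes:
                if b.species not in self.classes:
                    raise AnnotationError(f"unknown box species {b.species!r}")

    def per_class_counts(self) -> dict[str, int]:
        counts = {c: 0 for c in self.classes}
        for e in self.entries:
            counts[e.species] += 1
        return counts

    def originals(self) -> list[ManifestEntry]:
        return [e for e in self.entries if e.provenance == "original"]

    def with_entries(self, entries: Iterable[ManifestEntry]) -> "DatasetManifest":
        return DatasetManifest(self.classes, list(entries), self.root)


def _entry_to_dict(e: ManifestEntry) -> dict:
    return {
        "image": e.image_path,
        "species": e.species,
        "boxes": [[b.species, b.x_min, b.y_min, b.x_max, b.y_max] for b in e.boxes],
        "provenance": e.provenance,
        "source_id": e.source_id,
        "fold": e.fold,
    }


def _entry_from_dict(d: dict) -> ManifestEntry:
    return ManifestEntry(
        image_path=d["image"],
        species=d["species"],
        boxes=tuple(BoundingBoxAnnotation(s, x0, y0, x1, y1) for s, x0, y0, x1, y1 in d["boxes"]),
        provenance=d["provenance"],
        source_id=d["source_id"],
        fold=d["fold"],
    )


def write_manifest(path: str | Path, manifest: DatasetManifest) -> None:
    manifest.validate()
    path = Path(path)
    doc = {
        "format": MANIFEST_FORMAT,
        "classes": list(manifest.classes),
        "entries": [_entry_to_dict(e) for e in manifest.entries],
    }
    path.write_text(json.dumps(doc, indent=1, sort_keys=False) + "\n")


def read_manifest(path: str | Path) -> DatasetManifest:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"manifest not found: {path}")
    doc = json.loads(path.read_text())
    if doc.get("format") != MANIFEST_FORMAT:
        raise AnnotationError(f"{path}: unsupported manifest format {doc.get('format')!r}")
    manifest = DatasetManifest(
        classes=tuple(doc["classes"]),
        entries=[_entry_from_dict(d) for d in doc["entries"]],
        root=path.parent,
    )
    manifest.validate()
    return manifest


def assign_folds(manifest: DatasetManifest, fold_of_source: dict[str, int]) -> DatasetManifest:
    """Return a copy with each entry's fold set by its source image id."""
    return manifest.with_entries(
        replace(e, fold=fold_of_source[e.source_id]) for e in manifest.entries
    )
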