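"""Sliding-window pest detection.

The four-step procedure: (1) scan the image with windows of several scales,
(2) normalize every candidate window to the classifier's input side (32×32)
by bilinear interpolation, (3) classify the normalized crops with the
trained network, (4) delete windows judged non-pest. Greedy per-class
non-maximum suppression is applied afterwards, since every pest would
otherwise be reported by many overlapping windows.

The default window geometry is a 1.5× scale ladder (8, 12, 18, 27 px)
at stride fraction 0.25. Two boxes can only agree at IoU ≥ 0.3 when their
areas are within ~3× of each other, so the ladder has to bracket the
object sizes actually present (small pests at roughly 5–25 % of a 96-px
scene): the 8-px rung makes boxes down to √0.3 × 8 ≈ 4.4 px matchable,
which the generator's smallest pests require. Such tiny windows are only
usable because the classifier's background class is trained on crops of
the same sizes. The score threshold defaults to 0.8 — near-featureless
small windows attract moderate-confidence false alarms that a bare 0.5
cut admits — and the suppression threshold is deliberately low (0.05):
duplicate windows of one object across scales and offsets overlap each
other at IoU 0.05–0.3, so a conventional 0.3 threshold cannot reduce them
to the single detection per object that one-to-one matching assumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from tscnna.attention import bilinear_resize
from tscnna.io import BoundingBoxAnnotation
from tscnna.model import ModelParameters, forward

Array = np.ndarray


@dataclass(frozen=True)
class CandidateWindow:
    x_min: int
    y_min: int
    x_max: int
    y_max: int
    scale_index: int


@dataclass(frozen=True)
class Detection:
    box: BoundingBoxAnnotation
    score: float

    def __post_init__(self) -> None:
        if not (0.0 < self.score < 1.0):
            raise ValueError("score must be in (0, 1)")


@dataclass
class DetectionConfig:
    scales: tuple[int, ...] = (8, 12, 18, 27)
    aspect_ratios: tuple[float, ...] = (1.0,)
    stride_fraction: float = 0.25
    score_threshold: float = 0.8
    nms_iou: float = 0.05
    input_side: int = 32
    apply_nms: bool = True
    refine_boxes: bool = True  # cluster-average the surviving window boxes

    def __post_init__(self) -> None:
        if not (0.0 < self.stride_fraction <= 1.0):
            raise ValueError("stride fraction must be in (0, 1]")
        if not (0.0 < self.score_threshold < 1.0 and 0.0 < self.nms_iou < 1.0):
            raise ValueError("thresholds must be in (0, 1)")


# ---------------------------------------------------------------------------
# step 1: window proposal
# ---------------------------------------------------------------------------


def _starts(extent: int, scale: int, step: int) -> list[int]:
    starts = list(range(0, extent - scale + 1, step))
    if starts[-1] != extent - scale:  # flush final window to the edge
        starts.append(extent - scale)
    return starts


def propose_windows(
    height: int, width: int, scales: tuple[int, ...], stride_fraction: float,
    aspects: tuple[float, ...] = (1.0,),
) -> list[CandidateWindow]:
    """Multi-scale grid of windows covering the whole image at each scale.

    *aspects* adds width:height variants at each scale (area preserved):
    elongated bodies cannot reach IoU 0.3 against any square window once
    their aspect passes ~1:5, so the scan needs anisotropic windows to
    localize them.
    """
    windows: list[CandidateWindow] = []
    for si, s in enumerate(scales):
        if s > min(height, width):
            raise ValueError(f"scale {s} exceeds image {width}x{height}")
        for aspect in aspects:
            w = min(width, max(4, round(s * np.sqrt(aspect))))
            h = min(height, max(4, round(s / np.sqrt(aspect))))
            step_x = max(1, round(stride_fraction * w))
            step_y = max(1, round(stride_fraction * h))
            for y in _starts(height, h, step_y):
                for x in _starts(width, w, step_x):
                    windows.append(CandidateWindow(x, y, x + w, y + h, si))
    return windows


def window_grid_count(extent: int, scale: int, step: int) -> int:
    """Closed-form count of start positions along one axis (with flush edge)."""
    n = (extent - scale) // step + 1
    if (extent - scale) % step != 0:
        n += 1
    return n


# ---------------------------------------------------------------------------
# step 2: normalization
# ---------------------------------------------------------------------------


def normalize_window(image: Array, box: CandidateWindow | tuple[int, int, int, int],
                     side: int = 32) -> Array:
    """Crop a box and bilinearly resize it to side×side (identity if already)."""
    if isinstance(box, CandidateWindow):
        x0, y0, x1, y1 = box.x_min, box.y_min, box.x_max, box.y_max
    else:
        x0, y0, x1, y1 = box
    if x1 <= x0 or y1 <= y0:
        raise ValueError("empty box")
    crop = np.asarray(image, dtype=float)[y0:y1, x0:x1]
    if crop.shape[0] == side and crop.shape[1] == side:
        return crop
    return bilinear_resize(crop, side, side)


# ---------------------------------------------------------------------------
# step 3: classification
# ---------------------------------------------------------------------------


def _resize_batch(crops: Array, side: int) -> Array:
    """Bilinear resize of a stack of same-sized crops (N,h,w,3) to (N,side,side,3)."""
    n, h, w = crops.shape[:3]
    if h == side and w == side:
        return crops.astype(float)
    f = crops.astype(float)

    def grid(n_out: int, n_in: int):
        src = np.clip((np.arange(n_out) + 0.5) * (n_in / n_out) - 0.5, 0, n_in - 1)
        lo = np.floor(src).astype(int)
        return lo, np.minimum(lo + 1, n_in - 1), src - lo

    ylo, yhi, wy = grid(side, h)
    xlo, xhi, wx = grid(side, w)
    wy = wy[None, :, None, None]
    wx = wx[None, None, :, None]
    top = f[:, ylo][:, :, xlo] * (1 - wx) + f[:, ylo][:, :, xhi] * wx
    bot = f[:, yhi][:, :, xlo] * (1 - wx) + f[:, yhi][:, :, xhi] * wx
    return top * (1 - wy) + bot * wy


def classify_windows(
    params: ModelParameters, image: Array, windows: list[CandidateWindow],
    side: int = 32, batch_size: int = 64,
) -> Array:
    """Probability rows for every window, in window order."""
    if not windows:
        return np.zeros((0, params.config.n_outputs))
    image = np.asarray(image)
    crops = np.empty((len(windows), side, side, 3), dtype=np.float32)
    # group same-sized windows so each group is resized in one vector pass
    by_size: dict[tuple[int, int], list[int]] = {}
    for i, w in enumerate(windows):
        by_size.setdefault((w.y_max - w.y_min, w.x_max - w.x_min), []).append(i)
    for (h, w_), idxs in by_size.items():
        stack = np.stack(
            [image[windows[i].y_min : windows[i].y_max,
                   windows[i].x_min : windows[i].x_max] for i in idxs]
        )
        crops[idxs] = _resize_batch(stack, side).astype(np.float32)
    crops /= 255.0
    rows = [
        forward(params, crops[i : i + batch_size])
        for i in range(0, len(crops), batch_size)
    ]
    return np.concatenate(rows, axis=0)


# ---------------------------------------------------------------------------
# step 4: filtering + suppression
# ---------------------------------------------------------------------------


def iou(a: tuple[int, int, int, int], b: tuple[int, int, int, int]) -> float:
    ix0, iy0 = max(a[0], b[0]), max(a[1], b[1])
    ix1, iy1 = min(a[2], b[2]), min(a[3], b[3])
    inter = max(0, ix1 - ix0) * max(0, iy1 - iy0)
    if inter == 0:
        return 0.0
    area_a = (a[2] - a[0]) * (a[3] - a[1])
    area_b = (b[2] - b[0]) * (b[3] - b[1])
    return inter / (area_a + area_b - inter)


def filter_and_suppress(
    windows: list[CandidateWindow],
    probabilities: Array,
    classes: tuple[str, ...],
    background_index: int | None,
    score_threshold: float = 0.5,
    iou_threshold: float = 0.3,
    apply_nms: bool = True,
    refine_boxes: bool = False,
) -> list[Detection]:
    """Drop background / low-score windows, then greedy per-class NMS.

    With *refine_boxes*, each surviving window's box is replaced by the
    score-weighted average of the candidate windows it suppressed (its
    cluster): single windows are coarse — their corners sit on the scale
    ladder and stride grid — while the cluster mean localizes the object
    it collectively fired on considerably better.
    """
    candidates: list[tuple[int, float, CandidateWindow]] = []
    for w, row in zip(windows, probabilities):
        top = int(np.argmax(row))
        if background_index is not None and top == background_index:
            continue
        # float32 softmax can round to exactly 1.0; keep scores in (0, 1)
        score = min(float(row[top]), float(np.nextafter(1.0, 0.0)))
        if score < score_threshold:
            continue
        candidates.append((top, score, w))
    kept: list[Detection] = []
    for cls_idx in sorted({c for c, _, _ in candidates}):
        pool = sorted(
            (c for c in candidates if c[0] == cls_idx), key=lambda c: -c[1]
        )
        chosen: list[tuple[int, float, CandidateWindow]] = []
        clusters: list[list[tuple[float, CandidateWindow]]] = []
        for cand in pool:
            box = (cand[2].x_min, cand[2].y_min, cand[2].x_max, cand[2].y_max)
            suppressor = None
            if apply_nms:
                for ki, k in enumerate(chosen):
                    if iou(box, (k[2].x_min, k[2].y_min, k[2].x_max, k[2].y_max)) >= iou_threshold:
                        suppressor = ki
                        break
            if suppressor is not None:
                clusters[suppressor].append((cand[1], cand[2]))
                continue
            chosen.append(cand)
            clusters.append([(cand[1], cand[2])])
        for (cls, score, w), cluster in zip(chosen, clusters):
            if refine_boxes and len(cluster) > 1:
                weights = np.array([s for s, _ in cluster])
                corners = np.array(
                    [[cw.x_min, cw.y_min, cw.x_max, cw.y_max] for _, cw in cluster]
                )
                x0, y0, x1, y1 = np.round(
                    (weights[:, None] * corners).sum(axis=0) / weights.sum()
                ).astype(int)
            else:
                x0, y0, x1, y1 = w.x_min, w.y_min, w.x_max, w.y_max
            kept.append(
                Detection(BoundingBoxAnnotation(classes[cls], x0, y0, x1, y1), score)
            )
    kept.sort(key=lambda d: -d.score)
    return kept


def detect(params: ModelParameters, image: Array,
           config: DetectionConfig | None = None) -> list[Detection]:
    """Full pipeline: propose → normalize → classify → filter/suppress."""
    config = config or DetectionConfig(input_side=params.config.input_side)
    image = np.asarray(image)
    h, w = image.shape[:2]
    scales = tuple(s for s in config.scales if s <= min(h, w))
    if not scales:
        raise ValueError("no window scale fits the image")
    windows = propose_windows(h, w, scales, config.stride_fraction, config.aspect_ratios)
    probs = classify_windows(params, image, windows, side=config.input_side)
    bg = params.config.background_index if params.config.include_background else None
    classes_full = tuple(f"class_{i}" for i in range(params.config.n_outputs))
    return filter_and_suppress(
        windows, probs, classes_full, bg,
        config.score_threshold, config.nms_iou, config.apply_nms,
        config.refine_boxes,
    )


def detect_with_classes(
    params: ModelParameters, image: Array, classes: tuple[str, ...],
    config: DetectionConfig | None = None,
) -> list[Detection]:
    """Like :func:`detect` but labelling detections with real species names."""
    dets = detect(params, image, config)
    renamed = []
    for d in dets:
        idx = int(d.box.species.split("_")[-1])
        renamed.append(
            Detection(
                BoundingBoxAnnotation(
                    classes[idx], d.box.x_min, d.box.y_min, d.box.x_max, d.box.y_max
                ),
                d.score,
            )
        )
    return renamed


# ---------------------------------------------------------------------------
# evaluation against ground truth
# ---------------------------------------------------------------------------


def match_detections(
    detections: list[Detection],
    truths: list[BoundingBoxAnnotation],
    iou_threshold: float = 0.3,
) -> dict:
    """Greedy one-to-one matching by descending score with class agreement."""
    order = sorted(range(len(detections)), key=lambda i: -detections[i].score)
    matched_truth: set[int] = set()
    tp = 0
    for i in order:
        det = detections[i]
        best_j, best_iou = -1, iou_threshold
        for j, truth in enumerate(truths):
            if j in matched_truth or truth.species != det.box.species:
                continue
            val = iou(
                (det.box.x_min, det.box.y_min, det.box.x_max, det.box.y_max),
                (truth.x_min, truth.y_min, truth.x_max, truth.y_max),
            )
            if val >= best_iou:
                best_iou, best_j = val, j
        if best_j >= 0:
            matched_truth.add(best_j)
            tp += 1
    fp = len(detections) - tp
    fn = len(truths) - tp
    precision = tp / (tp + fp) if tp + fp else 1.0
    recall = tp / (tp + fn) if tp + fn else 1.0
    return {"tp": tp, "fp": fp, "fn": fn, "precision": precision, "recall": recall}
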