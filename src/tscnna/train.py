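"""Training and evaluation protocol.

Mini-batch momentum SGD (batch 35, momentum 0.9, weight decay 1e-4) with
the milestone learning-rate schedule: 0.01 initially, multiplied by
ρ = (0.0001/0.01)^(1/5) at each of the milestones {1000, 1500, 2000,
2500, 2900}, hence exactly 0.0001 at and after the last milestone.
One update is::

    v ← 0.9·v + ∇L + 1e-4·θ ;  θ ← θ − lr·v

Cross-validation is five-fold, stratified by class and split by SOURCE
image: all augmented copies of an image travel with it, so no augmented
variant of a test image ever appears in training.

Classification samples are pest-centred crops: the annotated box, padded
by 15 % and squared, resized to the network's input side. When the model
carries a background class, additional background crops are sampled from
regions away from any pest box so the detector's non-pest decision is
trained on the same scenes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from tscnna import autodiff as ad
from tscnna.autodiff import Tensor
from tscnna.attention import bilinear_resize
from tscnna.config import RunConfig
from tscnna.io import BoundingBoxAnnotation, DatasetManifest, read_image
from tscnna.model import ArchitectureConfig, ModelParameters, build_model, forward, forward_t

Array = np.ndarray

BACKGROUND_LABEL = "background"


# ---------------------------------------------------------------------------
# learning-rate schedule
# ---------------------------------------------------------------------------


def lr_schedule(iteration: int, config: RunConfig) -> float:
    """Piecewise-constant exponential attenuation over the milestones."""
    if iteration < 0:
        raise ValueError("iteration must be >= 0")
    milestones = config.milestones
    rho = (config.final_lr / config.initial_lr) ** (1.0 / len(milestones))
    passed = sum(1 for m in milestones if iteration >= m)
    if passed == len(milestones):
        return config.final_lr
    return config.initial_lr * rho**passed


# ---------------------------------------------------------------------------
# classification dataset
# ---------------------------------------------------------------------------


@dataclass
class ClassificationDataset:
    """Pest-centred crops (and optional background crops) ready for training.

    ``canonical`` flags the dataset's own views (padded box crops and clear
    background crops) as opposed to auxiliary window-geometry views (IoU-
    verified off-scale negatives and jittered positives) that exist to
    train the detector's rejection behaviour; evaluation reports are
    computed on the canonical views.
    """

    images: Array  # (N, side, side, 3) float32 in [0, 1]
    labels: Array  # (N,) int
    source_ids: np.ndarray  # (N,) str — source-image identifier
    classes: tuple[str, ...]  # pest classes + optionally "background"
    source_class: dict[str, str] = field(default_factory=dict)
    canonical: Array | None = None  # (N,) bool; None means all canonical

    def __len__(self) -> int:
        return len(self.labels)

    def canonical_mask(self) -> Array:
        if self.canonical is None:
            return np.ones(len(self.labels), dtype=bool)
        return self.canonical

    def subset(self, mask: Array) -> "ClassificationDataset":
        return ClassificationDataset(
            self.images[mask], self.labels[mask], self.source_ids[mask],
            self.classes, self.source_class,
            None if self.canonical is None else self.canonical[mask],
        )


def crop_box(image: Array, box: BoundingBoxAnnotation, side: int, pad: float = 0.15) -> Array:
    """Squared, padded crop around a box, resized to side×side (float [0,1])."""
    h, w = image.shape[:2]
    cx = 0.5 * (box.x_min + box.x_max)
    cy = 0.5 * (box.y_min + box.y_max)
    half = 0.5 * max(box.width, box.height) * (1.0 + 2 * pad)
    half = max(half, 2.0)
    x0, x1 = int(np.floor(cx - half)), int(np.ceil(cx + half))
    y0, y1 = int(np.floor(cy - half)), int(np.ceil(cy + half))
    x0, y0 = max(0, x0), max(0, y0)
    x1, y1 = min(w, x1), min(h, y1)
    crop = np.asarray(image, dtype=float)[y0:y1, x0:x1]
    return bilinear_resize(crop, side, side).astype(np.float32) / 255.0


def center_crop(image: Array, side: int) -> Array:
    h, w = image.shape[:2]
    s = min(h, w)
    y0, x0 = (h - s) // 2, (w - s) // 2
    crop = np.asarray(image, dtype=float)[y0 : y0 + s, x0 : x0 + s]
    return bilinear_resize(crop, side, side).astype(np.float32) / 255.0


def sample_background_crop(
    image: Array,
    boxes: list[BoundingBoxAnnotation],
    rng: np.random.Generator,
    size_range: tuple[int, int] = (8, 48),
    side: int = 32,
    attempts: int = 30,
) -> Array | None:
    """A crop overlapping no pest box (tries *attempts* times, else None)."""
    h, w = image.shape[:2]
    hi = min(size_range[1], min(h, w))
    for _ in range(attempts):
        s = int(rng.integers(size_range[0], hi + 1))
        x0 = int(rng.integers(0, w - s + 1))
        y0 = int(rng.integers(0, h - s + 1))
        clear = all(
            x0 + s <= b.x_min or b.x_max <= x0 or y0 + s <= b.y_min or b.y_max <= y0
            for b in boxes
        )
        if clear:
            crop = np.asarray(image, dtype=float)[y0 : y0 + s, x0 : x0 + s]
            return bilinear_resize(crop, side, side).astype(np.float32) / 255.0
    return None


def _box_window_iou(box: BoundingBoxAnnotation, x0: float, y0: float, x1: float, y1: float) -> float:
    ix0, iy0 = max(box.x_min, x0), max(box.y_min, y0)
    ix1, iy1 = min(box.x_max, x1), min(box.y_max, y1)
    inter = max(0.0, ix1 - ix0) * max(0.0, iy1 - iy0)
    union = box.area + (x1 - x0) * (y1 - y0) - inter
    return inter / union if union > 0 else 0.0


def _window_crop(image: Array, x0: int, y0: int, x1: int, y1: int, side: int) -> Array:
    crop = np.asarray(image, dtype=float)[y0:y1, x0:x1]
    return bilinear_resize(crop, side, side).astype(np.float32) / 255.0


def sample_offscale_crop(
    image: Array,
    box: BoundingBoxAnnotation,
    rng: np.random.Generator,
    side: int = 32,
    mode: int | None = None,
    attempts: int = 20,
) -> Array | None:
    """A square view of a pest through a WRONG window: IoU ≤ 0.22 with it.

    Sliding-window detection presents the classifier with many windows that
    graze a pest — far larger than it, nested inside it, centred on its
    corner, or diagonally offset — and all such windows fall below the
    IoU-0.3 matching threshold, so they must be rejected as non-pest.
    Candidate windows are drawn from those view families and accepted only
    after their IoU with the true box is verified ≤ 0.22, so the background
    label never contradicts the matching criterion (important for elongated
    boxes, whose square-window IoUs are compressed).
    """
    h, w = image.shape[:2]
    s = max(box.width, box.height)
    base_cx = 0.5 * (box.x_min + box.x_max)
    base_cy = 0.5 * (box.y_min + box.y_max)
    for _ in range(attempts):
        m = int(rng.integers(0, 5)) if mode is None else mode % 5
        cx, cy = base_cx, base_cy
        if m == 0:
            half = 0.5 * s * rng.uniform(2.8, 3.5)  # far context, pest centred
        elif m == 1:
            half = 0.5 * s * rng.uniform(1.4, 1.7)  # window on a random box corner
            cx = box.x_min if rng.random() < 0.5 else box.x_max
            cy = box.y_min if rng.random() < 0.5 else box.y_max
        elif m == 2:
            half = 0.5 * min(box.width, box.height) * rng.uniform(0.4, 0.6)  # interior
        elif m == 3:
            half = 0.5 * s * rng.uniform(1.9, 2.3)  # near context
        else:
            half = 0.5 * s  # same-size window diagonally offset
            d = s * rng.uniform(0.45, 0.6)
            cx += d * (1 if rng.random() < 0.5 else -1)
            cy += d * (1 if rng.random() < 0.5 else -1)
        x0, x1 = int(round(cx - half)), int(round(cx + half))
        y0, y1 = int(round(cy - half)), int(round(cy + half))
        x0, y0 = max(0, x0), max(0, y0)
        x1, y1 = min(w, x1), min(h, y1)
        if x1 - x0 < 4 or y1 - y0 < 4:
            continue
        if _box_window_iou(box, x0, y0, x1, y1) <= 0.22:
            return _window_crop(image, x0, y0, x1, y1, side)
    return None


def sample_jittered_positive(
    image: Array,
    box: BoundingBoxAnnotation,
    rng: np.random.Generator,
    side: int = 32,
    attempts: int = 20,
) -> Array:
    """A positive view through a randomly offset/sized window, IoU-verified.

    Candidates alternate between box-aspect rectangles (what the
    anisotropic detection scan presents for elongated bodies) and squares,
    jittered in size and centre, accepted at IoU ≥ 0.35 with the box —
    a clear margin above the off-scale negatives (IoU ≤ 0.22).
    Detection windows rarely frame a pest as neatly as the padded training
    crop does — and for elongated boxes the best square window covers only
    part of the body length. These views teach the classifier exactly the
    window geometry the detector will present, aligned with the IoU-0.3
    matching criterion.
    """
    h, w = image.shape[:2]
    best = None
    best_iou = -1.0
    for attempt in range(attempts):
        cx = 0.5 * (box.x_min + box.x_max) + box.width * rng.uniform(-0.2, 0.2)
        cy = 0.5 * (box.y_min + box.y_max) + box.height * rng.uniform(-0.2, 0.2)
        if attempt % 2 == 0:
            # box-aspect window, as the anisotropic detection scan presents
            half_x = 0.5 * box.width * rng.uniform(0.9, 1.35)
            half_y = 0.5 * box.height * rng.uniform(0.9, 1.35)
        else:
            half_x = half_y = 0.5 * max(box.width, box.height) * rng.uniform(0.55, 1.35)
        x0, x1 = int(round(cx - half_x)), int(round(cx + half_x))
        y0, y1 = int(round(cy - half_y)), int(round(cy + half_y))
        x0, y0 = max(0, x0), max(0, y0)
        x1, y1 = min(w, x1), min(h, y1)
        if x1 - x0 < 3 or y1 - y0 < 3:
            continue
        v = _box_window_iou(box, x0, y0, x1, y1)
        if v > best_iou:
            best_iou, best = v, (x0, y0, x1, y1)
        if v >= 0.35:
            return _window_crop(image, x0, y0, x1, y1, side)
    if best is not None and best_iou >= 0.3:
        return _window_crop(image, *best, side)
    return crop_box(image, box, side)


def load_classification_dataset(
    manifest: DatasetManifest,
    side: int = 32,
    include_background: bool = True,
    background_per_original: int = 3,
    offscale_per_original: int = 10,
    jittered_per_original: int = 4,
    background_size_range: tuple[int, int] = (8, 48),
    seed: int = 0,
) -> ClassificationDataset:
    """Materialize crops from every manifest entry (plus background crops).

    Pest crops come from each entry's first box; the rare entry whose boxes
    were all lost to aggressive cropping is skipped (it has no object left
    to crop). Background crops — clear regions plus off-scale views of
    pests — are sampled only from original images.
    """
    rng = np.random.default_rng(seed)
    classes = tuple(manifest.classes) + ((BACKGROUND_LABEL,) if include_background else ())
    label_of = {c: i for i, c in enumerate(classes)}
    images: list[Array] = []
    labels: list[int] = []
    sources: list[str] = []
    canonical: list[bool] = []
    source_class: dict[str, str] = {}

    def add(crop: Array, label: int, source: str, is_canonical: bool) -> None:
        images.append(crop)
        labels.append(label)
        sources.append(source)
        canonical.append(is_canonical)

    for entry in manifest.entries:
        source_class.setdefault(entry.source_id, entry.species)
        if not entry.boxes and entry.provenance == "augmented":
            continue
        img = read_image(manifest.root / entry.image_path)
        crop = crop_box(img, entry.boxes[0], side) if entry.boxes else center_crop(img, side)
        add(crop, label_of[entry.species], entry.source_id, True)
        if include_background and entry.provenance == "original":
            for _ in range(background_per_original):
                bg = sample_background_crop(
                    img, list(entry.boxes), rng, background_size_range, side
                )
                if bg is not None:
                    add(bg, label_of[BACKGROUND_LABEL], entry.source_id, True)
            for i in range(offscale_per_original):
                bg = sample_offscale_crop(
                    img, entry.boxes[i % len(entry.boxes)], rng, side, mode=i
                )
                if bg is not None:
                    add(bg, label_of[BACKGROUND_LABEL], entry.source_id, False)
            for i in range(jittered_per_original):
                box = entry.boxes[i % len(entry.boxes)]
                add(sample_jittered_positive(img, box, rng, side),
                    label_of[box.species], entry.source_id, False)
    return ClassificationDataset(
        np.stack(images).astype(np.float32),
        np.asarray(labels, dtype=np.int64),
        np.asarray(sources, dtype=object),
        classes,
        source_class,
        np.asarray(canonical, dtype=bool),
    )


# ---------------------------------------------------------------------------
# SGD training
# ---------------------------------------------------------------------------


@dataclass
class TrainState:
    iteration: int = 0
    learning_rate: float = 0.0
    velocities: dict[str, Array] = field(default_factory=dict)
    loss_history: list[float] = field(default_factory=list)
    precision_history: list[tuple[int, float]] = field(default_factory=list)


def train_step(
    params: ModelParameters,
    state: TrainState,
    batch_x: Array,
    batch_y: Array,
    config: RunConfig,
) -> float:
    """One momentum-SGD update in place; returns the pre-update batch loss."""
    tensors = {k: Tensor(v, requires_grad=True) for k, v in params.tensors.items()}
    logits, _ = forward_t(params, batch_x, train_params=tensors)
    loss = ad.softmax_cross_entropy(logits, batch_y)
    loss_val = float(loss.data)
    if not np.isfinite(loss_val):
        raise FloatingPointError(f"non-finite loss at iteration {state.iteration}")
    loss.backward()
    lr = lr_schedule(state.iteration, config)
    state.learning_rate = lr
    mu, wd = config.momentum, config.weight_decay
    for name, t in tensors.items():
        grad = t.grad if t.grad is not None else np.zeros_like(t.data)
        v = state.velocities.get(name)
        if v is None:
            v = np.zeros_like(t.data)
        v = mu * v + grad + wd * t.data
        state.velocities[name] = v
        params.tensors[name] = (t.data - lr * v).astype(t.data.dtype)
    state.iteration += 1
    state.loss_history.append(loss_val)
    return loss_val


def train(
    params: ModelParameters,
    dataset: ClassificationDataset,
    config: RunConfig,
    max_iterations: int | None = None,
    seed: int = 0,
    eval_set: ClassificationDataset | None = None,
    eval_every: int = 0,
) -> tuple[ModelParameters, TrainState]:
    """Run up to *max_iterations* of seeded, reshuffled-epoch mini-batch SGD."""
    if len(dataset) == 0:
        raise ValueError("empty training split")
    max_iterations = config.max_iterations if max_iterations is None else max_iterations
    rng = np.random.default_rng(seed)
    state = TrainState()
    n = len(dataset)
    order = np.empty(0, dtype=int)
    pos = n  # forces a reshuffle on first use
    while state.iteration < max_iterations:
        if pos >= n:
            order = rng.permutation(n)
            pos = 0
        idx = order[pos : pos + config.batch_size]
        pos += config.batch_size
        train_step(params, state, dataset.images[idx], dataset.labels[idx], config)
        if eval_every and eval_set is not None and state.iteration % eval_every == 0:
            report = evaluate_precision(params, eval_set)
            state.precision_history.append((state.iteration, report.overall))
    return params, state


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------


@dataclass
class EvalReport:
    overall: float  # percent correct
    confusion: Array  # (C, C): true class × predicted class
    per_class_precision: dict[str, float]
    per_class_recall: dict[str, float]
    n: int
    fold_values: list[float] = field(default_factory=list)

    @property
    def mean(self) -> float:
        return float(np.mean(self.fold_values)) if self.fold_values else self.overall

    @property
    def std(self) -> float:
        return float(np.std(self.fold_values)) if self.fold_values else 0.0


def predict_labels(params: ModelParameters, images: Array, batch_size: int = 64) -> Array:
    out = []
    for i in range(0, len(images), batch_size):
        probs = forward(params, images[i : i + batch_size])
        out.append(np.argmax(probs, axis=1))
    return np.concatenate(out) if out else np.empty(0, dtype=int)


def _report(y_true: Array, y_pred: Array, classes: tuple[str, ...]) -> EvalReport:
    c = len(classes)
    confusion = np.zeros((c, c), dtype=int)
    for t, p in zip(y_true, y_pred):
        confusion[t, p] += 1
    return _report_from_confusion(confusion, classes)


def _report_from_confusion(confusion: Array, classes: tuple[str, ...]) -> EvalReport:
    correct = int(np.trace(confusion))
    total = int(confusion.sum())
    precision = {}
    recall = {}
    for i, name in enumerate(classes):
        col = confusion[:, i].sum()
        row = confusion[i, :].sum()
        precision[name] = 100.0 * confusion[i, i] / col if col else float("nan")
        recall[name] = 100.0 * confusion[i, i] / row if row else float("nan")
    return EvalReport(
        overall=100.0 * correct / total,
        confusion=confusion,
        per_class_precision=precision,
        per_class_recall=recall,
        n=total,
    )


def evaluate_precision(params: ModelParameters, dataset: ClassificationDataset) -> EvalReport:
    """Proportion of correctly classified crops, as a percentage."""
    if len(dataset) == 0:
        raise ValueError("empty evaluation split")
    y_pred = predict_labels(params, dataset.images)
    return _report(dataset.labels, y_pred, dataset.classes)


def classify_image_patches(
    params: ModelParameters,
    image: Array,
    side: int = 32,
    grid: int = 3,
    overlap: float = 0.5,
) -> int:
    """Majority vote over an overlapping patch grid (ties: highest mean prob)."""
    h, w = image.shape[:2]
    patch_h = int(np.ceil(h / (1 + (grid - 1) * (1 - overlap))))
    patch_w = int(np.ceil(w / (1 + (grid - 1) * (1 - overlap))))
    step_y = max(1, int(patch_h * (1 - overlap)))
    step_x = max(1, int(patch_w * (1 - overlap)))
    crops = []
    for gy in range(grid):
        for gx in range(grid):
            y0 = min(gy * step_y, h - patch_h)
            x0 = min(gx * step_x, w - patch_w)
            patch = np.asarray(image, dtype=float)[y0 : y0 + patch_h, x0 : x0 + patch_w]
            crops.append(bilinear_resize(patch, side, side) / 255.0)
    probs = forward(params, np.stack(crops).astype(np.float32))
    votes = np.argmax(probs, axis=1)
    counts = np.bincount(votes, minlength=probs.shape[1])
    best = np.flatnonzero(counts == counts.max())
    if len(best) == 1:
        return int(best[0])
    mean_probs = probs.mean(axis=0)
    return int(best[np.argmax(mean_probs[best])])


# ---------------------------------------------------------------------------
# k-fold cross-validation
# ---------------------------------------------------------------------------


def make_source_folds(
    source_class: dict[str, str], k: int, rng: np.random.Generator
) -> dict[str, int]:
    """Stratified partition of source images into k folds (per-class balance)."""
    by_class: dict[str, list[str]] = {}
    for src in sorted(source_class):
        by_class.setdefault(source_class[src], []).append(src)
    fold_of: dict[str, int] = {}
    for cls in sorted(by_class):
        sources = by_class[cls]
        if k > len(sources):
            raise ValueError(f"k={k} exceeds the {len(sources)} sources of class {cls!r}")
        order = rng.permutation(len(sources))
        for rank, idx in enumerate(order):
            fold_of[sources[idx]] = rank % k
    return fold_of


def kfold_cv(
    dataset: ClassificationDataset,
    arch: ArchitectureConfig,
    config: RunConfig,
    k: int = 5,
    repeats: int = 1,
    max_iterations: int | None = None,
    seed: int = 0,
    dtype=np.float32,
) -> EvalReport:
    """k-fold CV split by source image, repeated with reshuffled folds.

    Training uses every view of the training sources (including the
    auxiliary window-geometry views); each fold is evaluated on the test
    sources' canonical crops. Returns an aggregate report whose
    ``fold_values`` holds the per-run overall precisions; ``mean``/``std``
    summarize across k×repeats runs.
    """
    rng = np.random.default_rng(seed)
    fold_values: list[float] = []
    confusion_total = None
    for rep in range(repeats):
        fold_of = make_source_folds(dataset.source_class, k, rng)
        folds = np.asarray([fold_of[s] for s in dataset.source_ids])
        for fold in range(k):
            test_mask = folds == fold
            train_set = dataset.subset(~test_mask)
            test_set = dataset.subset(test_mask & dataset.canonical_mask())
            model = build_model(arch, seed=seed * 1000 + rep * k + fold, dtype=dtype)
            model, _ = train(
                model, train_set, config,
                max_iterations=max_iterations, seed=seed + rep * k + fold,
            )
            report = evaluate_precision(model, test_set)
            fold_values.append(report.overall)
            confusion_total = (
                report.confusion if confusion_total is None
                else confusion_total + report.confusion
            )
    agg = _report_from_confusion(confusion_total, dataset.classes)
    agg.fold_values = fold_values
    return agg
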