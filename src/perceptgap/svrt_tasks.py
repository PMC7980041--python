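"""Scaled synthetic visual-reasoning tasks (spatial vs same-different).

Four representative two-class rules stand in for the classic 23-problem
abstract-reasoning battery, two per category:

* ``same_different_translation`` — are the two outline shapes identical up
  to translation?
* ``same_different_scaled`` — identical up to translation *and* scaling?
* ``inside_outside`` — is the small shape inside the large one? (spatial)
* ``left_of_right_of`` — is the small shape left of the large one? (spatial)

Shapes are random star-convex blobs (8-16 outline vertices) rendered as
closed outlines on gray, 128 px images by default.  Every label is exactly
recomputable from the stored outline geometry, and each task generator is
deterministic in its seed.

The scientific use of these tasks is the sample-efficiency contrast: in a
low-data regime, feed-forward models learn spatial rules far more easily
than same-different rules.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely.geometry import Point, Polygon

from . import classifiers as C
from .geometry import Polyline
from .render import RenderConfig, render

__all__ = [
    "TaskSpec", "ShapeInstance", "SvrtRecord", "TASKS", "generate_task",
    "recompute_label", "learning_curve",
]

_MAX_TRIES = 300


@dataclass(frozen=True)
class TaskSpec:
    task_id: str
    image_size: int = 128
    shape_complexity: int = 12       # outline vertices per blob

    @property
    def category(self) -> str:
        return TASKS[self.task_id]


@dataclass(frozen=True)
class ShapeInstance:
    outline: Polyline                # closed, in image coordinates
    scale: float = 1.0

    @property
    def position(self) -> np.ndarray:
        return self.outline.centroid()


@dataclass
class SvrtRecord:
    image: np.ndarray | None
    label: str
    task_id: str
    shapes: list[ShapeInstance]
    seed: int
    index: int

    _LABEL_INTS = {"same": 0, "different": 1,
                   "inside": 0, "outside": 1,
                   "left": 0, "right": 1}

    @property
    def y(self) -> int:
        return self._LABEL_INTS[self.label]


# task_id -> category
TASKS: dict[str, str] = {
    "same_different_translation": "same_different",
    "same_different_scaled": "same_different",
    "inside_outside": "spatial",
    "left_of_right_of": "spatial",
}


# ---------------------------------------------------------------------------
# Shape machinery
# ---------------------------------------------------------------------------

def _blob(rng: np.random.Generator, n_vertices: int, diameter: float
          ) -> np.ndarray:
    """Star-convex blob: jittered evenly spaced angles, random radii.

    Even angular spacing (with bounded jitter) keeps adjacent vertices
    separated, so the outline is always simple and free of sliver edges.
    """
    n = int(n_vertices)
    ang = (np.arange(n) + rng.uniform(-0.35, 0.35, n)) * (2 * np.pi / n)
    ang += rng.uniform(0, 2 * np.pi)
    r = rng.uniform(0.55, 1.0, n) * (diameter / 2.0)
    v = np.stack([r * np.cos(ang), r * np.sin(ang)], axis=1)
    d2 = ((v[:, None] - v[None, :]) ** 2).sum(-1)
    v *= diameter / np.sqrt(d2.max())
    return v


def _place_at(v: np.ndarray, center: np.ndarray) -> np.ndarray:
    return v - v.mean(axis=0) + center


def _mask_iou_aligned(a: np.ndarray, b: np.ndarray, size: int = 48) -> float:
    """Pixel IoU of two outlines' filled masks after aligning bounding-box
    corners (scale-sensitive)."""
    from skimage.draw import polygon as draw_polygon
    masks = []
    for v in (a, b):
        vv = v - v.min(axis=0)
        m = np.zeros((size, size), dtype=bool)
        rr, cc = draw_polygon(vv[:, 1], vv[:, 0], shape=(size, size))
        m[rr, cc] = True
        masks.append(m)
    inter = (masks[0] & masks[1]).sum()
    union = (masks[0] | masks[1]).sum() or 1
    return inter / union


def _random_center(rng, size, margin, diameter):
    lo = margin + diameter / 2
    hi = size - 1 - margin - diameter / 2
    return rng.uniform(lo, hi, size=2)


def _disjoint(a: Polyline, b: Polyline, clearance: float = 4.0) -> bool:
    return a.to_shapely().distance(b.to_shapely()) >= clearance


# ---------------------------------------------------------------------------
# Per-task scene samplers
# ---------------------------------------------------------------------------

def _scene_same_different(rng, spec: TaskSpec, label: str, scaled: bool
                          ) -> list[ShapeInstance]:
    size, margin = spec.image_size, 8
    d1 = rng.uniform(28.0, 40.0)
    v1 = _blob(rng, spec.shape_complexity, d1)
    if label == "same":
        v2 = v1.copy()
    else:
        for _ in range(_MAX_TRIES):
            v2 = _blob(rng, spec.shape_complexity, d1)
            if _mask_iou_aligned(v1, v2) <= 0.9:
                break
        else:
            raise RuntimeError("could not sample a distinct shape")
    s2 = 1.0
    if scaled:
        s2 = rng.uniform(0.55, 0.8) if rng.random() < 0.5 else rng.uniform(1.25, 1.6)
        v2 = v2 * s2
    for _ in range(_MAX_TRIES):
        p1 = _random_center(rng, size, margin, d1)
        p2 = _random_center(rng, size, margin, d1 * s2)
        s_a = Polyline(_place_at(v1, p1), closed=True)
        s_b = Polyline(_place_at(v2, p2), closed=True)
        if _disjoint(s_a, s_b):
            return [ShapeInstance(s_a, 1.0), ShapeInstance(s_b, s2)]
    raise RuntimeError("could not place shapes")


def _scene_inside_outside(rng, spec: TaskSpec, label: str) -> list[ShapeInstance]:
    size, margin = spec.image_size, 8
    d_big, d_small = rng.uniform(64.0, 88.0), rng.uniform(14.0, 20.0)
    for _ in range(_MAX_TRIES):
        vb = _blob(rng, spec.shape_complexity, d_big)
        pb = _random_center(rng, size, margin, d_big)
        big = Polyline(_place_at(vb, pb), closed=True)
        poly = Polygon(big.vertices)
        vs = _blob(rng, max(spec.shape_complexity - 4, 6), d_small)
        if label == "inside":
            # rejection-sample a center well inside the big polygon
            inner = poly.buffer(-(d_small / 2 + 3))
            if inner.is_empty:
                continue
            xmin, ymin, xmax, ymax = inner.bounds
            for _ in range(60):
                c = np.array([rng.uniform(xmin, xmax), rng.uniform(ymin, ymax)])
                if inner.contains(Point(c)):
                    small = Polyline(_place_at(vs, c), closed=True)
                    if poly.contains(Polygon(small.vertices)):
                        return [ShapeInstance(big), ShapeInstance(small)]
        else:
            for _ in range(60):
                c = _random_center(rng, size, margin, d_small)
                small = Polyline(_place_at(vs, c), closed=True)
                # distance between *filled* polygons: containment gives 0
                if poly.distance(Polygon(small.vertices)) >= 4.0:
                    return [ShapeInstance(big), ShapeInstance(small)]
    raise RuntimeError("could not build inside/outside scene")


def _scene_left_right(rng, spec: TaskSpec, label: str) -> list[ShapeInstance]:
    size, margin = spec.image_size, 8
    d_big, d_small = rng.uniform(40.0, 56.0), rng.uniform(16.0, 24.0)
    for _ in range(_MAX_TRIES):
        vb = _blob(rng, spec.shape_complexity, d_big)
        vs = _blob(rng, max(spec.shape_complexity - 4, 6), d_small)
        pb = _random_center(rng, size, margin, d_big)
        ps = _random_center(rng, size, margin, d_small)
        dx = ps[0] - pb[0]
        if abs(dx) < 16:             # unambiguous horizontal separation
            continue
        if (dx < 0) != (label == "left"):
            ps[0] = 2 * pb[0] - ps[0]            # mirror to the wanted side
            lo = margin + d_small / 2
            if not (lo <= ps[0] <= size - 1 - lo):
                continue
        big = Polyline(_place_at(vb, pb), closed=True)
        small = Polyline(_place_at(vs, ps), closed=True)
        if _disjoint(big, small):
            return [ShapeInstance(big), ShapeInstance(small)]
    raise RuntimeError("could not build left/right scene")


_LABELS_BY_TASK = {
    "same_different_translation": ("same", "different"),
    "same_different_scaled": ("same", "different"),
    "inside_outside": ("inside", "outside"),
    "left_of_right_of": ("left", "right"),
}


def _sample_scene(task_id: str, rng, spec: TaskSpec, label: str):
    if task_id == "same_different_translation":
        return _scene_same_different(rng, spec, label, scaled=False)
    if task_id == "same_different_scaled":
        return _scene_same_different(rng, spec, label, scaled=True)
    if task_id == "inside_outside":
        return _scene_inside_outside(rng, spec, label)
    if task_id == "left_of_right_of":
        return _scene_left_right(rng, spec, label)
    raise ValueError(f"unknown task_id {task_id!r}")


# ---------------------------------------------------------------------------
# Label recomputation (the rule, applied to stored geometry)
# ---------------------------------------------------------------------------

def recompute_label(record: SvrtRecord) -> str:
    """Re-derive the class label from the stored outlines alone."""
    a, b = record.shapes[0].outline.vertices, record.shapes[1].outline.vertices
    task = record.task_id
    if task == "same_different_translation":
        if a.shape == b.shape and np.allclose(
                a - a.min(axis=0), b - b.min(axis=0), atol=1e-6):
            return "same"
        return "different"
    if task == "same_different_scaled":
        if a.shape != b.shape:
            return "different"
        aa = a - a.mean(axis=0)
        bb = b - b.mean(axis=0)
        sa = np.abs(aa).max() or 1.0
        sb = np.abs(bb).max() or 1.0
        return "same" if np.allclose(aa / sa, bb / sb, atol=1e-4) else "different"
    if task == "inside_outside":
        big, small = Polygon(a), Polygon(b)
        return "inside" if big.contains(small) else "outside"
    if task == "left_of_right_of":
        return "left" if b.mean(axis=0)[0] < a.mean(axis=0)[0] else "right"
    raise ValueError(f"unknown task_id {task!r}")


# ---------------------------------------------------------------------------
# Dataset generation + learning curves
# ---------------------------------------------------------------------------

def generate_task(spec: TaskSpec | str, n: int, seed: int = 0,
                  render_images: bool = True) -> list[SvrtRecord]:
    """Generate a balanced dataset for one task (n/2 per class)."""
    if isinstance(spec, str):
        spec = TaskSpec(spec)
    if spec.task_id not in TASKS:
        raise ValueError(f"unknown task_id {spec.task_id!r}")
    names = _LABELS_BY_TASK[spec.task_id]
    labels = [names[0]] * (n // 2) + [names[1]] * (n - n // 2)
    np.random.default_rng(np.random.SeedSequence(
        [seed, 0x5A5A])).shuffle(labels)
    cfg = RenderConfig(image_size=spec.image_size)
    records = []
    for i, lbl in enumerate(labels):
        rng = np.random.default_rng(np.random.SeedSequence([seed, i, 0x57]))
        shapes = _sample_scene(spec.task_id, rng, spec, lbl)
        image = None
        if render_images:
            image = render([s.outline for s in shapes], cfg)
        records.append(SvrtRecord(image=image, label=lbl,
                                  task_id=spec.task_id, shapes=shapes,
                                  seed=seed, index=i))
    return records


def learning_curve(model_factory, tasks, train_sizes, seed: int = 0,
                   n_test: int = 400) -> pd.DataFrame:
    """Accuracy of fresh models across tasks and training-set sizes.

    ``model_factory(seed)`` must return an unfitted estimator.  Test sets
    are generated from a disjoint seed stream.  Returns a tidy table
    (task, category, train_size, seed, accuracy).
    """
    train_sizes = sorted(train_sizes)
    rows = []
    for task_id in tasks:
        test = generate_task(task_id, n_test, seed=seed + 10_000)
        full_train = generate_task(task_id, max(train_sizes), seed=seed)
        for n in train_sizes:
            model = model_factory(seed)
            sub = full_train[:n]
            if hasattr(model, "fit_records"):
                model.fit_records(sub)
            else:
                X, y = C.records_to_arrays(sub)
                model.fit(X, y)
            acc = C.evaluate(model, test, dataset_id=task_id).accuracy
            rows.append({"task": task_id, "category": TASKS[task_id],
                         "train_size": n, "seed": seed, "accuracy": acc})
    return pd.DataFrame(rows)
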