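"""Machine-based search for minimal recognizable configurations (MIRCs).

Starting from a full image that the model classifies correctly with
probability above a threshold (default 0.5), the image is successively
cropped and reduced in resolution.  At each step the candidate children of
the current node are five overlapping crops (four corners + center, at a
linear fraction of the parent) plus one resolution-reduction child; the
best-performing child becomes the new parent.  When every child scores
below the threshold, the parent is the MIRC, its children are the
sub-MIRCs, and the *recognition gap* is the MIRC's correct-class
probability minus that of the best-performing sub-MIRC — a conservative
definition (the gap to the worst sub-MIRC is always at least as large).

Probabilities at or above the threshold count as recognizable; sub-MIRCs
are strictly below.  An image whose full view already scores below the
threshold is skipped (result ``None``).  A node that still scores above
threshold but has no legal children (at the minimum analyzable size,
default 33 px — the local model's receptive field) is flagged as a
floor MIRC and excluded from gap statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.transform import resize

__all__ = [
    "SearchParams", "SearchNode", "MircResult", "GapStats",
    "expand_children", "descend", "recognition_gap", "aggregate_gaps",
    "model_probability_fn", "result_to_dict",
]


@dataclass(frozen=True)
class SearchParams:
    threshold: float = 0.5
    crop_fraction: float = 0.8
    crop_positions: int = 5          # four corners + center
    resolution_factor: float = 0.8
    min_size: int = 33
    max_depth: int = 64

    def __post_init__(self) -> None:
        if not (0 < self.crop_fraction < 1):
            raise ValueError("crop_fraction must be in (0, 1)")
        if not (0 < self.resolution_factor < 1):
            raise ValueError("resolution_factor must be in (0, 1)")
        if not (0 < self.threshold < 1):
            raise ValueError("threshold must be in (0, 1)")


@dataclass
class SearchNode:
    """A crop/resolution state in original-image coordinates.

    ``rect`` is half-open, 0-based ``(x0, y0, x1, y1)``; ``scale`` is the
    effective resolution factor accumulated through resolution children.
    """

    rect: tuple[int, int, int, int]
    scale: float = 1.0
    p_correct: float | None = None
    kind: str = "root"               # root | crop_tl/tr/bl/br/c | resolution
    depth: int = 0
    children: list["SearchNode"] = field(default_factory=list)

    @property
    def width(self) -> int:
        return self.rect[2] - self.rect[0]

    @property
    def height(self) -> int:
        return self.rect[3] - self.rect[1]

    @property
    def side(self) -> int:
        return min(self.width, self.height)

    @property
    def effective_pixels(self) -> float:
        return self.side * self.scale


@dataclass
class MircResult:
    mirc: SearchNode
    sub_mircs: list[SearchNode]
    gap: float
    trace: list[SearchNode]
    floor_flagged: bool = False


@dataclass(frozen=True)
class GapStats:
    mean: float
    sd: float                        # population standard deviation
    n: int
    n_floor: int = 0


# ---------------------------------------------------------------------------
# Tree expansion
# ---------------------------------------------------------------------------

def expand_children(node: SearchNode, params: SearchParams) -> list[SearchNode]:
    """Candidate children of a node, in the fixed deterministic order
    TL, TR, BL, BR, center crop, then resolution reduction.

    Crop children whose side would fall below ``min_size`` and resolution
    children whose effective pixel count would fall below ``min_size`` are
    omitted; the list is empty at the search floor.
    """
    x0, y0, x1, y1 = node.rect
    w, h = node.width, node.height
    cw = int(round(w * params.crop_fraction))
    ch = int(round(h * params.crop_fraction))
    out: list[SearchNode] = []
    if node.depth < params.max_depth:
        if min(cw, ch) >= params.min_size:
            anchors = [
                ("crop_tl", x0, y0),
                ("crop_tr", x1 - cw, y0),
                ("crop_bl", x0, y1 - ch),
                ("crop_br", x1 - cw, y1 - ch),
                ("crop_c", x0 + (w - cw) // 2, y0 + (h - ch) // 2),
            ][: params.crop_positions]
            for kind, ax, ay in anchors:
                out.append(SearchNode(rect=(ax, ay, ax + cw, ay + ch),
                                      scale=node.scale, kind=kind,
                                      depth=node.depth + 1))
        new_scale = node.scale * params.resolution_factor
        if node.side * new_scale >= params.min_size:
            out.append(SearchNode(rect=node.rect, scale=new_scale,
                                  kind="resolution", depth=node.depth + 1))
    return out


# ---------------------------------------------------------------------------
# Node evaluation
# ---------------------------------------------------------------------------

def node_image(image: np.ndarray, node: SearchNode) -> np.ndarray:
    """The degraded view a node represents: crop, then resolution loss
    (downsample by ``scale`` and upsample back, bilinear)."""
    x0, y0, x1, y1 = node.rect
    crop = np.asarray(image, dtype=float)[y0:y1, x0:x1]
    if node.scale < 1.0:
        small = (max(1, int(round(crop.shape[0] * node.scale))),
                 max(1, int(round(crop.shape[1] * node.scale))))
        low = resize(crop, small, order=1, anti_aliasing=True,
                     preserve_range=True)
        crop = resize(low, crop.shape, order=1, anti_aliasing=False,
                      preserve_range=True)
    return crop


def model_probability_fn(model, true_class: int, input_size: int = 256):
    """Adapter: fitted classifier -> p(true class | node view).

    Node views are resized (bilinear) to the model's training input size.
    """
    class_index = int(np.where(model.classes_ == true_class)[0][0])

    def prob(view: np.ndarray, node: SearchNode) -> float:
        x = resize(view, (input_size, input_size), order=1,
                   anti_aliasing=True, preserve_range=True)
        p = model.predict_proba(x[None].astype(np.float32))[0, class_index]
        return float(p)

    return prob


# ---------------------------------------------------------------------------
# Greedy descent
# ---------------------------------------------------------------------------

def descend(model, image: np.ndarray, true_class: int | None = None,
            params: SearchParams | None = None,
            input_size: int | None = None) -> MircResult | None:
    """Greedy MIRC search on one image.

    ``model`` is either a fitted classifier (``predict_proba`` +
    ``classes_``; ``true_class`` required) or a callable
    ``f(view, node) -> probability`` evaluated directly.  Returns ``None``
    when the whole image already scores below threshold ("skip image"),
    otherwise a :class:`MircResult`; results at the search floor carry
    ``floor_flagged=True`` and a NaN gap.
    """
    params = params or SearchParams()
    if callable(model) and not hasattr(model, "predict_proba"):
        prob = model
    else:
        if true_class is None:
            raise ValueError("true_class required for classifier models")
        size = input_size or (image.shape[0] if image.ndim == 2 else 256)
        prob = model_probability_fn(model, true_class, size)

    h, w = np.asarray(image).shape[:2]
    node = SearchNode(rect=(0, 0, w, h))
    node.p_correct = _checked_p(prob(node_image(image, node), node))
    if node.p_correct < params.threshold:
        return None

    trace = [node]
    while True:
        children = expand_children(node, params)
        for c in children:
            c.p_correct = _checked_p(prob(node_image(image, c), c))
        node.children = children
        if not children:
            return MircResult(mirc=node, sub_mircs=[], gap=float("nan"),
                              trace=trace, floor_flagged=True)
        best = max(children, key=lambda c: c.p_correct)  # first max wins ties
        if best.p_correct < params.threshold:
            gap = recognition_gap(node.p_correct,
                                  [c.p_correct for c in children])
            return MircResult(mirc=node, sub_mircs=children, gap=gap,
                              trace=trace)
        node = best
        trace.append(node)


def _checked_p(p: float) -> float:
    if not np.isfinite(p):
        raise ValueError("model produced a non-finite probability")
    return float(p)


def recognition_gap(p_mirc: float, p_children) -> float:
    """p(MIRC) minus the best-performing sub-MIRC's probability."""
    p_children = list(p_children)
    if not p_children:
        raise ValueError("recognition gap needs at least one sub-MIRC")
    return float(p_mirc) - float(max(p_children))


def aggregate_gaps(results) -> GapStats:
    """Mean and population SD of gaps; floor-flagged results are excluded
    from the statistics and counted separately."""
    results = list(results)
    if not results:
        raise ValueError("no results to aggregate")
    ok = [r for r in results if not r.floor_flagged]
    n_floor = len(results) - len(ok)
    if not ok:
        return GapStats(mean=float("nan"), sd=float("nan"), n=0,
                        n_floor=n_floor)
    gaps = np.array([r.gap for r in ok], dtype=float)
    return GapStats(mean=float(gaps.mean()), sd=float(gaps.std()),
                    n=len(ok), n_floor=n_floor)


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def _node_dict(n: SearchNode) -> dict:
    return {"rect": list(n.rect), "scale": n.scale, "p_correct": n.p_correct,
            "kind": n.kind, "depth": n.depth}


def result_to_dict(result: MircResult | None) -> dict:
    """JSON-ready summary of one search (full trace with 0-based half-open
    rectangles)."""
    if result is None:
        return {"skipped": True}
    return {
        "skipped": False,
        "floor_flagged": result.floor_flagged,
        "gap": None if np.isnan(result.gap) else result.gap,
        "mirc": _node_dict(result.mirc),
        "sub_mircs": [_node_dict(c) for c in result.sub_mircs],
        "trace": [_node_dict(t) for t in result.trace],
    }
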