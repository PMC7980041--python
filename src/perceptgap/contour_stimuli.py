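"""Procedural closed/open-contour stimuli and their out-of-distribution variants.

The training distribution contains 256x256 grayscale images with one *main
contour* of 3-9 straight segments — closed (forming a simple polygon) for
one class, open (with an endpoint gap of at least ``open_gap_min`` pixels)
for the other — plus several 1-2 segment *flankers* whose segments are at
least 32 px long.  Lines are black on a uniform gray background.

Class-statistics matching is enforced by construction: an open contour is
produced from a closed polygon by cutting it at a random vertex, retracting
one endpoint along its segment to open a gap, and rescaling about the
centroid so its total arc length equals the source polygon's perimeter.
Segment-count and arc-length distributions of the two classes are therefore
identical; the open class retains a small (~9% mean) diameter inflation,
which is documented as a known residual cue.

Fifteen systematically modified test distributions (curvy contours, dashed
or asymmetric flankers, line-width/color changes, ...) probe whether a
trained model generalizes beyond the training statistics; see ``VARIANTS``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .geometry import Polyline
from .render import RenderConfig, render, render_groups, save_png

LABELS = {"closed": 0, "open": 1}

__all__ = [
    "GenerationError", "MainContourSpec", "FlankerSpec", "VariantConfig",
    "GeneratorConfig", "StimulusRecord", "sample_main_contour",
    "sample_flankers", "generate_record", "generate_dataset",
    "generate_variant", "VARIANTS", "variant_config", "label_from_geometry",
    "write_dataset", "LABELS",
]


class GenerationError(RuntimeError):
    """Raised when rejection sampling exhausts its retry budget."""


# ---------------------------------------------------------------------------
# Specs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MainContourSpec:
    """One main contour: segment count, class, target size, minimum gap."""

    n_segments: int
    closed: bool
    target_diameter: float = 128.0
    open_gap_min: float = 16.0
    curvy: bool = False
    curvy_points: int = 48
    curvy_wiggle: float = 0.25

    def __post_init__(self) -> None:
        if not self.curvy and not (3 <= self.n_segments):
            raise ValueError("main contour needs at least 3 segments")
        if self.open_gap_min <= 0:
            raise ValueError("open_gap_min must be positive")


@dataclass(frozen=True)
class FlankerSpec:
    """Distractor family: 1-2 straight segments, each >= min_segment_length px."""

    n_segments: int | None = None          # None: pick 1 or 2 at random
    min_segment_length: float = 32.0
    max_segment_length: float = 64.0
    count_range: tuple[int, int] = (4, 8)
    asymmetric: bool = False               # two unequal segments, short one small
    short_length_range: tuple[float, float] = (8.0, 20.0)

    def __post_init__(self) -> None:
        if self.n_segments is not None and self.n_segments not in (1, 2):
            raise ValueError("flankers have 1 or 2 segments")
        if self.count_range[0] < 0 or self.count_range[1] < self.count_range[0]:
            raise ValueError("invalid count_range")


@dataclass(frozen=True)
class GeneratorConfig:
    """Full generative parameter set of one stimulus distribution."""

    image_size: int = 256
    margin: float = 16.0
    n_segments_range: tuple[int, int] = (3, 9)
    diameter_range: tuple[float, float] = (96.0, 160.0)
    open_gap_min: float = 16.0
    curvy: bool = False
    curvy_wiggle: float = 0.25
    flankers: FlankerSpec = field(default_factory=FlankerSpec)
    render: RenderConfig = field(default_factory=RenderConfig)
    # variant-only extras
    dashed_closed_flanker: bool = False
    n_curvy_open_flankers: int = 0
    main_clearance: float = 6.0
    flanker_clearance: float = 4.0

    def with_(self, **kw) -> "GeneratorConfig":
        return replace(self, **kw)


@dataclass(frozen=True)
class VariantConfig:
    """Selects one of the 15 out-of-distribution generators (1..15)."""

    variant_id: int
    parameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.variant_id not in VARIANTS:
            raise ValueError(f"unknown variant_id {self.variant_id!r}")


@dataclass
class StimulusRecord:
    """A rendered stimulus plus the full generative metadata."""

    image: np.ndarray | None
    label: str                      # "closed" | "open"
    main: Polyline
    flankers: list[Polyline]
    extras: dict                    # named extra polyline groups (variant-specific)
    variant_id: int                 # 0 = training distribution
    seed: int
    index: int
    gap: float                      # endpoint separation of the main contour
    render_cfg: RenderConfig

    @property
    def y(self) -> int:
        return LABELS[self.label]

    def to_metadata(self) -> dict:
        return {
            "index": self.index,
            "label": self.label,
            "variant_id": self.variant_id,
            "seed": self.seed,
            "gap": self.gap,
            "n_segments": self.main.n_segments,
            "n_flankers": len(self.flankers),
            "main": {"vertices": self.main.to_list(), "closed": self.main.closed},
            "flankers": [{"vertices": f.to_list(), "closed": f.closed}
                         for f in self.flankers],
            "extras": {k: [{"vertices": p.to_list(), "closed": p.closed}
                           for p in v] for k, v in self.extras.items()},
        }


def label_from_geometry(main: Polyline) -> str:
    """Recompute the class label from the stored main-contour geometry."""
    return "closed" if main.endpoint_separation == 0.0 else "open"


# ---------------------------------------------------------------------------
# Main-contour sampling
# ---------------------------------------------------------------------------

_MAX_TRIES = 200


def _star_polygon(n: int, diameter: float, rng: np.random.Generator,
                  min_seg: float = 8.0) -> np.ndarray:
    """A simple polygon: angularly ordered vertices around the origin.

    Angular ordering guarantees simplicity (the polygon is star-shaped
    about the origin).  Rescaled so the vertex-set diameter equals
    ``diameter`` exactly.
    """
    for _ in range(_MAX_TRIES):
        ang = np.sort(rng.uniform(0.0, 2 * np.pi, n))
        gaps = np.diff(np.concatenate([ang, [ang[0] + 2 * np.pi]]))
        if gaps.min() < 0.25 * (2 * np.pi / n):
            continue  # avoid sliver segments
        r = rng.uniform(0.55, 1.0, n) * (diameter / 2.0)
        v = np.stack([r * np.cos(ang), r * np.sin(ang)], axis=1)
        d2 = ((v[:, None] - v[None, :]) ** 2).sum(-1)
        cur = np.sqrt(d2.max())
        v *= diameter / cur
        seg = np.linalg.norm(np.diff(np.vstack([v, v[:1]]), axis=0), axis=1)
        if seg.min() >= min_seg:
            return v
    raise GenerationError("could not sample a valid polygon")


def _curvy_ring(n_points: int, diameter: float, wiggle: float,
                rng: np.random.Generator) -> np.ndarray:
    """A smooth closed 'curvy' outline as a dense polyline ring."""
    theta = np.linspace(0.0, 2 * np.pi, n_points, endpoint=False)
    r = np.ones_like(theta)
    for k in range(2, 6):
        amp = wiggle * rng.uniform(0.2, 1.0) / k
        r += amp * np.cos(k * theta + rng.uniform(0, 2 * np.pi))
    r = np.clip(r, 0.3, None) * (diameter / 2.0)
    v = np.stack([r * np.cos(theta), r * np.sin(theta)], axis=1)
    d2 = ((v[:, None] - v[None, :]) ** 2).sum(-1)
    v *= diameter / np.sqrt(d2.max())
    return v


def _retract_end(chain: np.ndarray, arc: float) -> np.ndarray | None:
    """Shorten a chain by ``arc`` pixels of arc length from its end.

    Whole trailing segments may be consumed; the final vertex is
    interpolated.  Returns None if the chain would degenerate.
    """
    pts = list(chain)
    remaining = arc
    while len(pts) >= 3:
        seg = pts[-1] - pts[-2]
        L = float(np.hypot(*seg))
        if L > remaining + 1.0:
            pts[-1] = pts[-1] - (remaining / L) * seg
            return np.asarray(pts)
        remaining -= L
        pts.pop()
    return None


def _open_from_closed(ring: np.ndarray, gap_min: float,
                      rng: np.random.Generator,
                      multi_segment: bool = False) -> tuple[np.ndarray, float]:
    """Cut a closed ring into an open chain with matched arc length.

    The ring is cut at a random vertex, the trailing endpoint is retracted
    along the chain by a gap drawn uniformly in [gap_min, 3*gap_min], and
    the chain is rescaled about its centroid so its arc length equals the
    ring's perimeter.  With ``multi_segment=False`` the gap must fit inside
    the single segment adjacent to the cut, preserving the segment count
    (required for the straight-line training distribution); dense curvy
    rings retract across segments instead.  Returns (vertices, endpoint
    separation).
    """
    n = ring.shape[0]
    closed_len = float(np.linalg.norm(
        np.diff(np.vstack([ring, ring[:1]]), axis=0), axis=1).sum())
    for _ in range(_MAX_TRIES):
        gap = rng.uniform(gap_min, 3 * gap_min)
        k = int(rng.integers(n))
        chain = np.vstack([ring[k:], ring[:k], ring[k:k + 1]])  # n+1 vertices
        if multi_segment:
            res = _retract_end(chain, gap)
            if res is None:
                continue
            chain = res
        else:
            last = chain[-1] - chain[-2]
            L = float(np.hypot(*last))
            if L <= gap + 2.0:
                continue  # adjacent segment too short to host the gap
            chain = chain.copy()
            chain[-1] = chain[-1] - (gap / L) * last
        open_len = float(np.linalg.norm(np.diff(chain, axis=0), axis=1).sum())
        f = closed_len / open_len
        c = chain.mean(axis=0)
        chain = c + f * (chain - c)
        sep = float(np.linalg.norm(chain[-1] - chain[0]))
        if sep >= gap_min:
            return chain, sep
    raise GenerationError("could not open the contour")


def _place(vertices: np.ndarray, image_size: int, margin: float,
           rng: np.random.Generator) -> np.ndarray:
    """Translate a vertex set to a uniform random admissible position."""
    xmin, ymin = vertices.min(axis=0)
    xmax, ymax = vertices.max(axis=0)
    lo_x, hi_x = margin - xmin, image_size - 1 - margin - xmax
    lo_y, hi_y = margin - ymin, image_size - 1 - margin - ymax
    if hi_x < lo_x or hi_y < lo_y:
        raise GenerationError("shape does not fit the canvas margin")
    return vertices + np.array([rng.uniform(lo_x, hi_x), rng.uniform(lo_y, hi_y)])


def sample_main_contour(spec: MainContourSpec, rng: np.random.Generator,
                        image_size: int = 256, margin: float = 16.0) -> Polyline:
    """Sample one main contour satisfying the spec.

    Closed contours are simple polygons with exactly ``n_segments``
    segments; open contours have the same segment count and arc length as
    a matched closed polygon but an endpoint gap >= ``open_gap_min``.
    """
    for _ in range(_MAX_TRIES):
        if spec.curvy:
            ring = _curvy_ring(spec.curvy_points, spec.target_diameter,
                               spec.curvy_wiggle, rng)
        else:
            ring = _star_polygon(spec.n_segments, spec.target_diameter, rng)
        if spec.closed:
            pl = Polyline(_place(ring, image_size, margin, rng), closed=True)
        else:
            chain, _ = _open_from_closed(ring, spec.open_gap_min, rng,
                                         multi_segment=spec.curvy)
            if spec.curvy:
                # curvy distributions are bounded by diameter, not arc
                # length: renormalize so the opened chain keeps the target
                p = Polyline(chain)
                c = chain.mean(axis=0)
                chain = c + (spec.target_diameter / p.diameter) * (chain - c)
            pl = Polyline(_place(chain, image_size, margin, rng), closed=False)
        if pl.is_simple() and pl.within_canvas(image_size, margin):
            return pl
    raise GenerationError("main-contour sampling exhausted retries")


# ---------------------------------------------------------------------------
# Flankers
# ---------------------------------------------------------------------------

def _flanker_chain(spec: FlankerSpec, rng: np.random.Generator) -> np.ndarray:
    n_seg = spec.n_segments or int(rng.integers(1, 3))
    if spec.asymmetric:
        n_seg = 2
        lens = [rng.uniform(spec.min_segment_length, spec.max_segment_length),
                rng.uniform(*spec.short_length_range)]
        if rng.random() < 0.5:
            lens.reverse()
    else:
        lens = list(rng.uniform(spec.min_segment_length,
                                spec.max_segment_length, n_seg))
    ang = rng.uniform(0.0, 2 * np.pi)
    pts = [np.zeros(2)]
    for i, L in enumerate(lens):
        if i > 0:  # turn, avoiding near-straight and near-reversal angles
            ang += rng.choice([-1, 1]) * rng.uniform(np.pi / 6, 5 * np.pi / 6)
        pts.append(pts[-1] + L * np.array([np.cos(ang), np.sin(ang)]))
    return np.asarray(pts)


def sample_flankers(spec: FlankerSpec, forbidden, rng: np.random.Generator,
                    image_size: int = 256, margin: float = 16.0,
                    count: int | None = None,
                    clearance: float = 4.0) -> list[Polyline]:
    """Sample non-overlapping open flankers avoiding ``forbidden``.

    ``forbidden`` is a shapely geometry (the dilated footprint of the main
    contour) or None.  Flankers also keep ``clearance`` px from each other.
    Raises :class:`GenerationError` after a bounded number of retries.
    """
    if count is None:
        count = int(rng.integers(spec.count_range[0], spec.count_range[1] + 1))
    placed: list[Polyline] = []
    placed_geoms = []
    for _ in range(count):
        for attempt in range(_MAX_TRIES):
            chain = _flanker_chain(spec, rng)
            try:
                chain = _place(chain, image_size, margin, rng)
            except GenerationError:
                continue
            pl = Polyline(chain, closed=False)
            if not pl.is_simple():
                continue
            g = pl.to_shapely()
            if forbidden is not None and g.distance(forbidden) < clearance:
                continue
            if any(g.distance(pg) < clearance for pg in placed_geoms):
                continue
            placed.append(pl)
            placed_geoms.append(g)
            break
        else:
            raise GenerationError("flanker placement exhausted retries")
    return placed


def _curvy_open_flanker(rng: np.random.Generator) -> np.ndarray:
    """A small smooth open arc used by the curvy-open-flankers variant."""
    ring = _curvy_ring(32, rng.uniform(36.0, 64.0), 0.3, rng)
    k = int(rng.integers(32))
    frac = rng.uniform(0.4, 0.7)
    m = max(int(frac * 32), 4)
    idx = [(k + i) % 32 for i in range(m)]
    return ring[idx]


# ---------------------------------------------------------------------------
# Record / dataset generation
# ---------------------------------------------------------------------------

def _record_rng(seed: int, index: int, attempt: int = 0) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), int(index), int(attempt)]))


def generate_record(label: str, config: GeneratorConfig, seed: int, index: int,
                    variant_id: int = 0, render_image: bool = True) -> StimulusRecord:
    """Generate one stimulus (geometry + optional raster) deterministically.

    Over-crowded scene draws (placement exhaustion) are rejected and the
    whole scene is resampled from a derived stream, up to 10 times.
    """
    last_err: Exception | None = None
    for attempt in range(10):
        try:
            return _generate_record_once(label, config, seed, index, attempt,
                                         variant_id, render_image)
        except GenerationError as err:
            last_err = err
    raise GenerationError(f"record {index} unsatisfiable: {last_err}")


def _generate_record_once(label: str, config: GeneratorConfig, seed: int,
                          index: int, attempt: int, variant_id: int,
                          render_image: bool) -> StimulusRecord:
    rng = _record_rng(seed, index, attempt)
    n_seg = int(rng.integers(config.n_segments_range[0],
                             config.n_segments_range[1] + 1))
    diam = rng.uniform(*config.diameter_range)
    spec = MainContourSpec(n_segments=max(n_seg, 3), closed=(label == "closed"),
                           target_diameter=diam, open_gap_min=config.open_gap_min,
                           curvy=config.curvy, curvy_wiggle=config.curvy_wiggle)
    main = sample_main_contour(spec, rng, config.image_size, config.margin)
    forbidden = main.to_shapely().buffer(config.main_clearance
                                         + config.render.line_width)
    flankers = sample_flankers(config.flankers, forbidden, rng,
                               config.image_size, config.margin,
                               clearance=config.flanker_clearance)
    occupied = forbidden
    for f in flankers:
        occupied = occupied.union(f.to_shapely().buffer(config.flanker_clearance))

    extras: dict[str, list[Polyline]] = {}
    if config.dashed_closed_flanker:
        extras["dashed_closed_flanker"] = [
            _place_extra(_star_polygon(5, rng.uniform(40, 60), rng), True,
                         occupied, rng, config)]
    if config.n_curvy_open_flankers > 0:
        arcs = []
        for _ in range(config.n_curvy_open_flankers):
            arcs.append(_place_extra(_curvy_open_flanker(rng), False,
                                     occupied, rng, config))
            occupied = occupied.union(arcs[-1].to_shapely().buffer(
                config.flanker_clearance))
        extras["curvy_open_flankers"] = arcs

    image = None
    if render_image:
        image = render_stimulus(main, flankers, extras, config)
    gap = main.endpoint_separation
    return StimulusRecord(image=image, label=label, main=main,
                          flankers=flankers, extras=extras,
                          variant_id=variant_id, seed=seed, index=index,
                          gap=gap, render_cfg=config.render)


def _place_extra(vertices: np.ndarray, closed: bool, occupied,
                 rng: np.random.Generator, config: GeneratorConfig) -> Polyline:
    for _ in range(_MAX_TRIES):
        v = _place(vertices, config.image_size, config.margin, rng)
        pl = Polyline(v, closed=closed)
        if pl.to_shapely().distance(occupied) >= config.flanker_clearance:
            return pl
    raise GenerationError("extra-element placement exhausted retries")


def render_stimulus(main: Polyline, flankers: Sequence[Polyline],
                    extras: dict, config: GeneratorConfig) -> np.ndarray:
    """Rasterize one stimulus scene, honoring variant-specific styling."""
    groups = [([main, *flankers], config.render)]
    if "dashed_closed_flanker" in extras:
        groups.append((extras["dashed_closed_flanker"],
                       config.render.with_(dashed=(6.0, 6.0))))
    if "curvy_open_flankers" in extras:
        groups.append((extras["curvy_open_flankers"], config.render))
    return render_groups(groups, config.render)


def generate_dataset(n: int, class_balance: float = 0.5, seed: int = 0,
                     config: GeneratorConfig | None = None,
                     variant_id: int = 0, render_images: bool = True,
                     ) -> tuple[list[StimulusRecord], pd.DataFrame]:
    """Generate ``n`` stimuli with the given class balance.

    Identical arguments produce bitwise-identical images and manifest.
    Returns the records and a manifest table with one row per record.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    config = config or GeneratorConfig()
    n_closed = int(round(n * class_balance))
    labels = np.array(["closed"] * n_closed + ["open"] * (n - n_closed))
    np.random.default_rng(np.random.SeedSequence([int(seed), 0xBA1A])).shuffle(labels)
    records = [generate_record(lbl, config, seed, i, variant_id, render_images)
               for i, lbl in enumerate(labels)]
    manifest = pd.DataFrame([{
        "filename": f"stim_{variant_id:02d}_{r.index:06d}.png",
        "label": r.label, "variant_id": r.variant_id, "seed": r.seed,
        "n_segments": r.main.n_segments, "n_flankers": len(r.flankers),
        "gap": r.gap,
    } for r in records])
    return records, manifest


def write_dataset(records: Sequence[StimulusRecord], manifest: pd.DataFrame,
                  out_dir) -> None:
    """Write PNGs, a CSV manifest and a JSON geometry sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for r, fname in zip(records, manifest["filename"]):
        if r.image is None:
            raise ValueError("record has no rendered image")
        save_png(r.image, out / fname)
    manifest.to_csv(out / "manifest.csv", index=False)
    with open(out / "geometry.json", "w") as fh:
        json.dump([r.to_metadata() for r in records], fh)


# ---------------------------------------------------------------------------
# The 15 out-of-distribution variants
# ---------------------------------------------------------------------------

_BASE = GeneratorConfig()


def _v(name: str, **overrides) -> tuple[str, Callable[[], GeneratorConfig]]:
    return name, (lambda: _BASE.with_(**overrides))


VARIANTS: dict[int, tuple[str, Callable[[], GeneratorConfig]]] = {
    1: _v("curvy_contours", curvy=True, diameter_range=(70.0, 95.0)),
    2: _v("dashed_closed_flanker", dashed_closed_flanker=True),
    3: _v("curvy_contours_wiggly", curvy=True, curvy_wiggle=0.45,
          diameter_range=(70.0, 95.0)),
    4: _v("no_flankers", flankers=FlankerSpec(count_range=(0, 0))),
    5: _v("more_edges", n_segments_range=(10, 15)),
    6: _v("asymmetric_flankers",
          flankers=FlankerSpec(n_segments=2, asymmetric=True)),
    7: _v("curvy_open_flankers", n_curvy_open_flankers=3),
    8: _v("larger_contour", diameter_range=(176.0, 224.0)),
    9: _v("binarized",
          render=RenderConfig(antialias=False, background_value=255)),
    10: _v("thin_lines", render=RenderConfig(line_width=1.0)),
    11: _v("light_gray_lines", render=RenderConfig(line_value=64)),
    12: _v("white_lines", render=RenderConfig(line_value=255)),
    13: _v("thick_lines", render=RenderConfig(line_width=4.0)),
    14: _v("extra_thick_lines", render=RenderConfig(line_width=6.0)),
    15: _v("dashed_curvy_lines", curvy=True, diameter_range=(70.0, 95.0),
           render=RenderConfig(dashed=(7.0, 5.0))),
}


def variant_config(vc: VariantConfig) -> GeneratorConfig:
    """Resolve a VariantConfig to a full generator configuration.

    Non-overridden parameters equal the training distribution's.
    """
    _, builder = VARIANTS[vc.variant_id]
    cfg = builder()
    if vc.parameters:
        cfg = cfg.with_(**vc.parameters)
    return cfg


def generate_variant(vc: VariantConfig | int, n: int, seed: int = 0,
                     render_images: bool = True,
                     ) -> tuple[list[StimulusRecord], pd.DataFrame]:
    """Generate a dataset from one of the 15 o.o.d. variant distributions."""
    if isinstance(vc, int):
        vc = VariantConfig(vc)
    cfg = variant_config(vc)
    return generate_dataset(n, 0.5, seed, cfg, variant_id=vc.variant_id,
                            render_images=render_images)
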