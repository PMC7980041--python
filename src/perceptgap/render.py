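"""Grayscale rasterization of polylines.

The renderer is a small distance-field rasterizer: for every segment the
coverage of each nearby pixel is computed from the distance between the
pixel center and the segment, and per-pixel coverages are combined with a
maximum.  This gives exact control over line width, antialiasing and dash
patterns — the degrees of freedom the out-of-distribution variants
manipulate — while keeping rendering deterministic.

With ``antialias=False`` a pixel is either fully line or fully background,
so the raster contains exactly two gray levels.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
from PIL import Image

from .geometry import Polyline


@dataclass(frozen=True)
class RenderConfig:
    """Rasterization parameters.

    ``line_value`` / ``background_value`` are 8-bit gray levels; the default
    is black lines on a uniform mid-gray background.  ``dashed`` is an
    optional ``(on_len, off_len)`` pair in pixels of arc length.
    """

    image_size: int = 256
    line_value: int = 0
    background_value: int = 128
    line_width: float = 2.0
    antialias: bool = True
    dashed: tuple[float, float] | None = None

    def with_(self, **kw) -> "RenderConfig":
        return replace(self, **kw)


def _dash_segments(polyline: Polyline, on_len: float, off_len: float) -> np.ndarray:
    """Split a polyline into the 'on' pieces of a dash cycle.

    Returns an (m, 2, 2) array of sub-segments.  The dash phase runs
    continuously along the chain's arc length.
    """
    seg = polyline.segments()
    period = on_len + off_len
    pieces = []
    s0 = 0.0  # arc length at segment start
    for (p, q) in seg:
        L = float(np.hypot(*(q - p)))
        if L <= 0:
            continue
        u = (q - p) / L
        # on-intervals of the global dash cycle intersected with [s0, s0+L]
        k = int(np.floor(s0 / period))
        t = k * period
        while t < s0 + L:
            a = max(t, s0)
            b = min(t + on_len, s0 + L)
            if b > a:
                pieces.append([p + (a - s0) * u, p + (b - s0) * u])
            t += period
        s0 += L
    if not pieces:
        return np.zeros((0, 2, 2))
    return np.asarray(pieces)


def _accumulate_segment(cov: np.ndarray, p: np.ndarray, q: np.ndarray,
                        half_w: float, antialias: bool) -> None:
    """Max-combine one segment's coverage into ``cov`` (in place)."""
    n = cov.shape[0]
    pad = half_w + 1.5
    x0 = max(int(np.floor(min(p[0], q[0]) - pad)), 0)
    x1 = min(int(np.ceil(max(p[0], q[0]) + pad)) + 1, n)
    y0 = max(int(np.floor(min(p[1], q[1]) - pad)), 0)
    y1 = min(int(np.ceil(max(p[1], q[1]) + pad)) + 1, n)
    if x0 >= x1 or y0 >= y1:
        return
    ys, xs = np.mgrid[y0:y1, x0:x1]
    d = q - p
    L2 = float(d @ d)
    if L2 == 0:
        dist = np.hypot(xs - p[0], ys - p[1])
    else:
        t = ((xs - p[0]) * d[0] + (ys - p[1]) * d[1]) / L2
        t = np.clip(t, 0.0, 1.0)
        dist = np.hypot(xs - (p[0] + t * d[0]), ys - (p[1] + t * d[1]))
    if antialias:
        c = np.clip(half_w + 0.5 - dist, 0.0, 1.0)
    else:
        c = (dist <= half_w).astype(float)
    np.maximum(cov[y0:y1, x0:x1], c, out=cov[y0:y1, x0:x1])


def coverage_map(polylines: Iterable[Polyline], cfg: RenderConfig) -> np.ndarray:
    """Per-pixel line coverage in [0, 1] for a set of polylines."""
    cov = np.zeros((cfg.image_size, cfg.image_size), dtype=float)
    half_w = cfg.line_width / 2.0
    for pl in polylines:
        if not pl.within_canvas(cfg.image_size, margin=0.0):
            raise ValueError("polyline vertex outside canvas")
        if cfg.dashed is not None:
            pieces = _dash_segments(pl, *cfg.dashed)
        else:
            pieces = pl.segments()
        for (p, q) in pieces:
            _accumulate_segment(cov, p, q, half_w, cfg.antialias)
    return cov


def render(polylines: Sequence[Polyline], cfg: RenderConfig | None = None) -> np.ndarray:
    """Rasterize polylines to an 8-bit grayscale image.

    An empty polyline list yields a uniform image at ``background_value``.
    """
    cfg = cfg or RenderConfig()
    cov = coverage_map(polylines, cfg)
    img = cfg.background_value + (cfg.line_value - cfg.background_value) * cov
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def render_groups(groups: Sequence[tuple[Sequence[Polyline], RenderConfig]],
                  base_cfg: RenderConfig) -> np.ndarray:
    """Rasterize groups of polylines, each with its own render settings.

    Coverages are max-combined; gray levels (line/background) come from
    ``base_cfg``.  Used by variants where only some scene elements are
    dashed or restyled.
    """
    cov = np.zeros((base_cfg.image_size, base_cfg.image_size), dtype=float)
    for polylines, cfg in groups:
        if polylines:
            np.maximum(cov, coverage_map(polylines, cfg), out=cov)
    img = base_cfg.background_value + (base_cfg.line_value - base_cfg.background_value) * cov
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def line_mask(polylines: Sequence[Polyline], cfg: RenderConfig,
              threshold: float = 0.5) -> np.ndarray:
    """Boolean mask of pixels whose line coverage exceeds ``threshold``."""
    return coverage_map(polylines, cfg) > threshold


def save_png(image: np.ndarray, path) -> None:
    Image.fromarray(np.asarray(image, dtype=np.uint8), mode="L").save(path)


def load_image(path) -> np.ndarray:
    """Load a PNG/JPEG as 8-bit grayscale (RGB inputs are converted)."""
    with Image.open(path) as im:
        return np.asarray(im.convert("L"), dtype=np.uint8)
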