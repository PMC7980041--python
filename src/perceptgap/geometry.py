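"""Polyline primitives for procedural stimulus construction.

A :class:`Polyline` is an ordered chain of 2-D vertices in pixel
coordinates.  It is the universal geometric object of the package: main
contours (closed or open), flankers and blob outlines are all polylines.

Coordinate convention: origin at the top-left image corner, ``x`` grows
rightward, ``y`` grows downward, 0-based, pixel centers at integer
coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from shapely.geometry import LinearRing, LineString


@dataclass(frozen=True)
class Polyline:
    """An ordered vertex chain in pixel coordinates.

    Parameters
    ----------
    vertices : (n, 2) array of float
        Vertex coordinates ``(x, y)`` in pixels.  For a closed polyline the
        first vertex is *not* repeated: an implicit segment joins the last
        vertex back to the first.
    closed : bool
        Whether the implicit closing segment exists.
    """

    vertices: np.ndarray
    closed: bool = False

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 2:
            raise ValueError("vertices must be an (n>=2, 2) array")
        object.__setattr__(self, "vertices", v)
        if self.closed and v.shape[0] < 3:
            raise ValueError("a closed polyline needs at least 3 vertices")

    # -- basic measures -------------------------------------------------

    @property
    def n_segments(self) -> int:
        return self.vertices.shape[0] - 1 + (1 if self.closed else 0)

    def segments(self) -> np.ndarray:
        """Return segments as an (n_segments, 2, 2) array of endpoints."""
        v = self.vertices
        if self.closed:
            v = np.vstack([v, v[:1]])
        return np.stack([v[:-1], v[1:]], axis=1)

    def segment_lengths(self) -> np.ndarray:
        seg = self.segments()
        return np.linalg.norm(seg[:, 1] - seg[:, 0], axis=1)

    @property
    def length(self) -> float:
        return float(self.segment_lengths().sum())

    @property
    def endpoint_separation(self) -> float:
        """Euclidean distance between chain start and chain end.

        Under the closed convention the chain ends where it starts, so a
        closed polyline has separation exactly 0.
        """
        if self.closed:
            return 0.0
        return float(np.linalg.norm(self.vertices[-1] - self.vertices[0]))

    def bounding_box(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the vertex set."""
        v = self.vertices
        return (
            float(v[:, 0].min()),
            float(v[:, 1].min()),
            float(v[:, 0].max()),
            float(v[:, 1].max()),
        )

    @property
    def diameter(self) -> float:
        """Diameter of the vertex set (max pairwise vertex distance)."""
        v = self.vertices
        d2 = ((v[:, None, :] - v[None, :, :]) ** 2).sum(-1)
        return float(np.sqrt(d2.max()))

    def centroid(self) -> np.ndarray:
        return self.vertices.mean(axis=0)

    # -- predicates -----------------------------------------------------

    def is_simple(self) -> bool:
        """True when no two non-adjacent segments intersect."""
        if self.closed:
            return bool(LinearRing(self.vertices).is_simple)
        return bool(LineString(self.vertices).is_simple)

    def within_canvas(self, image_size: int, margin: float) -> bool:
        xmin, ymin, xmax, ymax = self.bounding_box()
        hi = image_size - 1 - margin
        return xmin >= margin and ymin >= margin and xmax <= hi and ymax <= hi

    def to_shapely(self):
        if self.closed:
            return LinearRing(self.vertices)
        return LineString(self.vertices)

    # -- transforms -----------------------------------------------------

    def translated(self, dx: float, dy: float) -> "Polyline":
        return Polyline(self.vertices + np.array([dx, dy]), self.closed)

    def scaled(self, factor: float, about: np.ndarray | None = None) -> "Polyline":
        c = self.centroid() if about is None else np.asarray(about, float)
        return Polyline(c + factor * (self.vertices - c), self.closed)

    def to_list(self) -> list[list[float]]:
        return [[float(x), float(y)] for x, y in self.vertices]

    @classmethod
    def from_list(cls, pts: list, closed: bool = False) -> "Polyline":
        return cls(np.asarray(pts, dtype=float), closed=closed)


def resample_arc(polyline: Polyline, n_points: int) -> np.ndarray:
    """Sample ``n_points`` equally spaced (by arc length) points on the chain."""
    v = polyline.vertices
    if polyline.closed:
        v = np.vstack([v, v[:1]])
    seg = np.linalg.norm(np.diff(v, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    t = np.linspace(0.0, s[-1], n_points)
    x = np.interp(t, s, v[:, 0])
    y = np.interp(t, s, v[:, 1])
    return np.stack([x, y], axis=1)


def min_distance(a: Polyline, b: Polyline) -> float:
    """Minimum Euclidean distance between two polylines (0 if they touch)."""
    return float(a.to_shapely().distance(b.to_shapely()))
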