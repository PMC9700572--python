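"""Planar polyline/contour primitives shared by every pipeline stage.

Coordinates are physical millimetres throughout, ``(x, y)`` with x rightward
and y downward (image convention). A closed polyline stores each vertex once;
the edge from the last vertex back to the first is implicit.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidContourError

__all__ = ["ContourPolyline", "polyline_segments", "is_simple_polyline"]


def _as_vertex_array(vertices) -> np.ndarray:
    arr = np.asarray(vertices, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise InvalidContourError(f"vertices must have shape (n, 2), got {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise InvalidContourError("vertices contain non-finite coordinates")
    return arr


@dataclass(frozen=True)
class ContourPolyline:
    """An ordered polyline in mm; closed by default (border contours).

    ``closed=False`` is permitted for degenerate test curves (e.g. a straight
    segment used as a fractal-dimension oracle); area is undefined for those.
    """

    vertices: np.ndarray
    closed: bool = True
    source: str = "generated"
    metadata: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        arr = _as_vertex_array(self.vertices)
        # collapse an explicitly repeated closing vertex
        if self.closed and len(arr) > 1 and np.array_equal(arr[0], arr[-1]):
            arr = arr[:-1]
        min_n = 3 if self.closed else 2
        if len(arr) < min_n:
            raise InvalidContourError(
                f"need at least {min_n} vertices, got {len(arr)}"
            )
        arr.setflags(write=False)
        object.__setattr__(self, "vertices", arr)

    # -- basic measures -------------------------------------------------
    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def segments(self) -> tuple[np.ndarray, np.ndarray]:
        return polyline_segments(self.vertices, self.closed)

    def perimeter(self) -> float:
        p, q = self.segments()
        return float(np.linalg.norm(q - p, axis=1).sum())

    def area(self) -> float:
        """Absolute shoelace area (closed contours only)."""
        if not self.closed:
            raise InvalidContourError("area undefined for an open polyline")
        x, y = self.vertices[:, 0], self.vertices[:, 1]
        return float(abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))) / 2.0)

    def bounds(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) in mm."""
        mn = self.vertices.min(axis=0)
        mx = self.vertices.max(axis=0)
        return float(mn[0]), float(mn[1]), float(mx[0]), float(mx[1])

    def centroid(self) -> tuple[float, float]:
        c = self.vertices.mean(axis=0)
        return float(c[0]), float(c[1])

    # -- transforms -----------------------------------------------------
    def translated(self, dx: float, dy: float) -> "ContourPolyline":
        return ContourPolyline(self.vertices + np.array([dx, dy]),
                               closed=self.closed, source=self.source,
                               metadata=dict(self.metadata))

    def scaled(self, k: float) -> "ContourPolyline":
        return ContourPolyline(self.vertices * float(k),
                               closed=self.closed, source=self.source,
                               metadata=dict(self.metadata))

    # -- validity -------------------------------------------------------
    def is_simple(self) -> bool:
        return is_simple_polyline(self.vertices, self.closed)

    def require_simple(self) -> "ContourPolyline":
        if not self.is_simple():
            raise InvalidContourError("contour is self-intersecting")
        return self


def polyline_segments(vertices: np.ndarray, closed: bool) -> tuple[np.ndarray, np.ndarray]:
    """Return (start, end) arrays of shape (m, 2) for all edges."""
    v = np.asarray(vertices, dtype=float)
    if closed:
        return v, np.roll(v, -1, axis=0)
    return v[:-1], v[1:]


def _cross(o, a, b):
    """z-component of (a-o) x (b-o); vectorized over leading axes."""
    return ((a[..., 0] - o[..., 0]) * (b[..., 1] - o[..., 1])
            - (a[..., 1] - o[..., 1]) * (b[..., 0] - o[..., 0]))


def _segments_intersect(p1, q1, p2, q2):
    """Boolean array: does segment (p1,q1) intersect (p2,q2) at any point?

    Touching at an endpoint counts as an intersection; callers exclude
    adjacent edge pairs themselves.
    """
    d1 = _cross(p2, q2, p1)
    d2 = _cross(p2, q2, q1)
    d3 = _cross(p1, q1, p2)
    d4 = _cross(p1, q1, q2)
    proper = ((d1 > 0) != (d2 > 0)) & ((d3 > 0) != (d4 > 0)) \
        & (d1 != 0) & (d2 != 0) & (d3 != 0) & (d4 != 0)

    def on_seg(p, q, r):
        return ((np.minimum(p[..., 0], q[..., 0]) <= r[..., 0])
                & (r[..., 0] <= np.maximum(p[..., 0], q[..., 0]))
                & (np.minimum(p[..., 1], q[..., 1]) <= r[..., 1])
                & (r[..., 1] <= np.maximum(p[..., 1], q[..., 1])))

    touch = ((d1 == 0) & on_seg(p2, q2, p1)) | ((d2 == 0) & on_seg(p2, q2, q1)) \
        | ((d3 == 0) & on_seg(p1, q1, p2)) | ((d4 == 0) & on_seg(p1, q1, q2))
    return proper | touch


def is_simple_polyline(vertices: np.ndarray, closed: bool = True,
                       _chunk: int = 512) -> bool:
    """Strict simplicity via pairwise segment tests (bbox-pruned, chunked).

    Non-adjacent edges must be disjoint; adjacent edges may share exactly
    their common vertex (no collinear doubling back). Zero-length edges make
    a polyline non-simple.
    """
    p, q = polyline_segments(vertices, closed)
    m = len(p)
    if m < 2:
        return True
    if np.any(np.all(p == q, axis=1)):
        return False

    # adjacent pairs: reject exact doubling back (collinear, opposite direction)
    d = q - p
    nxt = np.roll(d, -1, axis=0) if closed else d[1:]
    cur = d if closed else d[:-1]
    cross = cur[:, 0] * nxt[:, 1] - cur[:, 1] * nxt[:, 0]
    dot = (cur * nxt).sum(axis=1)
    if np.any((cross == 0) & (dot < 0)):
        return False

    xmin = np.minimum(p[:, 0], q[:, 0])
    xmax = np.maximum(p[:, 0], q[:, 0])
    ymin = np.minimum(p[:, 1], q[:, 1])
    ymax = np.maximum(p[:, 1], q[:, 1])

    idx = np.arange(m)
    for start in range(0, m, _chunk):
        sl = slice(start, min(start + _chunk, m))
        i = idx[sl][:, None]      # (ci, 1)
        j = idx[None, :]          # (1, m)
        cand = j > i + 1          # strictly non-adjacent, each pair once
        if closed:
            cand &= ~((i == 0) & (j == m - 1))  # wrap-around adjacency
        # bbox prune
        cand &= (xmin[sl][:, None] <= xmax[None, :]) & (xmin[None, :] <= xmax[sl][:, None])
        cand &= (ymin[sl][:, None] <= ymax[None, :]) & (ymin[None, :] <= ymax[sl][:, None])
        ii, jj = np.nonzero(cand)
        if len(ii) == 0:
            continue
        ii = ii + start
        if np.any(_segments_intersect(p[ii], q[ii], p[jj], q[jj])):
            return False
    return True
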