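"""Concave hulls, polygon overlap similarity, unions and centroids.

Cluster boundaries use the k-nearest-neighbour concave hull: a
gift-wrapping walk that, at each boundary vertex, considers only the k
nearest unused points, picks the candidate making the sharpest right-hand
turn whose edge keeps the polygon simple, and increases k when the walk
fails to close or leaves points outside.  The result "shrink-wraps" the
point set and never exceeds the convex hull's area.  No installed geometry
library exposes this construction, so the walk is implemented here; all
polygon boolean operations (intersection, union, area, centroid) are
delegated to shapely.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property
from typing import Iterable, Sequence

import numpy as np
import shapely
from shapely.geometry import LineString, MultiPoint, Point, Polygon

from .errors import DegenerateClusterError, DegenerateRegionError, ParameterError

__all__ = [
    "Hull",
    "Region",
    "concave_hull",
    "convex_hull",
    "overlap_similarity",
    "union_regions",
    "centroid",
    "degenerate_region",
]

# snap tolerance for boolean ops, px; suppresses sliver artifacts in unions
_GRID = 1e-9
_AREA_EPS = 1e-12


@dataclass(frozen=True)
class Hull:
    """A simple closed polygon bounding one cluster (vertices in px)."""

    vertices: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if len(self.vertices) < 3:
            raise DegenerateClusterError("a hull needs at least 3 vertices")

    @cached_property
    def polygon(self) -> Polygon:
        return Polygon(self.vertices)

    @property
    def area(self) -> float:
        return float(self.polygon.area)

    def as_region(self) -> "Region":
        return Region.from_shapely(self.polygon)


@dataclass(frozen=True)
class Region:
    """A positive-area union of one or more disjoint polygons."""

    geom: shapely.Geometry

    @staticmethod
    def from_shapely(geom: shapely.Geometry) -> "Region":
        if geom.is_empty or geom.area <= _AREA_EPS:
            raise DegenerateRegionError("region has zero area")
        return Region(geom)

    @property
    def area(self) -> float:
        return float(self.geom.area)

    @property
    def components(self) -> list[Polygon]:
        if isinstance(self.geom, Polygon):
            return [self.geom]
        return [g for g in self.geom.geoms if isinstance(g, Polygon)]

    def wkt(self) -> str:
        """Textual dump for debugging / visualization."""
        return self.geom.wkt


def _dedupe(points: np.ndarray) -> np.ndarray:
    seen: dict[tuple[float, float], None] = {}
    for p in points:
        seen.setdefault((float(p[0]), float(p[1])), None)
    return np.array(list(seen), dtype=float)


def _collinear(points: np.ndarray) -> bool:
    if len(points) < 3:
        return True
    p0 = points[0]
    v = points - p0
    cross = v[:, 0, None] * v[None, :, 1] - v[:, 1, None] * v[None, :, 0]
    return bool(np.all(np.abs(cross) < 1e-9))


def convex_hull(points: np.ndarray) -> Hull:
    """Convex hull as a :class:`Hull` (fallback boundary)."""
    hull = MultiPoint([tuple(p) for p in points]).convex_hull
    if not isinstance(hull, Polygon):
        raise DegenerateClusterError("points are collinear")
    return Hull(tuple(hull.exterior.coords)[:-1])


def _cross(o, a, b) -> float:
    return (a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0])


def _on_segment(p, q, r, eps=1e-12) -> bool:
    """r known collinear with pq: is it within the segment's bounding box?"""
    return (
        min(p[0], q[0]) - eps <= r[0] <= max(p[0], q[0]) + eps
        and min(p[1], q[1]) - eps <= r[1] <= max(p[1], q[1]) + eps
    )


def _segments_touch(a, b, c, d, eps=1e-12) -> bool:
    """Do closed segments [a,b] and [c,d] share any point?"""
    d1, d2 = _cross(c, d, a), _cross(c, d, b)
    d3, d4 = _cross(a, b, c), _cross(a, b, d)
    if ((d1 > eps and d2 < -eps) or (d1 < -eps and d2 > eps)) and (
        (d3 > eps and d4 < -eps) or (d3 < -eps and d4 > eps)
    ):
        return True
    if abs(d1) <= eps and _on_segment(c, d, a):
        return True
    if abs(d2) <= eps and _on_segment(c, d, b):
        return True
    if abs(d3) <= eps and _on_segment(a, b, c):
        return True
    if abs(d4) <= eps and _on_segment(a, b, d):
        return True
    return False


def _knn_hull(points: np.ndarray, k: int) -> list[int] | None:
    """One gift-wrapping attempt with k nearest neighbours; None on failure."""
    n = len(points)
    k = min(max(k, 3), n - 1)
    first = int(np.lexsort((points[:, 0], points[:, 1]))[0])  # lowest y, then x
    hull = [first]
    current = first
    prev_angle = 0.0
    used = np.zeros(n, dtype=bool)
    used[first] = True
    step = 2
    while True:
        if step == 4:
            used[first] = False  # hull may now close on the start vertex
        avail = np.flatnonzero(~used)
        if len(avail) == 0:
            return None
        dist = np.hypot(*(points[avail] - points[current]).T)
        nearest = avail[np.argsort(dist, kind="stable")[:k]]
        angles = np.arctan2(
            points[nearest, 1] - points[current, 1],
            points[nearest, 0] - points[current, 0],
        )
        # prev_angle points from current back to the previous vertex; the
        # largest counter-clockwise rotation from it hugs the boundary
        turn = np.mod(angles - prev_angle, 2.0 * np.pi)
        order = nearest[np.argsort(-turn, kind="stable")]

        chosen = -1
        for cand in order:
            closing = cand == first
            # the new edge may share endpoints only with its hull neighbours
            last_excluded = len(hull) - 1
            first_excluded = 0 if closing else -1
            ok = True
            for i in range(len(hull) - 1):
                if i == last_excluded - 1 or i == first_excluded:
                    continue
                if _segments_touch(
                    points[current], points[cand], points[hull[i]], points[hull[i + 1]]
                ):
                    ok = False
                    break
            if ok:
                chosen = int(cand)
                break
        if chosen < 0:
            return None
        if chosen == first:
            break
        hull.append(chosen)
        used[chosen] = True
        prev_angle = float(
            np.arctan2(
                points[current][1] - points[chosen][1],
                points[current][0] - points[chosen][0],
            )
        )
        current = chosen
        step += 1
        if len(hull) > n:
            return None
    if len(hull) < 3:
        return None
    return hull


def concave_hull(points: Iterable[Sequence[float]], k0: int = 3) -> Hull:
    """Concave hull of a point set via the k-nearest-neighbour walk.

    Starts at ``k = k0`` and increments k until the walk yields a simple
    polygon containing every input point; at ``k = n`` the convex hull is
    returned.  Duplicated points are collapsed first.

    Raises
    ------
    DegenerateClusterError
        For fewer than 3 distinct points or an all-collinear set; callers
        should substitute a buffered point or segment
        (:func:`degenerate_region`).
    """
    pts = _dedupe(np.asarray(list(points), dtype=float).reshape(-1, 2))
    if len(pts) < 3 or _collinear(pts):
        raise DegenerateClusterError(
            f"cannot bound {len(pts)} distinct point(s) with a polygon"
        )
    if len(pts) == 3:
        return Hull(tuple((float(x), float(y)) for x, y in pts))
    for k in range(max(3, k0), len(pts)):
        idx = _knn_hull(pts, k)
        if idx is None:
            continue
        poly = Polygon(pts[idx])
        if not (poly.is_valid and poly.area > _AREA_EPS):
            continue
        padded = poly.buffer(1e-9)
        if all(padded.covers(Point(*p)) for p in pts):
            return Hull(tuple((float(x), float(y)) for x, y in pts[idx]))
    return convex_hull(pts)


def degenerate_region(points: Iterable[Sequence[float]], pad: float = 1.0) -> Region:
    """Positive-area stand-in for a cluster too thin to hull.

    A single point becomes a disc, a pair or collinear set a padded
    segment; ``pad`` is the buffer radius in px.
    """
    pts = _dedupe(np.asarray(list(points), dtype=float).reshape(-1, 2))
    if len(pts) == 0:
        raise ParameterError("no points to buffer")
    if len(pts) == 1:
        geom = Point(*pts[0]).buffer(pad)
    else:
        order = np.lexsort((pts[:, 1], pts[:, 0]))
        geom = LineString(pts[order]).buffer(pad)
    return Region.from_shapely(geom)


def _snapped(geom: shapely.Geometry) -> shapely.Geometry:
    return shapely.set_precision(geom, _GRID, mode="pointwise")


def overlap_similarity(p: Region, q: Region) -> float:
    """Intersection-over-union of two regions' areas, in [0, 1]."""
    if p.area <= _AREA_EPS or q.area <= _AREA_EPS:
        raise DegenerateRegionError("overlap similarity undefined for zero area")
    a, b = _snapped(p.geom), _snapped(q.geom)
    inter = float(shapely.intersection(a, b).area)
    union = float(shapely.union(a, b).area)
    return min(1.0, max(0.0, inter / union))


def union_regions(regions: Sequence[Region]) -> Region:
    """Set-theoretic union of regions (may be disconnected)."""
    if len(regions) == 0:
        raise ParameterError("union of an empty region sequence")
    return Region.from_shapely(shapely.union_all([_snapped(r.geom) for r in regions]))


def centroid(region: Region) -> tuple[float, float]:
    """Area-weighted geometric centre; may fall outside a ring-like region."""
    if region.area <= _AREA_EPS:
        raise DegenerateRegionError("centroid undefined for zero area")
    c = region.geom.centroid
    return float(c.x), float(c.y)
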