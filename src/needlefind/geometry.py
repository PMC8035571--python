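"""2D line geometry for needle-axis estimation.

All geometry lives in millimetre coordinates (pixel indices are converted to
mm once, at ingest, using the slice pixel spacing).  A needle axis is an
*undirected* line, represented by an anchor point and a sign-normalised unit
direction; directedness (entry vs tip) is restored later by tip localisation.

Coordinate convention: 0-based pixel indices, pixel-centre convention,
x = column * col_spacing, y = row * row_spacing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

__all__ = [
    "Point2D",
    "LineModel",
    "PointSet",
    "point_line_distance",
    "fit_line_pca",
    "angular_deviation",
    "tip_deviation",
]


class Point2D(NamedTuple):
    """A point in millimetre coordinates."""

    x: float
    y: float


def _normalize_direction(d: np.ndarray) -> np.ndarray:
    d = np.asarray(d, dtype=float)
    norm = np.linalg.norm(d)
    if not np.isfinite(norm) or norm == 0.0:
        raise ValueError("line direction must be a nonzero finite vector")
    d = d / norm
    # Sign convention: first component with magnitude above tolerance is
    # positive, so that equal undirected lines compare equal.
    if d[0] < -1e-12 or (abs(d[0]) <= 1e-12 and d[1] < 0):
        d = -d
    return d


@dataclass(frozen=True)
class LineModel:
    """An undirected 2D line: ``anchor + t * direction``, ``t`` in mm."""

    anchor: Point2D
    direction: tuple[float, float]

    def __post_init__(self) -> None:
        a = np.asarray(self.anchor, dtype=float)
        if not np.all(np.isfinite(a)):
            raise ValueError("anchor must be finite")
        d = _normalize_direction(np.asarray(self.direction, dtype=float))
        object.__setattr__(self, "anchor", Point2D(float(a[0]), float(a[1])))
        object.__setattr__(self, "direction", (float(d[0]), float(d[1])))

    @property
    def normal(self) -> np.ndarray:
        """Unit normal (perpendicular to the direction)."""
        dx, dy = self.direction
        return np.array([-dy, dx])

    def point_at(self, t: float | np.ndarray):
        """Point(s) at arc-length ``t`` from the anchor, in mm."""
        a = np.asarray(self.anchor, dtype=float)
        d = np.asarray(self.direction, dtype=float)
        t = np.asarray(t, dtype=float)
        pts = a + np.multiply.outer(t, d)
        if pts.ndim == 1:
            return Point2D(float(pts[0]), float(pts[1]))
        return pts

    @classmethod
    def through(cls, p: Point2D, q: Point2D) -> "LineModel":
        """The line through two distinct points."""
        p = np.asarray(p, dtype=float)
        q = np.asarray(q, dtype=float)
        return cls(Point2D(*p), tuple(q - p))


@dataclass
class PointSet:
    """Candidate needle points in mm with optional per-point intensity.

    Indices are stable: operations that subset a PointSet report index sets
    into the original ordering rather than re-ordering points.
    """

    xy: np.ndarray
    intensity: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.xy = np.atleast_2d(np.asarray(self.xy, dtype=float))
        if self.xy.size == 0:
            self.xy = self.xy.reshape(0, 2)
        if self.xy.shape[1] != 2:
            raise ValueError("xy must be an (N, 2) array")
        if self.intensity is not None:
            self.intensity = np.asarray(self.intensity, dtype=float)
            if self.intensity.shape != (len(self.xy),):
                raise ValueError("intensity must have one value per point")

    def __len__(self) -> int:
        return len(self.xy)

    def subset(self, indices) -> "PointSet":
        idx = np.asarray(indices)
        inten = None if self.intensity is None else self.intensity[idx]
        return PointSet(self.xy[idx], inten)

    def point(self, i: int) -> Point2D:
        return Point2D(float(self.xy[i, 0]), float(self.xy[i, 1]))


def point_line_distance(p, line: LineModel) -> float | np.ndarray:
    """Perpendicular distance (mm) from point(s) ``p`` to ``line``.

    ``p`` may be a single point or an (N, 2) array; the result is then a
    scalar or an (N,) array respectively.
    """
    pts = np.asarray(p, dtype=float)
    a = np.asarray(line.anchor, dtype=float)
    d = np.asarray(line.direction, dtype=float)
    rel = pts - a
    cross = rel[..., 0] * d[1] - rel[..., 1] * d[0]
    dist = np.abs(cross)
    if dist.ndim == 0:
        return float(dist)
    return dist


def fit_line_pca(points: PointSet | np.ndarray) -> LineModel:
    """Total-least-squares line fit: centroid anchor, first principal axis.

    Minimises the sum of squared *orthogonal* distances.  Raises ValueError
    for fewer than two points or an all-coincident cloud.  For an exactly
    isotropic cloud (equal principal variances) the tie is broken
    deterministically in favour of the axis closer to the x-axis.
    """
    xy = points.xy if isinstance(points, PointSet) else np.atleast_2d(np.asarray(points, float))
    if len(xy) < 2:
        raise ValueError("need at least 2 points to fit a line")
    centroid = xy.mean(axis=0)
    rel = xy - centroid
    cov = rel.T @ rel
    if not np.any(np.abs(rel) > 1e-12):
        raise ValueError("all points coincident; line fit is degenerate")
    evals, evecs = np.linalg.eigh(cov)
    # eigh sorts ascending; the principal axis is the last column.
    if abs(evals[1] - evals[0]) <= 1e-12 * max(abs(evals[1]), 1.0):
        direction = np.array([1.0, 0.0])  # isotropic tie-break: x-axis
    else:
        direction = evecs[:, 1]
    return LineModel(Point2D(*centroid), tuple(direction))


def angular_deviation(a: LineModel, b: LineModel) -> float:
    """Angle in degrees between two undirected axes, folded into [0, 90].

    The fold uses the absolute dot product: a needle axis has no intrinsic
    direction sign, so (1, 0) vs (-1, 0.001) is ~0.06 deg, not ~180 deg.
    Symmetric in its arguments.
    """
    da = np.asarray(a.direction, dtype=float)
    db = np.asarray(b.direction, dtype=float)
    c = abs(float(np.dot(da, db)))
    return float(np.degrees(np.arccos(min(c, 1.0))))


def tip_deviation(p1, p2) -> float:
    """Euclidean distance (mm) between two tip positions on the slice."""
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    return float(np.hypot(*(p1 - p2)))
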