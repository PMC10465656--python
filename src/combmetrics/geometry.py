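"""Stimulus-to-wall geometric metrics.

Four operators relate a stimulus to the walls bees built on a tab:

* **rim overlap** — total arc (degrees) of a pit's 4.0 mm gauge circle that
  lies within a tolerance band of any built wall;
* **tangent divergence** — angular difference between a wall and the common
  tangent of a pit pair (the line orthogonal to the centre-centre line);
* **bisection divergence** — angular difference between a wall and the
  internal bisector of a V-shaped strip;
* **proximity ratio** — P = d1/(d1+d2), where d1 and d2 are distances from
  the V apex to the nearest and next-nearest built-wall corners.

All coordinates are world millimetres (image convention: x right, y down);
angles are clockwise from horizontal, undirected orientations reduced
mod 180 deg.  The rim-overlap arcs are computed analytically as the
intersection of the gauge circle with the capsule-shaped proximity band of
each wall segment, not by sampling.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

log = logging.getLogger(__name__)

DEFAULT_GAUGE_DIAMETER_MM = 4.0
# half of a natural wall thickness; the band within which a rim point is
# counted as coincident with a wall
DEFAULT_OVERLAP_TOL_MM = 0.35


class GeometryError(ValueError):
    """Degenerate geometric input."""


def _xy(p) -> np.ndarray:
    """Accept a PlanarPoint, tuple or array; return a float (2,) array."""
    if hasattr(p, "xy"):
        p = p.xy
    a = np.asarray(p, dtype=float)
    if a.shape != (2,):
        raise GeometryError(f"expected a 2-D point, got shape {a.shape}")
    if not np.all(np.isfinite(a)):
        raise GeometryError("non-finite point")
    return a


# ---------------------------------------------------------------------------
# Angular utilities
# ---------------------------------------------------------------------------

def norm180(angle_deg: float) -> float:
    """Reduce an angle to the undirected-orientation range [0, 180)."""
    a = float(angle_deg) % 180.0
    return 0.0 if a == 180.0 else a


def angular_divergence(a_deg: float, b_deg: float) -> float:
    """Smallest angle (degrees, in [0, 90]) between two undirected orientations.

    Symmetric and invariant to adding any multiple of 180 deg to either
    argument.
    """
    d = abs(norm180(a_deg) - norm180(b_deg))
    return min(d, 180.0 - d)


def direction_angle(origin, tip) -> float:
    """Clockwise-from-horizontal angle (deg, [0, 360)) of the ray origin->tip."""
    o, t = _xy(origin), _xy(tip)
    d = t - o
    if np.hypot(*d) < 1e-12:
        raise GeometryError("zero-length direction")
    # y grows downward, so atan2(dy, dx) is the clockwise screen angle
    return math.degrees(math.atan2(d[1], d[0])) % 360.0


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PitStimulus:
    """A single nascent-cell pit with its measurement gauge circle."""

    centre: tuple[float, float]
    gauge_diameter_mm: float = DEFAULT_GAUGE_DIAMETER_MM

    def __post_init__(self) -> None:
        object.__setattr__(self, "centre", tuple(_xy(self.centre)))
        if not self.gauge_diameter_mm > 0:
            raise GeometryError("gauge diameter must be positive")

    @property
    def radius(self) -> float:
        return self.gauge_diameter_mm / 2.0


@dataclass(frozen=True)
class PitPairStimulus:
    """Two pits whose shared wall is predicted along their common tangent."""

    centre_a: tuple[float, float]
    centre_b: tuple[float, float]

    def __post_init__(self) -> None:
        a, b = _xy(self.centre_a), _xy(self.centre_b)
        object.__setattr__(self, "centre_a", tuple(a))
        object.__setattr__(self, "centre_b", tuple(b))
        if np.hypot(*(a - b)) < 1e-12:
            raise GeometryError("pit-pair centres coincide")

    @property
    def separation(self) -> float:
        return float(np.hypot(*(np.subtract(self.centre_b, self.centre_a))))

    @property
    def midpoint(self) -> tuple[float, float]:
        return tuple((np.asarray(self.centre_a) + self.centre_b) / 2.0)


@dataclass(frozen=True)
class VStimulus:
    """A V-shaped strip: two arms meeting at an apex."""

    end_a: tuple[float, float]
    apex: tuple[float, float]
    end_b: tuple[float, float]

    def __post_init__(self) -> None:
        a, p, b = _xy(self.end_a), _xy(self.apex), _xy(self.end_b)
        object.__setattr__(self, "end_a", tuple(a))
        object.__setattr__(self, "apex", tuple(p))
        object.__setattr__(self, "end_b", tuple(b))
        if np.hypot(*(a - p)) < 1e-12 or np.hypot(*(b - p)) < 1e-12:
            raise GeometryError("V arm end coincides with apex")


@dataclass(frozen=True)
class WallSegment:
    """An undirected built-wall segment."""

    p1: tuple[float, float]
    p2: tuple[float, float]
    wall_id: str = ""

    def __post_init__(self) -> None:
        a, b = _xy(self.p1), _xy(self.p2)
        object.__setattr__(self, "p1", tuple(a))
        object.__setattr__(self, "p2", tuple(b))
        if np.hypot(*(a - b)) < 1e-12:
            raise GeometryError(f"zero-length wall segment {self.wall_id!r}")

    @property
    def length(self) -> float:
        return float(np.hypot(*(np.subtract(self.p2, self.p1))))

    @property
    def midpoint(self) -> tuple[float, float]:
        return tuple((np.asarray(self.p1) + self.p2) / 2.0)


def undirected_orientation(w: WallSegment) -> float:
    """Orientation of a wall in [0, 180), clockwise from horizontal."""
    return norm180(direction_angle(w.p1, w.p2))


def segment_point_distance(w: WallSegment, p) -> float:
    """Euclidean distance from a point to the closed segment."""
    a, b, q = _xy(w.p1), _xy(w.p2), _xy(p)
    d = b - a
    t = float(np.dot(q - a, d) / np.dot(d, d))
    t = min(1.0, max(0.0, t))
    return float(np.hypot(*(a + t * d - q)))


# ---------------------------------------------------------------------------
# Arc sets on the gauge circle
# ---------------------------------------------------------------------------

@dataclass
class ArcSet:
    """Disjoint, normalized arc intervals [start, end) in degrees on a circle.

    Intervals are stored with start in [0, 360); an interval crossing 0 is
    split.  ``FULL`` is represented as the single interval [0, 360).
    """

    intervals: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.intervals = self._normalize(self.intervals)

    @staticmethod
    def _normalize(intervals) -> list[tuple[float, float]]:
        pieces: list[tuple[float, float]] = []
        for s, e in intervals:
            if e - s >= 360.0 - 1e-12:
                return [(0.0, 360.0)]
            if e <= s:
                continue
            s_m = s % 360.0
            if s_m >= 360.0:  # float rounding of tiny negative starts
                s_m = 0.0
            span = e - s
            if s_m + span <= 360.0:
                pieces.append((s_m, s_m + span))
            else:
                if 360.0 > s_m:
                    pieces.append((s_m, 360.0))
                if s_m + span - 360.0 > 0.0:
                    pieces.append((0.0, s_m + span - 360.0))
        if not pieces:
            return []
        pieces.sort()
        merged = [list(pieces[0])]
        for s, e in pieces[1:]:
            if s <= merged[-1][1] + 1e-12:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        # merge across the 0/360 seam
        if len(merged) > 1 and merged[0][0] <= 1e-12 and merged[-1][1] >= 360.0 - 1e-12:
            merged[0][0] = merged[-1][0] - 360.0
            merged.pop()
            s, e = merged[0]
            if e - s >= 360.0 - 1e-12:
                return [(0.0, 360.0)]
            merged[0] = [s % 360.0, s % 360.0 + (e - s)]
            if merged[0][1] > 360.0:
                merged = [[merged[0][0], 360.0], [0.0, merged[0][1] - 360.0]] + merged[1:]
                merged.sort()
        return [(float(s), float(e)) for s, e in merged]

    @classmethod
    def full(cls) -> "ArcSet":
        return cls([(0.0, 360.0)])

    @classmethod
    def empty(cls) -> "ArcSet":
        return cls([])

    @property
    def total_degrees(self) -> float:
        return float(sum(e - s for s, e in self.intervals))

    def contains(self, angle_deg: float) -> bool:
        a = angle_deg % 360.0
        return any(s - 1e-9 <= a < e + 1e-9 for s, e in self.intervals)

    def union(self, other: "ArcSet") -> "ArcSet":
        return ArcSet(self.intervals + other.intervals)

    def intersection(self, other: "ArcSet") -> "ArcSet":
        out = []
        for s1, e1 in self.intervals:
            for s2, e2 in other.intervals:
                s, e = max(s1, s2), min(e1, e2)
                if e > s:
                    out.append((s, e))
        return ArcSet(out)


def _halfplane_arc(centre: np.ndarray, radius: float, n: np.ndarray, c: float) -> ArcSet:
    """Arcs of the circle lying in the half-plane {p : n.p <= c} (|n| = 1)."""
    s = float(np.dot(n, centre) - c)
    if s <= -radius:
        return ArcSet.full()
    if s >= radius:
        return ArcSet.empty()
    phi = math.degrees(math.atan2(n[1], n[0]))
    alpha = math.degrees(math.acos(max(-1.0, min(1.0, -s / radius))))
    # points with cos(theta - phi) <= -s/r : theta in [phi + alpha, phi + 360 - alpha]
    return ArcSet([(phi + alpha, phi + 360.0 - alpha)])


def _disc_arc(centre: np.ndarray, radius: float, q: np.ndarray, r: float) -> ArcSet:
    """Arcs of the circle lying within distance r of point q."""
    v = q - centre
    D = float(np.hypot(*v))
    if D < 1e-12:
        return ArcSet.full() if r >= radius else ArcSet.empty()
    k = (radius * radius + D * D - r * r) / (2.0 * radius * D)
    if k <= -1.0:
        return ArcSet.full()
    if k >= 1.0:
        return ArcSet.empty()
    phi = math.degrees(math.atan2(v[1], v[0]))
    beta = math.degrees(math.acos(k))
    return ArcSet([(phi - beta, phi + beta)])


def _capsule_arcs(centre: np.ndarray, radius: float, w: WallSegment, tol: float) -> ArcSet:
    """Arcs of the gauge circle within ``tol`` of the segment (capsule test)."""
    a, b = np.asarray(w.p1), np.asarray(w.p2)
    u = b - a
    L = float(np.hypot(*u))
    u = u / L
    n = np.array([-u[1], u[0]])
    # strip of half-width tol around the infinite line, cut to the segment span
    strip = _halfplane_arc(centre, radius, n, float(np.dot(n, a)) + tol)
    strip = strip.intersection(_halfplane_arc(centre, radius, -n, -float(np.dot(n, a)) + tol))
    strip = strip.intersection(_halfplane_arc(centre, radius, u, float(np.dot(u, b))))
    strip = strip.intersection(_halfplane_arc(centre, radius, -u, -float(np.dot(u, a))))
    # end caps
    caps = _disc_arc(centre, radius, a, tol).union(_disc_arc(centre, radius, b, tol))
    return strip.union(caps)


def rim_wall_overlap(pit: PitStimulus, walls, tol_mm: float = DEFAULT_OVERLAP_TOL_MM) -> ArcSet:
    """Total angular overlap between a pit's gauge circle and built walls.

    A gauge-circle point overlaps a wall when it lies within ``tol_mm`` of
    the wall polyline.  The arcs are the exact intersection of the circle
    with each wall's capsule-shaped proximity band, merged across walls.
    An empty wall list yields an empty arc set (total 0 deg), not an error.
    """
    if not tol_mm > 0:
        raise GeometryError("tol_mm must be positive")
    centre = np.asarray(pit.centre)
    out = ArcSet.empty()
    for w in walls:
        # cheap rejects: capsule entirely outside or entirely inside the circle
        if segment_point_distance(w, centre) > pit.radius + tol_mm:
            continue
        far = max(np.hypot(*(np.asarray(w.p1) - centre)),
                  np.hypot(*(np.asarray(w.p2) - centre)))
        if far + tol_mm < pit.radius:
            continue
        out = out.union(_capsule_arcs(centre, pit.radius, w, tol_mm))
    return out


# ---------------------------------------------------------------------------
# Pair / V operators
# ---------------------------------------------------------------------------

def common_tangent_orientation(p: PitPairStimulus) -> float:
    """Orientation (deg, [0,180)) perpendicular to the centre-centre line."""
    line = direction_angle(p.centre_a, p.centre_b)
    return norm180(line + 90.0)


def bisection_orientation(v: VStimulus) -> float:
    """Orientation (deg, [0,180)) of the internal-angle bisector at the apex."""
    apex = np.asarray(v.apex)
    da = np.asarray(v.end_a) - apex
    db = np.asarray(v.end_b) - apex
    da = da / np.hypot(*da)
    db = db / np.hypot(*db)
    bis = da + db
    if np.hypot(*bis) < 1e-9:
        raise GeometryError("degenerate V: arms are opposite (splay 180 deg)")
    return norm180(math.degrees(math.atan2(bis[1], bis[0])))


def splay_angle(v: VStimulus) -> float:
    """Internal angle (deg, (0, 180)) between the two arms at the apex."""
    apex = np.asarray(v.apex)
    da = np.asarray(v.end_a) - apex
    db = np.asarray(v.end_b) - apex
    c = float(np.dot(da, db) / (np.hypot(*da) * np.hypot(*db)))
    ang = math.degrees(math.acos(max(-1.0, min(1.0, c))))
    if ang <= 1e-9 or ang >= 180.0 - 1e-9:
        raise GeometryError(f"degenerate V splay ({ang:.3f} deg)")
    return ang


def wall_between_centres(p: PitPairStimulus, w: WallSegment) -> bool:
    """Fig-style exclusion test for pit pairs.

    True iff the infinite line through the wall crosses the *open* segment
    between the two pit centres; measurements whose nearest wall fails this
    are excluded from the pair analysis.  The infinite line is used (rather
    than the finite segment) because marked walls may be offset along their
    own axis.
    """
    a, b = np.asarray(w.p1), np.asarray(w.p2)
    d = b - a
    ca = np.asarray(p.centre_a) - a
    cb = np.asarray(p.centre_b) - a
    s1 = d[0] * ca[1] - d[1] * ca[0]
    s2 = d[0] * cb[1] - d[1] * cb[0]
    return bool(s1 * s2 < 0.0)


def corner_distance(apex, w: WallSegment) -> float:
    """Distance from a point to the nearer marked endpoint ("corner") of a wall."""
    q = _xy(apex)
    return min(float(np.hypot(*(np.asarray(w.p1) - q))),
               float(np.hypot(*(np.asarray(w.p2) - q))))


def nearest_wall_corners(apex, walls) -> tuple[float, float, tuple[int, int]]:
    """Distances from the apex to the two nearest distinct walls' corners.

    Returns ``(d1, d2, (i1, i2))`` with d1 <= d2 and i1, i2 the indices of
    the two walls in input order.  Ties are broken by input order (logged).
    """
    walls = list(walls)
    if len(walls) < 2:
        raise GeometryError("nearest_wall_corners needs at least 2 walls")
    dists = [(corner_distance(apex, w), i) for i, w in enumerate(walls)]
    dists.sort()  # ties fall back to index order
    (d1, i1), (d2, i2) = dists[0], dists[1]
    if d1 == d2:
        log.info("corner-distance tie (%.6f mm); broken by wall order (%d, %d)", d1, i1, i2)
    return d1, d2, (i1, i2)


def proximity_ratio(d1: float, d2: float) -> float:
    """P = d1/(d1+d2) for 0 <= d1 <= d2; P in (0, 0.5], small P = wall at apex."""
    if d1 > d2:
        raise GeometryError(f"proximity_ratio requires d1 <= d2 (got {d1} > {d2})")
    if d2 <= 0:
        raise GeometryError("proximity_ratio requires d2 > 0")
    if d1 == 0.0:
        log.warning("d1 = 0: wall corner exactly at the apex; P = 0 boundary")
        return 0.0
    return d1 / (d1 + d2)


__all__ = [
    "GeometryError", "PitStimulus", "PitPairStimulus", "VStimulus",
    "WallSegment", "ArcSet", "norm180", "angular_divergence",
    "direction_angle", "undirected_orientation", "segment_point_distance",
    "rim_wall_overlap", "common_tangent_orientation", "bisection_orientation",
    "splay_angle", "wall_between_centres", "corner_distance",
    "nearest_wall_corners", "proximity_ratio",
    "DEFAULT_GAUGE_DIAMETER_MM", "DEFAULT_OVERLAP_TOL_MM",
]
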