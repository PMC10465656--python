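"""Projective registration of the before/after photograph pair.

The photographic jig held each frame approximately in place, but not well
enough to compare wax features at the cell-wall scale across photographs.
Four landmarks visible in both images determine a plane projective map
(homography) exactly; applying it to marked points removes scale,
displacement, rotation and perspective change between the two photographs.
No pixels are resampled for measurement — the map is applied to landmark
coordinates only.  Optional image warping exists for visual checks.
"""

from __future__ import annotations

import logging
import math

import numpy as np

from .annotations import AlignmentPair, PlanarPoint

log = logging.getLogger(__name__)

# condition number above which the 4-point configuration is reported as
# nearly degenerate (points close to collinear or coincident)
COND_WARN = 1e8


class DegenerateConfigurationError(ValueError):
    """Alignment landmarks do not determine a projective map."""


class Homography:
    """A 3x3 projective map between two coordinate frames.

    The matrix is normalized so the bottom-right entry is 1.  ``src_frame``
    and ``dst_frame`` are carried along so that applying the map retags the
    point's frame.
    """

    def __init__(self, matrix, src_frame: str | None = None, dst_frame: str | None = None):
        m = np.asarray(matrix, dtype=float)
        if m.shape != (3, 3):
            raise ValueError(f"homography matrix must be 3x3, got {m.shape}")
        if not np.all(np.isfinite(m)):
            raise DegenerateConfigurationError("non-finite homography matrix")
        if abs(m[2, 2]) < 1e-300:
            raise DegenerateConfigurationError("cannot normalize: H[2,2] ~ 0")
        self.matrix = m / m[2, 2]
        self.src_frame = src_frame
        self.dst_frame = dst_frame
        if abs(np.linalg.det(self.matrix)) < 1e-12:
            raise DegenerateConfigurationError("homography is singular")

    def __repr__(self) -> str:
        return f"Homography({self.matrix.tolist()}, {self.src_frame!r} -> {self.dst_frame!r})"

    # -- projective action ---------------------------------------------------

    def apply_xy(self, xy) -> np.ndarray:
        """Apply to an (n, 2) or (2,) array of coordinates."""
        pts = np.atleast_2d(np.asarray(xy, dtype=float))
        ones = np.ones((pts.shape[0], 1))
        hom = np.hstack([pts, ones]) @ self.matrix.T
        w = hom[:, 2]
        if np.any(np.abs(w) < 1e-12):
            raise DegenerateConfigurationError("point maps to infinity (zero denominator)")
        out = hom[:, :2] / w[:, None]
        return out[0] if np.asarray(xy).ndim == 1 else out

    def apply(self, p: PlanarPoint) -> PlanarPoint:
        """Map a single tagged point, switching its frame tag."""
        if self.src_frame is not None and p.frame != self.src_frame:
            raise ValueError(f"point frame {p.frame!r} does not match map source {self.src_frame!r}")
        x, y = self.apply_xy((p.x, p.y))
        return PlanarPoint(float(x), float(y), self.dst_frame or p.frame)

    def invert(self) -> "Homography":
        return Homography(np.linalg.inv(self.matrix), self.dst_frame, self.src_frame)

    def compose(self, other: "Homography") -> "Homography":
        """self o other: apply ``other`` first, then ``self``."""
        return Homography(self.matrix @ other.matrix, other.src_frame, self.dst_frame)

    @classmethod
    def identity(cls, frame: str | None = None) -> "Homography":
        return cls(np.eye(3), frame, frame)


def _check_not_collinear(pts: np.ndarray, label: str) -> None:
    n = len(pts)
    for i in range(n):
        for j in range(i + 1, n):
            if np.hypot(*(pts[i] - pts[j])) < 1e-9:
                raise DegenerateConfigurationError(f"duplicate {label} points {i} and {j}")
            for k in range(j + 1, n):
                a, b, c = pts[i], pts[j], pts[k]
                area2 = abs((b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0]))
                # triangle area relative to the span of the three points
                scale = max(np.hypot(*(b - a)), np.hypot(*(c - a)), 1e-12)
                if area2 / scale < 1e-7:
                    raise DegenerateConfigurationError(
                        f"{label} points {i}, {j}, {k} are (nearly) collinear"
                    )


def estimate_homography(pairs, src_frame: str | None = None,
                        dst_frame: str | None = None) -> Homography:
    """Solve the projective map defined exactly by 4 point correspondences.

    ``pairs`` is a sequence of 4 ``AlignmentPair`` objects or of
    ``((x, y), (u, v))`` source/target coordinate pairs.  With exactly four
    correspondences the 8 projective degrees of freedom are determined by a
    direct 8x8 linear solve; no least-squares estimation is involved, so the
    map interpolates its defining landmarks to machine precision.
    """
    pairs = list(pairs)
    if len(pairs) != 4:
        raise ValueError(f"4 alignment points required, got {len(pairs)}")
    src, dst = [], []
    for pr in pairs:
        if isinstance(pr, AlignmentPair):
            src.append(pr.before.xy)
            dst.append(pr.after.xy)
            src_frame = src_frame or pr.before.frame
            dst_frame = dst_frame or pr.after.frame
        else:
            s, d = pr
            src.append((float(s[0]), float(s[1])))
            dst.append((float(d[0]), float(d[1])))
    src_a = np.asarray(src)
    dst_a = np.asarray(dst)
    _check_not_collinear(src_a, "source")
    _check_not_collinear(dst_a, "target")

    # rows: [x y 1 0 0 0 -ux -uy] h = u ; [0 0 0 x y 1 -vx -vy] h = v
    A = np.zeros((8, 8))
    b = np.zeros(8)
    for i, ((x, y), (u, v)) in enumerate(zip(src, dst)):
        A[2 * i] = [x, y, 1, 0, 0, 0, -u * x, -u * y]
        b[2 * i] = u
        A[2 * i + 1] = [0, 0, 0, x, y, 1, -v * x, -v * y]
        b[2 * i + 1] = v

    cond = np.linalg.cond(A)
    if not math.isfinite(cond):
        raise DegenerateConfigurationError("degenerate correspondence configuration")
    if cond > COND_WARN:
        log.warning("ill-conditioned alignment configuration (cond=%.3g)", cond)
    try:
        h = np.linalg.solve(A, b)
    except np.linalg.LinAlgError as e:
        raise DegenerateConfigurationError(f"alignment solve failed: {e}") from e
    H = np.array([[h[0], h[1], h[2]], [h[3], h[4], h[5]], [h[6], h[7], 1.0]])
    return Homography(H, src_frame, dst_frame)


def warp_image(image: np.ndarray, h: Homography, output_shape=None) -> np.ndarray:
    """Warp a raster with the estimated map, for visual comparison only.

    Measurements never pass through this function; it exists so a registered
    before/after blend can be rendered for inspection.
    """
    from skimage.transform import ProjectiveTransform, warp

    tf = ProjectiveTransform(matrix=h.matrix)
    return warp(image, tf.inverse, output_shape=output_shape, preserve_range=True)


__all__ = [
    "Homography", "estimate_homography", "warp_image",
    "DegenerateConfigurationError", "COND_WARN",
]
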