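"""2-D rigid transforms between histology slices.

A :class:`RigidTransform` is a rotation about an explicit center followed by a
translation, expressed in pixel units at a stated pyramid level.  Points map
*fixed ← moving*: ``x_fixed = R(x_moving - c) + c + t``.  Transforms carry
their level so they can be rescaled between pyramid resolutions (halving a
level doubles all pixel quantities but leaves the angle unchanged).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage as ndi

__all__ = [
    "RigidTransform",
    "estimate_rigid",
    "warp_image",
    "warp_mask",
]


@dataclass(frozen=True)
class RigidTransform:
    """Rotation + translation, no scale or shear (det(R) = +1).

    Parameters
    ----------
    theta_deg : float
        Counterclockwise rotation angle in degrees (in the (x, y) = (column,
        row) convention with y pointing down, a positive angle turns the image
        content clockwise on screen).
    dx, dy : float
        Translation in pixels at ``level``.
    level : int
        Pyramid level the pixel units refer to (0 = full resolution).
    center : tuple of float
        Rotation center ``(cx, cy)`` in pixel coordinates at ``level``.
    note : str or None
        Optional QC annotation (e.g. ``"degenerate_triplet"``); ignored by
        all arithmetic.
    """

    theta_deg: float = 0.0
    dx: float = 0.0
    dy: float = 0.0
    level: int = 0
    center: tuple[float, float] = (0.0, 0.0)
    note: str | None = field(default=None, compare=False)

    # ---------------------------------------------------------------- matrix
    def as_matrix(self) -> np.ndarray:
        """3x3 homogeneous matrix acting on (x, y, 1) column vectors."""
        th = math.radians(self.theta_deg)
        c, s = math.cos(th), math.sin(th)
        cx, cy = self.center
        r = np.array([[c, -s], [s, c]])
        # x' = R (x - c) + c + t
        t = -r @ np.array([cx, cy]) + np.array([cx + self.dx, cy + self.dy])
        m = np.eye(3)
        m[:2, :2] = r
        m[:2, 2] = t
        return m

    @classmethod
    def from_matrix(
        cls,
        matrix: np.ndarray,
        level: int = 0,
        center: tuple[float, float] = (0.0, 0.0),
        note: str | None = None,
    ) -> "RigidTransform":
        """Recover (theta, dx, dy) from a rigid homogeneous matrix.

        The rotation block must be orthonormal with determinant +1.
        """
        r = np.asarray(matrix, dtype=float)[:2, :2]
        det = np.linalg.det(r)
        if not (np.allclose(r.T @ r, np.eye(2), atol=1e-6) and det > 0):
            raise ValueError("matrix is not a proper rigid transform")
        theta = math.degrees(math.atan2(r[1, 0], r[0, 0]))
        cx, cy = center
        t_global = np.asarray(matrix, dtype=float)[:2, 2]
        # t = t_global + R c - c
        t = t_global + r @ np.array([cx, cy]) - np.array([cx, cy])
        return cls(theta, float(t[0]), float(t[1]), level, (cx, cy), note)

    # ------------------------------------------------------------- algebra
    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return ``self ∘ other`` (apply *other* first, then *self*).

        Both transforms must live at the same level; the result keeps
        ``self``'s rotation center.
        """
        if self.level != other.level:
            raise ValueError(
                f"cannot compose transforms at levels {self.level} and {other.level}"
            )
        m = self.as_matrix() @ other.as_matrix()
        return RigidTransform.from_matrix(m, self.level, self.center)

    def inverse(self) -> "RigidTransform":
        return RigidTransform.from_matrix(
            np.linalg.inv(self.as_matrix()), self.level, self.center
        )

    def rescale_to_level(self, level: int) -> "RigidTransform":
        """Re-express the transform at another pyramid level.

        Moving one level finer (``level - 1``) doubles dx, dy and the center;
        theta is scale-invariant.  Equivalent to ``S M S^{-1}`` with
        ``S = diag(2^Δ, 2^Δ, 1)``.
        """
        f = 2.0 ** (self.level - level)
        return replace(
            self,
            dx=self.dx * f,
            dy=self.dy * f,
            level=level,
            center=(self.center[0] * f, self.center[1] * f),
        )

    def apply_points(self, pts: np.ndarray) -> np.ndarray:
        """Map an (N, 2) array of (x, y) points moving → fixed."""
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        m = self.as_matrix()
        return pts @ m[:2, :2].T + m[:2, 2]

    @property
    def is_identity(self) -> bool:
        return (
            abs(self.theta_deg) < 1e-12 and abs(self.dx) < 1e-12 and abs(self.dy) < 1e-12
        )

    # ---------------------------------------------------------------- (de)ser
    def to_dict(self) -> dict:
        return {
            "theta_deg": self.theta_deg,
            "dx": self.dx,
            "dy": self.dy,
            "level": self.level,
            "center": list(self.center),
            "matrix": [float(v) for v in self.as_matrix().ravel()],
            "note": self.note,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RigidTransform":
        return cls(
            float(d["theta_deg"]),
            float(d["dx"]),
            float(d["dy"]),
            int(d["level"]),
            tuple(float(v) for v in d["center"]),
            d.get("note"),
        )


def estimate_rigid(
    moving_pts: np.ndarray,
    fixed_pts: np.ndarray,
    level: int = 0,
    center: tuple[float, float] = (0.0, 0.0),
) -> RigidTransform:
    """Least-squares rigid fit mapping ``moving_pts`` onto ``fixed_pts``.

    Orthogonal Procrustes restricted to a proper rotation (det +1, no
    scaling), solved by SVD of the 2x2 cross-covariance.  A unique rigid
    transform needs at least 3 point pairs; with fewer the fit refuses.

    Raises
    ------
    ValueError
        If fewer than 3 point pairs are supplied or the point sets are
        degenerate (all points coincident).
    """
    moving_pts = np.asarray(moving_pts, dtype=float)
    fixed_pts = np.asarray(fixed_pts, dtype=float)
    if moving_pts.shape != fixed_pts.shape or moving_pts.ndim != 2 or moving_pts.shape[1] != 2:
        raise ValueError("point arrays must both be (N, 2)")
    if moving_pts.shape[0] < 3:
        raise ValueError(
            f"a rigid transform requires at least 3 point pairs, got {moving_pts.shape[0]}"
        )
    mc = moving_pts.mean(axis=0)
    fc = fixed_pts.mean(axis=0)
    a = moving_pts - mc
    b = fixed_pts - fc
    if np.allclose(a, 0) or np.allclose(b, 0):
        raise ValueError("degenerate point set: all points coincide")
    h = a.T @ b
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    r = vt.T @ np.diag([1.0, d]) @ u.T
    t = fc - r @ mc
    m = np.eye(3)
    m[:2, :2] = r
    m[:2, 2] = t
    return RigidTransform.from_matrix(m, level, center)


def _inverse_coords(transform: RigidTransform, shape: tuple[int, int]) -> np.ndarray:
    """Sampling coordinates (row, col) in the moving image for each output pixel."""
    h, w = shape
    minv = np.linalg.inv(transform.as_matrix())
    yy, xx = np.mgrid[0:h, 0:w]
    xs = minv[0, 0] * xx + minv[0, 1] * yy + minv[0, 2]
    ys = minv[1, 0] * xx + minv[1, 1] * yy + minv[1, 2]
    return np.stack([ys, xs])


def warp_image(
    image: np.ndarray,
    transform: RigidTransform,
    fill: float = 0.0,
    order: int = 1,
) -> np.ndarray:
    """Warp ``image`` into the fixed frame of ``transform``.

    Output pixel x samples the moving image at ``T^{-1} x`` (bilinear by
    default); out-of-canvas samples take ``fill``.
    """
    image = np.asarray(image, dtype=float)
    if transform.is_identity:
        return image.copy()
    coords = _inverse_coords(transform, image.shape[:2])
    if image.ndim == 2:
        return ndi.map_coordinates(image, coords, order=order, cval=fill, mode="constant")
    out = np.empty_like(image)
    for c in range(image.shape[2]):
        out[..., c] = ndi.map_coordinates(
            image[..., c], coords, order=order, cval=fill, mode="constant"
        )
    return out


def warp_mask(mask: np.ndarray, transform: RigidTransform) -> np.ndarray:
    """Warp a boolean mask with nearest-neighbor interpolation (stays binary)."""
    out = warp_image(mask.astype(np.uint8), transform, fill=0.0, order=0)
    return out > 0.5
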