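"""Rough whole-tissue alignment by exhaustive rigid SSD search.

Consecutive slices can be rotated and shifted relative to each other by the
mounting process.  Before any ROI work, each cleaned slice pair is aligned
by minimizing

    Σ_{x,y} ( T_{θ,dx,dy}[moving](x, y) − fixed(x, y) )²

over a discrete grid of rotations and translations, where both images are
the *phase-mean* reconstructions of their Mumford–Shah segmentations (so
the SSD compares denoised, stain-normalized intensities).  The search is a
true exhaustive enumeration of the grid: the argmin over the grid is exact,
with ties broken toward the identity.

The search runs at a coarse pyramid level (default r = 2) and the winning
transform is rescaled to level 0 before use.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .image import SlideImage
from .mumford_shah import MSSegmentation
from .transforms import RigidTransform, warp_image

__all__ = ["SearchGrid", "rough_align_pair", "apply_rough_alignment", "default_grid"]


@dataclass
class SearchGrid:
    """Discretization of the (θ, dx, dy) search space at one pyramid level."""

    theta_values: np.ndarray
    dx_values: np.ndarray
    dy_values: np.ndarray
    level: int = 2

    def __post_init__(self) -> None:
        self.theta_values = np.atleast_1d(np.asarray(self.theta_values, dtype=float))
        self.dx_values = np.atleast_1d(np.asarray(self.dx_values, dtype=float))
        self.dy_values = np.atleast_1d(np.asarray(self.dy_values, dtype=float))
        for name, vals in (("theta", self.theta_values), ("dx", self.dx_values),
                           ("dy", self.dy_values)):
            if vals.size == 0:
                raise ValueError(f"{name}_values must be nonempty")
        if not (np.any(self.theta_values == 0) and np.any(self.dx_values == 0)
                and np.any(self.dy_values == 0)):
            raise ValueError("search grid must include the identity triple (0, 0, 0)")


def default_grid(width: int, level: int = 2) -> SearchGrid:
    """Default search grid: θ ±30° step 1°, shifts ±20% of width, step W/64."""
    step = max(1, width // 64)
    tmax = int(round(0.2 * width))
    shifts = np.arange(-tmax, tmax + 1, step, dtype=float)
    if 0 not in shifts:
        shifts = np.sort(np.append(shifts, 0.0))
    thetas = np.arange(-30.0, 30.0 + 0.5, 1.0)
    return SearchGrid(thetas, shifts, shifts, level)


def _as_phase_image(seg: MSSegmentation | SlideImage | np.ndarray) -> np.ndarray:
    if isinstance(seg, MSSegmentation):
        return seg.phase_mean_image
    if isinstance(seg, SlideImage):
        return np.asarray(seg.pixels, dtype=float)
    return np.asarray(seg, dtype=float)


def _rotate_padded(moving: np.ndarray, theta: float, center: tuple[float, float],
                   pad: int, fill: float) -> np.ndarray:
    """Rotate ``moving`` about ``center`` onto a canvas extended by ``pad``.

    The padded canvas covers coordinates [-pad, w+pad) × [-pad, h+pad), so a
    subsequent integer shift by up to ``pad`` pixels samples true rotated
    content — exactly what a single combined rigid warp would see — instead
    of content clipped at the original canvas edge.
    """
    from scipy import ndimage as ndi

    h, w = moving.shape
    t = RigidTransform(theta, 0.0, 0.0, 0, center)
    minv = np.linalg.inv(t.as_matrix())
    yy, xx = np.mgrid[-pad:h + pad, -pad:w + pad]
    xs = minv[0, 0] * xx + minv[0, 1] * yy + minv[0, 2]
    ys = minv[1, 0] * xx + minv[1, 1] * yy + minv[1, 2]
    return ndi.map_coordinates(moving, [ys, xs], order=1, cval=fill,
                               mode="constant")


def _shifted_ssd(rotated_pad: np.ndarray, fixed: np.ndarray, dx: int, dy: int,
                 pad: int) -> float:
    """SSD of the integer-shifted padded rotation against the full fixed canvas."""
    h, w = fixed.shape
    window = rotated_pad[pad - dy:pad - dy + h, pad - dx:pad - dx + w]
    return float(np.sum((window - fixed) ** 2))


def rough_align_pair(
    fixed: MSSegmentation | np.ndarray,
    moving: MSSegmentation | np.ndarray,
    grid: SearchGrid,
    fill: float | None = None,
) -> RigidTransform:
    """Exact argmin of the rigid SSD objective over the search grid.

    Both inputs are segmentations (matched on their phase-mean images) or
    plain arrays.  ``fill`` is the out-of-canvas intensity; by default the
    fixed image's median (a background-like value).  Ties are broken by
    smallest |θ|, then |dx| + |dy|, then lexicographic (θ, dx, dy) order.
    """
    fpx = _as_phase_image(fixed)
    mpx = _as_phase_image(moving)
    if fpx.shape != mpx.shape:
        raise ValueError(f"shape mismatch: fixed {fpx.shape} vs moving {mpx.shape}")
    if fill is None:
        fill = float(np.median(fpx))
    h, w = fpx.shape
    center = ((w - 1) / 2.0, (h - 1) / 2.0)

    best_key: tuple | None = None
    best: tuple[float, float, float] | None = None
    int_shifts = (np.all(grid.dx_values == np.round(grid.dx_values))
                  and np.all(grid.dy_values == np.round(grid.dy_values)))
    pad = int(np.ceil(max(np.abs(grid.dx_values).max(),
                          np.abs(grid.dy_values).max())))
    for theta in grid.theta_values:
        rotated = _rotate_padded(mpx, float(theta), center, pad, fill) \
            if int_shifts else None
        for dx in grid.dx_values:
            for dy in grid.dy_values:
                if int_shifts:
                    ssd = _shifted_ssd(rotated, fpx, int(dx), int(dy), pad)
                else:
                    t = RigidTransform(theta, dx, dy, grid.level, center)
                    ssd = float(np.sum((warp_image(mpx, t, fill=fill) - fpx) ** 2))
                key = (ssd, abs(theta), abs(dx) + abs(dy), theta, dx, dy)
                if best_key is None or key < best_key:
                    best_key = key
                    best = (float(theta), float(dx), float(dy))
    theta, dx, dy = best
    return RigidTransform(theta, dx, dy, grid.level, center)


def apply_rough_alignment(
    moving: SlideImage, transform: RigidTransform, fill: float = 0.0
) -> SlideImage:
    """Warp the moving slice by the recovered rough transform (I' ← T[Ĩ])."""
    if transform.level != moving.level:
        raise ValueError(
            f"transform level {transform.level} does not match image level {moving.level}"
        )
    warped = warp_image(np.asarray(moving.pixels, dtype=float), transform, fill=fill)
    return SlideImage(warped, moving.level, moving.spacing, moving.slice_index)
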