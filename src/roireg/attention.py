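"""Multi-scale attention registration of a user-defined ROI.

The central idea: instead of registering whole slides at every pyramid
level, the attention window keeps a *fixed pixel size* across levels.  At a
coarse level the same 256x256 window covers a large fraction of the tissue
(broad context); at full resolution it covers only the neighborhood of the
structure of interest.  Registration therefore starts from broad context
and progressively concentrates on the ROI, so artifacts elsewhere in the
slide never enter the finest (decisive) comparisons.

Per level r = k … 0:

1. detect SIFT keypoints inside the ROI of both images and match them on
   descriptors augmented with their (normalized, weighted) spatial
   coordinates;
2. keep the 8 strongest matches (all of them if fewer);
3. fit one rigid transform per 3-combination of those matches
   (C(8,3) = 56 candidates);
4. warp the moving image by each candidate and keep the one with the least
   sum of squared intensity differences over the ROI, the identity always
   competing as a safety candidate.

The per-level transforms compose into F* = F_0 F_1 … F_k at level 0.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from skimage.feature import SIFT

from .image import SlideImage, SlidePyramid
from .transforms import RigidTransform, estimate_rigid, warp_image

__all__ = [
    "ROIBox",
    "KeypointMatch",
    "LevelRegistration",
    "PairRegistration",
    "StackRegistrationResult",
    "AttentionParams",
    "extract_roi_at_level",
    "detect_and_match",
    "select_strong_matches",
    "enumerate_rigid_candidates",
    "roi_ssd",
    "register_roi_level",
    "register_roi_pair",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ROIBox:
    """Axis-aligned attention window.

    The center is given in pixels at ``level``; width and height are the
    *level-invariant* attention size.  The box is half-open
    ``[x0, x0+w) × [y0, y0+h)`` and is clamped to the image bounds when
    materialized at a level.
    """

    center_x: float
    center_y: float
    width: int
    height: int
    level: int = 0

    def bounds(self, image_shape: tuple[int, int]) -> tuple[int, int, int, int]:
        """(x0, y0, w, h) of the clamped box within an image of this level."""
        h_img, w_img = image_shape[:2]
        w = min(self.width, w_img)
        h = min(self.height, h_img)
        x0 = int(round(self.center_x - w / 2.0))
        y0 = int(round(self.center_y - h / 2.0))
        x0 = max(0, min(x0, w_img - w))
        y0 = max(0, min(y0, h_img - h))
        return x0, y0, w, h

    def contains(self, x: float, y: float, image_shape: tuple[int, int]) -> bool:
        x0, y0, w, h = self.bounds(image_shape)
        return x0 <= x < x0 + w and y0 <= y < y0 + h


@dataclass(frozen=True)
class KeypointMatch:
    """A matched keypoint pair with its augmented-descriptor distance."""

    p_fixed: tuple[float, float]
    p_moving: tuple[float, float]
    descriptor_distance: float


@dataclass
class LevelRegistration:
    """Outcome of one pyramid level's ROI registration."""

    level: int
    chosen_transform: RigidTransform
    candidate_count: int
    best_ssd: float
    matches_used: list[KeypointMatch] = field(default_factory=list)
    match_count: int = 0
    flags: tuple[str, ...] = ()


@dataclass
class PairRegistration:
    """Transforms registered for one slice of the stack."""

    slice_index: int
    rough: RigidTransform
    composed_roi: RigidTransform
    levels: list[LevelRegistration] = field(default_factory=list)
    flags: tuple[str, ...] = ()

    @property
    def total(self) -> RigidTransform:
        """Transform mapping the raw slice into the ROI-registered frame."""
        return self.composed_roi.compose(self.rough)


@dataclass
class StackRegistrationResult:
    """Per-slice transforms + configuration snapshot for a registered stack."""

    per_slice: list[PairRegistration]
    roi0: ROIBox | None = None
    config: dict = field(default_factory=dict)

    @property
    def flags(self) -> list[tuple[int, str]]:
        out = []
        for rec in self.per_slice:
            for f in rec.flags:
                out.append((rec.slice_index, f))
            for lv in rec.levels:
                for f in lv.flags:
                    out.append((rec.slice_index, f"level{lv.level}:{f}"))
        return out


@dataclass
class AttentionParams:
    """Parameters of the ROI registration stage.

    n_levels : pyramid levels used (r = n_levels-1 … 0).
    layers_per_octave : SIFT scales per octave (10 works well on tissue).
    spatial_weight : weight of the normalized keypoint coordinates appended
        to the descriptors; ``None`` uses 0.25 x the median raw-descriptor
        norm of the matched sets.
    n_strong_matches : matches kept for triplet enumeration.
    ratio_test : optional Lowe ratio threshold (disabled by default — it can
        starve the match pool in repetitive tissue).
    """

    n_levels: int = 4
    layers_per_octave: int = 10
    spatial_weight: float | None = None
    n_strong_matches: int = 8
    ratio_test: float | None = None
    fill: float = 0.0


def extract_roi_at_level(roi0: ROIBox, level: int, image_shape: tuple[int, int]) -> ROIBox:
    """Materialize the level-0 ROI at a coarser level.

    The center is divided by 2^level; width/height stay fixed (the attention
    mechanism) but are clamped to the level's image bounds.
    """
    if level < 0:
        raise ValueError("level must be >= 0")
    if roi0.level != 0:
        raise ValueError("extract_roi_at_level expects a level-0 ROI")
    h_img, w_img = image_shape[:2]
    cx = roi0.center_x / 2**level
    cy = roi0.center_y / 2**level
    if not (0 <= roi0.center_x and 0 <= roi0.center_y):
        raise ValueError("ROI center must lie inside the level-0 image")
    if cx > w_img * 1.0 or cy > h_img * 1.0:
        raise ValueError("ROI center lies outside the level image")
    return ROIBox(cx, cy, min(roi0.width, w_img), min(roi0.height, h_img), level)


def _roi_crop(image: np.ndarray, roi: ROIBox) -> tuple[np.ndarray, int, int]:
    x0, y0, w, h = roi.bounds(image.shape)
    return image[y0:y0 + h, x0:x0 + w], x0, y0


def _detect(image: np.ndarray, layers_per_octave: int) -> tuple[np.ndarray, np.ndarray]:
    """SIFT keypoints (N, 2 as row, col) and descriptors, empty on failure."""
    det = SIFT(n_scales=layers_per_octave)
    try:
        det.detect_and_extract(image.astype(float))
    except RuntimeError:
        return np.empty((0, 2)), np.empty((0, 128))
    return det.keypoints, det.descriptors.astype(float)


def detect_and_match(
    fixed: SlideImage | np.ndarray,
    moving: SlideImage | np.ndarray,
    roi: ROIBox,
    layers_per_octave: int = 10,
    spatial_weight: float | None = None,
    ratio_test: float | None = None,
) -> list[KeypointMatch]:
    """SIFT detection inside the ROI of both images + mutual-NN matching.

    Each 128-dim descriptor is augmented with the keypoint's position
    normalized to [0, 1] by the ROI extent and scaled by ``spatial_weight``,
    so matching prefers geometrically plausible pairs.  Matches are mutual
    nearest neighbors in augmented-descriptor space, sorted ascending by
    distance.  Keypoint coordinates are returned in level-image pixels.
    """
    fpx = fixed.pixels if isinstance(fixed, SlideImage) else np.asarray(fixed)
    mpx = moving.pixels if isinstance(moving, SlideImage) else np.asarray(moving)
    fcrop, fx0, fy0 = _roi_crop(np.asarray(fpx, dtype=float), roi)
    mcrop, mx0, my0 = _roi_crop(np.asarray(mpx, dtype=float), roi)
    kf, df = _detect(fcrop, layers_per_octave)
    km, dm = _detect(mcrop, layers_per_octave)
    if len(kf) == 0 or len(km) == 0:
        return []

    _, _, w, h = roi.bounds(np.asarray(fpx).shape)
    if spatial_weight is None:
        norms = np.linalg.norm(np.vstack([df, dm]), axis=1)
        spatial_weight = 0.25 * float(np.median(norms))
    sf = np.column_stack([kf[:, 1] / max(w - 1, 1), kf[:, 0] / max(h - 1, 1)])
    sm = np.column_stack([km[:, 1] / max(w - 1, 1), km[:, 0] / max(h - 1, 1)])
    af = np.hstack([df, spatial_weight * sf])
    am = np.hstack([dm, spatial_weight * sm])

    d = cdist(af, am)
    nn_f = d.argmin(axis=1)
    nn_m = d.argmin(axis=0)
    matches = []
    for i, j in enumerate(nn_f):
        if nn_m[j] != i:
            continue
        if ratio_test is not None and d.shape[1] >= 2:
            row = np.partition(d[i], 1)
            if row[1] > 0 and row[0] / row[1] > ratio_test:
                continue
        matches.append(
            KeypointMatch(
                p_fixed=(float(kf[i, 1] + fx0), float(kf[i, 0] + fy0)),
                p_moving=(float(km[j, 1] + mx0), float(km[j, 0] + my0)),
                descriptor_distance=float(d[i, j]),
            )
        )
    matches.sort(key=lambda m: (m.descriptor_distance, m.p_fixed))
    return matches


def select_strong_matches(matches: list[KeypointMatch], n: int = 8) -> list[KeypointMatch]:
    """First min(n, len) matches by ascending descriptor distance (stable)."""
    if n < 3:
        raise ValueError("n must be >= 3 for a rigid fit downstream")
    ordered = sorted(matches, key=lambda m: m.descriptor_distance)
    return ordered[: min(n, len(ordered))]


_DEGENERATE_AREA_TOL = 1e-6


def enumerate_rigid_candidates(
    matches: list[KeypointMatch],
    level: int = 0,
    center: tuple[float, float] = (0.0, 0.0),
) -> list[RigidTransform]:
    """One rigid transform per 3-combination of the matches (C(n,3) total).

    Each triplet is fit by least squares (det=+1 Procrustes, no scaling)
    mapping the moving points onto the fixed points.  Triplets whose fixed
    points are collinear within tolerance yield a flagged identity candidate
    instead of being dropped, so the count is always C(n, 3).
    """
    if len(matches) < 3:
        return []
    out: list[RigidTransform] = []
    for trip in itertools.combinations(matches, 3):
        fixed_pts = np.array([m.p_fixed for m in trip])
        moving_pts = np.array([m.p_moving for m in trip])
        v1 = fixed_pts[1] - fixed_pts[0]
        v2 = fixed_pts[2] - fixed_pts[0]
        area = 0.5 * abs(v1[0] * v2[1] - v1[1] * v2[0])
        scale = max(np.ptp(fixed_pts, axis=0).max(), 1.0)
        if area < _DEGENERATE_AREA_TOL * scale**2:
            out.append(RigidTransform(0.0, 0.0, 0.0, level, center, "degenerate_triplet"))
            continue
        try:
            t = estimate_rigid(moving_pts, fixed_pts, level, center)
        except ValueError:
            t = RigidTransform(0.0, 0.0, 0.0, level, center, "degenerate_triplet")
        out.append(t)
    return out


def roi_ssd(
    fixed: SlideImage | np.ndarray,
    moving_warped: SlideImage | np.ndarray,
    roi: ROIBox,
) -> float:
    """Sum of squared grayscale differences over the ROI pixels (the D of
    the candidate-selection objective)."""
    fpx = np.asarray(fixed.pixels if isinstance(fixed, SlideImage) else fixed, dtype=float)
    mpx = np.asarray(
        moving_warped.pixels if isinstance(moving_warped, SlideImage) else moving_warped,
        dtype=float,
    )
    if fpx.shape != mpx.shape:
        raise ValueError("fixed and moving images must share a shape")
    fcrop, _, _ = _roi_crop(fpx, roi)
    mcrop, _, _ = _roi_crop(mpx, roi)
    return float(np.sum((fcrop - mcrop) ** 2))


def _candidate_ssd(
    fixed: np.ndarray, moving: np.ndarray, roi: ROIBox, t: RigidTransform, fill: float
) -> float:
    """SSD over the ROI of ``warp(moving, t)`` without warping the full image.

    Samples the moving image at the inverse-transformed ROI grid; identical
    to ``roi_ssd(fixed, warp_image(moving, t, fill), roi)`` up to float
    round-off.
    """
    from scipy import ndimage as ndi

    x0, y0, w, h = roi.bounds(fixed.shape)
    if t.is_identity:
        return float(np.sum((fixed[y0:y0 + h, x0:x0 + w]
                             - moving[y0:y0 + h, x0:x0 + w]) ** 2))
    minv = np.linalg.inv(t.as_matrix())
    yy, xx = np.mgrid[y0:y0 + h, x0:x0 + w]
    xs = minv[0, 0] * xx + minv[0, 1] * yy + minv[0, 2]
    ys = minv[1, 0] * xx + minv[1, 1] * yy + minv[1, 2]
    sampled = ndi.map_coordinates(moving, [ys, xs], order=1, cval=fill, mode="constant")
    return float(np.sum((fixed[y0:y0 + h, x0:x0 + w] - sampled) ** 2))


def register_roi_level(
    fixed: SlideImage | np.ndarray,
    moving: SlideImage | np.ndarray,
    roi: ROIBox,
    params: AttentionParams | None = None,
) -> LevelRegistration:
    """Register one pyramid level's ROI: match, enumerate triplets, pick by SSD.

    The identity transform always competes as a safety candidate, so the
    chosen SSD can never exceed the unregistered SSD.  With fewer than 3
    matches the identity is returned with a ``too_few_matches`` flag.  Ties
    prefer the candidate nearest the identity.
    """
    params = params or AttentionParams()
    fpx = np.asarray(fixed.pixels if isinstance(fixed, SlideImage) else fixed, dtype=float)
    mpx = np.asarray(moving.pixels if isinstance(moving, SlideImage) else moving, dtype=float)
    level = roi.level
    x0, y0, w, h = roi.bounds(fpx.shape)
    roi_center = (x0 + (w - 1) / 2.0, y0 + (h - 1) / 2.0)
    identity = RigidTransform(0.0, 0.0, 0.0, level, roi_center)

    matches = detect_and_match(
        fpx, mpx, roi, params.layers_per_octave, params.spatial_weight, params.ratio_test
    )
    strong = select_strong_matches(matches, params.n_strong_matches) if matches else []
    flags: tuple[str, ...] = ()
    if len(strong) < 3:
        ssd0 = _candidate_ssd(fpx, mpx, roi, identity, params.fill)
        return LevelRegistration(level, identity, 0, ssd0, [], len(matches),
                                 ("too_few_matches",))
    candidates = enumerate_rigid_candidates(strong, level, roi_center)
    n_candidates = len(candidates)
    triplets = list(itertools.combinations(range(len(strong)), 3))

    best = None
    best_key = None
    for t, trip_idx in zip(candidates, triplets):
        ssd = _candidate_ssd(fpx, mpx, roi, t, params.fill)
        key = (ssd, abs(t.theta_deg), math.hypot(t.dx, t.dy))
        if best_key is None or key < best_key:
            best_key, best = key, (t, ssd, trip_idx)
    ssd0 = _candidate_ssd(fpx, mpx, roi, identity, params.fill)
    key0 = (ssd0, 0.0, 0.0)
    if key0 < best_key:
        best = (identity, ssd0, None)
        flags = flags + ("identity_preferred",)
    t, ssd, trip_idx = best
    used = [strong[i] for i in trip_idx] if trip_idx is not None else []
    log.debug("level %d: %d matches, %d candidates, best SSD %.4g, theta %.3f deg, "
              "shift (%.2f, %.2f)", level, len(matches), n_candidates, ssd,
              t.theta_deg, t.dx, t.dy)
    return LevelRegistration(level, t, n_candidates, ssd, used, len(matches), flags)


def register_roi_pair(
    fixed_pyr: SlidePyramid,
    moving_pyr: SlidePyramid,
    roi0: ROIBox,
    n_levels: int = 4,
    params: AttentionParams | None = None,
) -> tuple[RigidTransform, list[LevelRegistration]]:
    """Coarse-to-fine ROI registration of one slice pair.

    For r = n_levels-1 … 0 the moving slice (carrying all coarser
    transforms, rescaled to the current level) is registered within the
    attention window; the per-level transforms compose into
    F* = F_0 F_1 … F_k expressed at level 0.
    """
    params = params or AttentionParams(n_levels=n_levels)
    if n_levels < 1:
        raise ValueError("n_levels must be >= 1")
    if fixed_pyr.n_levels < n_levels or moving_pyr.n_levels < n_levels:
        raise ValueError(
            f"pyramids provide {min(fixed_pyr.n_levels, moving_pyr.n_levels)} levels, "
            f"{n_levels} requested"
        )
    shape0 = fixed_pyr[0].pixels.shape[:2]
    accumulated = RigidTransform(0.0, 0.0, 0.0, 0, ((shape0[1] - 1) / 2.0,
                                                    (shape0[0] - 1) / 2.0))
    records: list[LevelRegistration] = []
    for r in range(n_levels - 1, -1, -1):
        fixed_img = fixed_pyr[r]
        roi_r = extract_roi_at_level(roi0, r, fixed_img.pixels.shape)
        moving_px = np.asarray(moving_pyr[r].pixels, dtype=float)
        acc_r = accumulated.rescale_to_level(r)
        warped = warp_image(moving_px, acc_r, fill=params.fill)
        rec = register_roi_level(fixed_img.pixels, warped, roi_r, params)
        records.append(rec)
        f0 = rec.chosen_transform.rescale_to_level(0)
        accumulated = f0.compose(accumulated)
    return accumulated, records
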