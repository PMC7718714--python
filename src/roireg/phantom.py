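"""Seeded synthetic whole-slide stacks with ground truth.

Real serial-section IHC stacks are rarely shareable, so every stage of the
pipeline is exercised on a phantom that emulates their registration-relevant
structure: a textured tissue section containing a vessel (dark wall ring,
bright lumen) whose center and caliber drift slowly through the stack, a
per-slice stain-intensity scale, an independent rigid mounting perturbation
per slice (recorded as ground truth), and — on demand — stain blobs and
tear wedges injected strictly outside an exclusion zone around the ROI.

The texture is band-limited noise shared across the stack (consecutive
4 µm sections of real tissue look locally similar, which is what gives SIFT
something to match) with a small per-slice component.  Everything is driven
by one explicit seed; the same seed reproduces the stack bitwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

from .attention import ROIBox
from .evaluation import LumenMaskStack
from .image import SlidePyramid, build_pyramid
from .transforms import RigidTransform, warp_image, warp_mask

__all__ = ["VesselConfig", "PerturbationConfig", "StainConfig", "ArtifactConfig",
           "PhantomConfig", "PhantomStack", "generate_phantom", "inject_artifacts"]


@dataclass(frozen=True)
class VesselConfig:
    """Geometry of the simulated vessel through the stack.

    The center follows a low-order polynomial in z with a bounded derivative
    so consecutive unperturbed lumens overlap strongly; radius drifts
    sinusoidally by a fraction of a pixel per slice.
    """

    center: tuple[float, float] | None = None  # (x, y) at level 0; None → (0.586 W, 0.508 H)
    drift: tuple[float, float] = (0.6, -0.45)     # px per slice, linear term
    curve: tuple[float, float] = (0.03, 0.02)     # px per slice², quadratic term
    lumen_radius: float = 20.0
    radius_drift: float = 1.5                     # sinusoidal amplitude over the stack
    wall_thickness: float = 7.0


@dataclass(frozen=True)
class PerturbationConfig:
    """Per-slice rigid mounting error, uniform and independent per slice."""

    theta_max: float = 10.0   # degrees
    shift_max: float = 30.0   # pixels at level 0


@dataclass(frozen=True)
class StainConfig:
    """Per-slice multiplicative stain-density variation."""

    scale_range: tuple[float, float] = (0.85, 1.15)


@dataclass(frozen=True)
class ArtifactConfig:
    """Stain blobs and tear wedges injected outside the ROI exclusion zone."""

    n_blobs: int = 5
    blob_radius_range: tuple[float, float] = (10.0, 22.0)
    blob_intensity: float = 45.0
    n_tears: int = 1
    tear_length_frac: float = 0.2   # of canvas width
    tear_width_deg: float = 7.0
    exclusion_factor: float = 1.5   # × ROI half-diagonal
    max_tries: int = 200


@dataclass(frozen=True)
class PhantomConfig:
    """Full description of a synthetic stack; ``seed`` is mandatory."""

    n_slices: int = 10
    canvas: tuple[int, int] = (512, 512)  # (H, W) at level 0
    n_levels: int = 4
    vessel: VesselConfig = field(default_factory=VesselConfig)
    perturbation: PerturbationConfig = field(default_factory=PerturbationConfig)
    stain: StainConfig = field(default_factory=StainConfig)
    artifacts: ArtifactConfig | None = None
    roi_size: int = 128
    background: float = 235.0
    tissue_intensity: float = 150.0
    wall_intensity: float = 60.0
    lumen_intensity: float = 228.0
    texture_amplitude: float = 22.0
    seed: int = 0


@dataclass
class PhantomStack:
    """Generated stack: image pyramids, true rigid perturbations, lumen masks."""

    pyramids: list[SlidePyramid]
    true_transforms: list[RigidTransform]
    lumen_masks: LumenMaskStack
    roi0: ROIBox
    config: PhantomConfig


def _vessel_center(cfg: VesselConfig, z: int, canvas: tuple[int, int]) -> tuple[float, float]:
    h, w = canvas
    cx, cy = cfg.center if cfg.center is not None else (0.586 * w, 0.508 * h)
    return (
        cx + cfg.drift[0] * z + cfg.curve[0] * z**2,
        cy + cfg.drift[1] * z + cfg.curve[1] * z**2,
    )


def _lumen_radius(cfg: VesselConfig, z: int, n: int) -> float:
    return cfg.lumen_radius + cfg.radius_drift * np.sin(2 * np.pi * z / max(2 * n, 1))


def _render_canonical(
    config: PhantomConfig, z: int, base_texture: np.ndarray,
    slice_noise: np.ndarray, stain_scale: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Unperturbed slice image + lumen mask in the canonical frame."""
    h, w = config.canvas
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    ch, cw = (h - 1) / 2.0, (w - 1) / 2.0

    # irregular tissue section boundary (radial harmonic wobble)
    ang = np.arctan2(yy - ch, xx - cw)
    radius = 0.42 * min(h, w) * (1 + 0.05 * np.sin(3 * ang) + 0.03 * np.cos(5 * ang))
    tissue = np.hypot(xx - cw, yy - ch) < radius

    vx, vy = _vessel_center(config.vessel, z, config.canvas)
    r_lumen = _lumen_radius(config.vessel, z, config.n_slices)
    dist = np.hypot(xx - vx, yy - vy)
    lumen = dist < r_lumen
    wall = (dist >= r_lumen) & (dist < r_lumen + config.vessel.wall_thickness)

    img = np.full((h, w), config.background)
    tex = config.texture_amplitude * base_texture + slice_noise
    img[tissue] = config.tissue_intensity + tex[tissue]
    img[wall] = config.wall_intensity + 0.35 * tex[wall]
    img[lumen] = config.lumen_intensity
    # stain-density variation scales deviation from the illuminated background
    img = config.background - stain_scale * (config.background - img)
    return np.clip(img, 0, 255), lumen & tissue


def generate_phantom(config: PhantomConfig) -> PhantomStack:
    """Render the full seeded stack (deterministic given ``config.seed``).

    Slice 0 is the unperturbed reference; slices 1… receive independent
    uniform rigid perturbations recorded in ``true_transforms``.  Artifacts
    are injected afterwards when ``config.artifacts`` is set.
    """
    rng = np.random.default_rng(config.seed)
    h, w = config.canvas
    center = ((w - 1) / 2.0, (h - 1) / 2.0)

    # stack-shared band-limited texture: two spatial scales of smoothed noise
    t1 = ndi.gaussian_filter(rng.standard_normal((h, w)), 1.5)
    t2 = ndi.gaussian_filter(rng.standard_normal((h, w)), 4.0)
    base_texture = t1 / t1.std() * 0.6 + t2 / t2.std() * 0.4

    pyramids, transforms, masks = [], [], []
    for z in range(config.n_slices):
        noise = ndi.gaussian_filter(rng.standard_normal((h, w)), 1.0)
        noise = noise / noise.std() * 4.0
        scale = rng.uniform(*config.stain.scale_range)
        if z == 0:
            t = RigidTransform(0.0, 0.0, 0.0, 0, center)
            # burn the unused draws so slice 0's presence doesn't shift the others
            rng.uniform(-1, 1, size=3)
        else:
            theta = rng.uniform(-config.perturbation.theta_max, config.perturbation.theta_max)
            dx = rng.uniform(-config.perturbation.shift_max, config.perturbation.shift_max)
            dy = rng.uniform(-config.perturbation.shift_max, config.perturbation.shift_max)
            t = RigidTransform(theta, dx, dy, 0, center)
        canonical, lumen = _render_canonical(config, z, base_texture, noise, scale)
        observed = warp_image(canonical, t, fill=config.background)
        mask = warp_mask(lumen, t)
        pyramids.append(build_pyramid(observed, config.n_levels, slice_index=z))
        transforms.append(t)
        masks.append(mask)

    cx0, cy0 = _vessel_center(config.vessel, 0, config.canvas)
    cxn, cyn = _vessel_center(config.vessel, config.n_slices - 1, config.canvas)
    roi0 = ROIBox((cx0 + cxn) / 2.0, (cy0 + cyn) / 2.0, config.roi_size, config.roi_size, 0)
    stack = PhantomStack(pyramids, transforms, LumenMaskStack(masks), roi0, config)
    if config.artifacts is not None:
        stack = inject_artifacts(stack, config.artifacts)
    return stack


def _exclusion(stack: PhantomStack, cfg: ArtifactConfig, z: int) -> tuple[np.ndarray, float]:
    """Exclusion-zone center (in the observed slice frame) and radius."""
    roi = stack.roi0
    half_diag = 0.5 * np.hypot(roi.width, roi.height)
    radius = cfg.exclusion_factor * half_diag
    c = stack.true_transforms[z].apply_points([[roi.center_x, roi.center_y]])[0]
    return c, radius


def inject_artifacts(stack: PhantomStack, cfg: ArtifactConfig | None = None) -> PhantomStack:
    """Add stain blobs and tear wedges outside the ROI exclusion zone.

    Lumen masks and true transforms are untouched; every pixel inside the
    exclusion circle around the (perturbed) ROI center is preserved bitwise.
    Placement that cannot satisfy the exclusion constraint raises.
    """
    cfg = cfg or ArtifactConfig()
    config = stack.config
    h, w = config.canvas
    rng = np.random.default_rng(config.seed + 10_000)
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    ch, cw = (h - 1) / 2.0, (w - 1) / 2.0
    new_pyramids = []
    for z, pyr in enumerate(stack.pyramids):
        img = np.asarray(pyr[0].pixels, dtype=float).copy()
        excl_c, excl_r = _exclusion(stack, cfg, z)

        def place(radius_needed: float) -> tuple[float, float]:
            for _ in range(cfg.max_tries):
                r = rng.uniform(0.28, 0.46) * min(h, w)
                a = rng.uniform(0, 2 * np.pi)
                x = cw + r * np.cos(a)
                y = ch + r * np.sin(a)
                if np.hypot(x - excl_c[0], y - excl_c[1]) > excl_r + radius_needed:
                    return x, y
            raise ValueError(
                "could not place an artifact outside the ROI exclusion zone; "
                "shrink the exclusion radius or the artifact sizes"
            )

        for _ in range(cfg.n_blobs):
            br = rng.uniform(*cfg.blob_radius_range)
            bx, by = place(br)
            blob = np.hypot(xx - bx, yy - by) < br
            img[blob] = cfg.blob_intensity
        inside_excl = np.hypot(xx - excl_c[0], yy - excl_c[1]) <= excl_r
        for _ in range(cfg.n_tears):
            length = cfg.tear_length_frac * w
            wedge = None
            for _try in range(cfg.max_tries):
                r = rng.uniform(0.38, 0.46) * min(h, w)
                a = rng.uniform(0, 2 * np.pi)
                tx, ty = cw + r * np.cos(a), ch + r * np.sin(a)
                direction = np.arctan2(ch - ty, cw - tx)  # wedge points inward
                ang = np.arctan2(yy - ty, xx - tx)
                dang = np.angle(np.exp(1j * (ang - direction)))
                dist = np.hypot(xx - tx, yy - ty)
                cand = (np.abs(dang) < np.radians(cfg.tear_width_deg)) & (dist < length)
                if not (cand & inside_excl).any():
                    wedge = cand
                    break
            if wedge is None:
                raise ValueError(
                    "could not place a tear wedge outside the ROI exclusion zone; "
                    "shrink the exclusion radius or the tear length"
                )
            img[wedge] = config.background
        new_pyramids.append(build_pyramid(img, config.n_levels, slice_index=z))
    return replace_stack(stack, new_pyramids)


def replace_stack(stack: PhantomStack, pyramids: list[SlidePyramid]) -> PhantomStack:
    return PhantomStack(pyramids, stack.true_transforms, stack.lumen_masks,
                        stack.roi0, stack.config)
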