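"""End-to-end stack registration: cleanup → rough alignment → ROI attention.

Slices are registered sequentially into the frame of slice 0.  For each
consecutive pair the moving slice is cleaned, roughly aligned to the
already-registered fixed slice by the exhaustive Mumford–Shah SSD search,
and then the ROI is registered coarse-to-fine by the attention mechanism.
The stored per-slice transform maps the *raw* slice into the registered
frame (composed_roi ∘ rough), so lumen masks can be warped directly.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np

from .attention import (AttentionParams, LevelRegistration, PairRegistration,
                        ROIBox, StackRegistrationResult, register_roi_pair)
from .config import PipelineConfig
from .image import SlideImage, SlidePyramid, build_pyramid
from .mumford_shah import mumford_shah_segment
from .preprocessing import PreprocessParams, clean_tissue, to_grayscale_smoothed
from .rough import SearchGrid, default_grid, rough_align_pair
from .transforms import RigidTransform, warp_image

__all__ = ["register_stack"]

log = logging.getLogger(__name__)


def _gray0(pyr: SlidePyramid) -> SlideImage:
    img = pyr[0]
    if img.is_gray:
        return img
    return to_grayscale_smoothed(img, sigma=1e-6)  # conversion only


def register_stack(
    slices: list[SlidePyramid],
    roi0: ROIBox,
    config: PipelineConfig | None = None,
) -> StackRegistrationResult:
    """Register the ROI through a slide stack; deterministic given the config seed."""
    config = config or PipelineConfig()
    if len(slices) < 2:
        raise ValueError("need at least 2 slices to register")
    n_levels = config.attention.n_levels
    rough_level = config.rough_level

    pre = config.preprocessing
    cleaned: list[np.ndarray] = []
    fills: list[float] = []
    flags_per_slice: list[tuple[str, ...]] = []
    for pyr in slices:
        img, hull = clean_tissue(_gray0(pyr), pre)
        px = np.asarray(img.pixels, dtype=float)
        outside = ~hull.mask
        fills.append(float(np.median(px[outside])) if outside.any() else float(np.median(px)))
        cleaned.append(px)
        flags_per_slice.append(hull.flags)

    shape0 = cleaned[0].shape
    center0 = ((shape0[1] - 1) / 2.0, (shape0[0] - 1) / 2.0)
    identity = RigidTransform(0.0, 0.0, 0.0, 0, center0)
    per_slice = [PairRegistration(slices[0].slice_index, identity, identity, [],
                                  flags_per_slice[0])]

    grid = config.grid or default_grid(
        int(np.ceil(shape0[1] / 2**rough_level)), rough_level)
    current_fixed0 = cleaned[0]
    for i in range(1, len(slices)):
        fill = fills[i]
        depth = max(n_levels, rough_level + 1)
        fixed_pyr = build_pyramid(current_fixed0, depth,
                                  slice_index=slices[i - 1].slice_index)
        moving0 = cleaned[i]

        # rough whole-tissue alignment on Mumford–Shah phase-mean images
        moving_pyr = build_pyramid(moving0, depth, slice_index=slices[i].slice_index)
        seg_seed = (config.seed % 20_000) * 100_003 + i
        seg_fixed = mumford_shah_segment(
            fixed_pyr[rough_level].pixels,
            config.n_phases, config.lambda_boundary, config.ms_iterations, seg_seed)
        seg_moving = mumford_shah_segment(
            moving_pyr[rough_level].pixels, config.n_phases, config.lambda_boundary,
            config.ms_iterations, seg_seed + 1)
        t_rough = rough_align_pair(seg_fixed, seg_moving, grid, fill=fill)
        t_rough0 = t_rough.rescale_to_level(0)
        log.info("slice %d rough: theta %.2f deg, shift (%.1f, %.1f) at level 0",
                 slices[i].slice_index, t_rough0.theta_deg, t_rough0.dx, t_rough0.dy)

        moving_rough0 = warp_image(moving0, t_rough0, fill=fill)
        moving_rough_pyr = build_pyramid(moving_rough0, n_levels,
                                         slice_index=slices[i].slice_index)

        params = dataclasses.replace(config.attention, fill=fill)
        f_star, levels = register_roi_pair(fixed_pyr, moving_rough_pyr, roi0,
                                           n_levels, params)
        total = f_star.compose(t_rough0)
        per_slice.append(PairRegistration(slices[i].slice_index, t_rough0, f_star,
                                          levels, flags_per_slice[i]))
        current_fixed0 = warp_image(moving0, total, fill=fill)

    snapshot = config.to_dict()
    return StackRegistrationResult(per_slice, roi0, snapshot)
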