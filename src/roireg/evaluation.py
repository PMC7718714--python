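"""Registration accuracy via Dice overlap of warped lumen masks.

Vessel lumens segmented on each slice (independently of the registration)
give a geometric ground truth: after a good registration, consecutive lumen
masks should coincide.  Accuracy is summarized as the Dice similarity
coefficient DSC = 2|A∩B| / (|A|+|B|) between each consecutive mask pair,
reported as mean ± std over pairs.  Dice stays meaningful across vessel
branching, which is why it is preferred over center-distance metrics here.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import tifffile

from .attention import StackRegistrationResult
from .transforms import warp_mask

__all__ = ["LumenMaskStack", "DSCReport", "dice", "warp_mask_stack",
           "evaluate_stack", "export_volume"]

log = logging.getLogger(__name__)


@dataclass
class LumenMaskStack:
    """Binary lumen masks, one per slice, all at level 0 and one shape."""

    masks: list[np.ndarray]
    slice_indices: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.masks = [np.asarray(m, dtype=bool) for m in self.masks]
        if not self.slice_indices:
            self.slice_indices = list(range(len(self.masks)))
        shapes = {m.shape for m in self.masks}
        if len(shapes) > 1:
            raise ValueError(f"masks must share one shape, got {shapes}")


@dataclass
class DSCReport:
    """Per-pair Dice values plus their mean and std (NaN pairs excluded)."""

    pairwise: list[dict]
    mean: float
    std: float


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice similarity coefficient 2|A∩B| / (|A|+|B|) of two binary masks.

    Returns NaN (with a warning) when both masks are empty, where the
    coefficient is undefined.
    """
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        warnings.warn("dice of two empty masks is undefined; returning NaN",
                      RuntimeWarning, stacklevel=2)
        return float("nan")
    return 2.0 * int(np.logical_and(a, b).sum()) / denom


def warp_mask_stack(
    masks: LumenMaskStack, result: StackRegistrationResult
) -> LumenMaskStack:
    """Warp each slice's lumen mask into the registered frame.

    Each mask is warped by its slice's total transform (ROI registration
    composed with rough alignment) using nearest-neighbor interpolation, so
    masks stay binary.
    """
    if len(masks.masks) != len(result.per_slice):
        raise ValueError(
            f"{len(masks.masks)} masks for {len(result.per_slice)} registered slices"
        )
    warped = [warp_mask(m, rec.total) for m, rec in zip(masks.masks, result.per_slice)]
    return LumenMaskStack(warped, list(masks.slice_indices))


def evaluate_stack(masks: LumenMaskStack) -> DSCReport:
    """Dice for every consecutive mask pair; mean ± std over defined pairs."""
    if len(masks.masks) < 2:
        raise ValueError("need at least 2 masks to evaluate")
    pairwise = []
    values = []
    for i in range(len(masks.masks) - 1):
        a, b = masks.masks[i], masks.masks[i + 1]
        if not a.any() and not b.any():
            warnings.warn(f"both masks empty for pair ({i}, {i + 1}); excluded",
                          RuntimeWarning, stacklevel=2)
            d = float("nan")
        else:
            d = dice(a, b)
        pairwise.append({"slice_i": masks.slice_indices[i],
                         "slice_j": masks.slice_indices[i + 1], "dsc": d})
        if not np.isnan(d):
            values.append(d)
    mean = float(np.mean(values)) if values else float("nan")
    std = float(np.std(values)) if values else float("nan")
    return DSCReport(pairwise, mean, std)


def export_volume(images_or_masks: list[np.ndarray], out_path) -> None:
    """Write a stack as a multi-page TIFF volume (z = slice order)."""
    if not images_or_masks:
        raise ValueError("cannot export an empty stack")
    arrs = []
    for a in images_or_masks:
        a = np.asarray(a)
        if a.dtype == bool:
            a = (a * 255).astype(np.uint8)
        elif np.issubdtype(a.dtype, np.floating):
            a = np.clip(a, 0, 255).astype(np.uint8) if a.max() > 1 else (
                a * 255).astype(np.uint8)
        arrs.append(a)
    try:
        tifffile.imwrite(str(out_path), np.stack(arrs), photometric="minisblack")
    except OSError as exc:
        raise OSError(f"failed to write volume to {out_path}: {exc}") from exc
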