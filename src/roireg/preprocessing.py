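"""Removal of extra stains and artifacts surrounding the tissue.

Stray stain drops, pen marks and detached tissue fragments around the main
section create spurious structure that can pull a registration off the
tissue.  This stage segments the main tissue section and blanks everything
outside its convex hull: grayscale conversion and Gaussian smoothing,
thresholding at the mean intensity, morphological opening/closing with a
disc, selection of the contours that are large and central, and cropping to
their convex hull.  Pixels outside the hull are replaced by a background
fill value so no hard edge (and hence no fake keypoint) is introduced.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage import color, morphology

from .image import SlideImage

__all__ = [
    "PreprocessParams",
    "TissueMask",
    "to_grayscale_smoothed",
    "threshold_at_mean",
    "morphological_cleanup",
    "clean_tissue",
]

log = logging.getLogger(__name__)


@dataclass
class PreprocessParams:
    """Tunables of the artifact-removal stage.

    sigma : Gaussian smoothing std in pixels at the working level.
    kernel_radius : disc radius for morphological opening/closing.
    tissue_below_mean : tissue darker than background (brightfield default).
    min_score_fraction : keep contours scoring at least this fraction of the
        best contour's centrality/area score.
    """

    sigma: float = 10.0
    kernel_radius: int = 20
    tissue_below_mean: bool = True
    min_score_fraction: float = 0.25
    level: int = 0


@dataclass
class TissueMask:
    """Binary tissue mask with a record of the step that produced it."""

    mask: np.ndarray
    provenance: str = "threshold"  # threshold | morphology | convex_hull
    flags: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)


def to_grayscale_smoothed(image: SlideImage, sigma: float = 10.0) -> SlideImage:
    """Convert to single-channel and Gaussian-smooth with the given sigma."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    px = np.asarray(image.pixels, dtype=float)
    if px.size == 0:
        raise ValueError("empty image")
    if px.ndim == 3:
        scale = px.max() if px.max() > 1 else 1.0
        px = color.rgb2gray(px / scale) * scale
    smoothed = ndi.gaussian_filter(px, sigma)
    return SlideImage(smoothed, image.level, image.spacing, image.slice_index)


def threshold_at_mean(image: SlideImage, below: bool = True) -> TissueMask:
    """Mask pixels on the tissue side of the image-mean intensity.

    Brightfield tissue is darker than the illuminated background, so the
    default keeps pixels strictly below the mean.
    """
    px = image.pixels
    if px.ndim != 2:
        raise ValueError("threshold_at_mean expects a single-channel image")
    mean = px.mean()
    mask = px < mean if below else px > mean
    return TissueMask(mask, "threshold")


def morphological_cleanup(mask: TissueMask, radius: int = 20) -> TissueMask:
    """Opening then closing with a disc, removing specks and sealing cracks."""
    if radius < 1:
        raise ValueError("radius must be >= 1")
    disc = morphology.disk(radius)
    m = morphology.opening(mask.mask, disc)
    m = morphology.closing(m, disc)
    return TissueMask(m, "morphology", mask.flags)


def _select_components(mask: np.ndarray, min_score_fraction: float) -> np.ndarray:
    """Keep connected components that are large and near the image center.

    Each external component is scored area / (1 + distance of its centroid
    from the image center); the top scorer and every component within
    ``min_score_fraction`` of that score are kept.
    """
    labels, n = ndi.label(mask)
    if n == 0:
        return np.zeros_like(mask)
    h, w = mask.shape
    center = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    areas = ndi.sum_labels(np.ones_like(labels), labels, index=range(1, n + 1))
    centroids = np.array(ndi.center_of_mass(mask, labels, range(1, n + 1)))
    dist = np.linalg.norm(centroids - center, axis=1)
    scores = areas / (1.0 + dist)
    keep = np.flatnonzero(scores >= min_score_fraction * scores.max()) + 1
    return np.isin(labels, keep)


def clean_tissue(
    image: SlideImage, params: PreprocessParams | None = None
) -> tuple[SlideImage, TissueMask]:
    """Full artifact-removal pipeline, returning the cleaned image and hull mask.

    Pixels inside the convex hull of the selected tissue contours are left
    untouched; everything outside is replaced by the per-channel median of
    the non-tissue (background) pixels.  A blank slide comes back unchanged
    with a ``no_tissue_found`` flag instead of raising.
    """
    params = params or PreprocessParams()
    gray = to_grayscale_smoothed(image, params.sigma)
    thresh = threshold_at_mean(gray, below=params.tissue_below_mean)
    cleaned = morphological_cleanup(thresh, params.kernel_radius)
    selected = _select_components(cleaned.mask, params.min_score_fraction)
    if not selected.any():
        log.warning("slice %d: no tissue contour found; image left unchanged",
                    image.slice_index)
        full = TissueMask(np.ones_like(selected), "convex_hull", ("no_tissue_found",))
        return SlideImage(np.asarray(image.pixels, dtype=float).copy(),
                          image.level, image.spacing, image.slice_index), full
    hull = morphology.convex_hull_image(selected)

    px = np.asarray(image.pixels, dtype=float).copy()
    bg = ~thresh.mask
    if px.ndim == 2:
        fill = float(np.median(px[bg])) if bg.any() else float(np.median(px))
        px[~hull] = fill
    else:
        for c in range(px.shape[2]):
            ch = px[..., c]
            fill = float(np.median(ch[bg])) if bg.any() else float(np.median(ch))
            ch[~hull] = fill
    n_labels = int(ndi.label(selected)[1])
    log.info("slice %d: %d tissue contour(s) kept, hull area %d px",
             image.slice_index, n_labels, int(hull.sum()))
    cleaned_img = SlideImage(px, image.level, image.spacing, image.slice_index)
    return cleaned_img, TissueMask(hull, "convex_hull")


def background_fill_value(image: SlideImage, params: PreprocessParams | None = None) -> float:
    """Fill value the cleanup stage would use for this image (grayscale)."""
    params = params or PreprocessParams()
    gray = to_grayscale_smoothed(image, params.sigma)
    bg = ~threshold_at_mean(gray, below=params.tissue_below_mean).mask
    px = gray.pixels
    return float(np.median(px[bg])) if bg.any() else float(np.median(px))
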