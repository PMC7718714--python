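"""Slide images and multi-resolution pyramids.

A whole-slide scan is stored as a pyramid of images, level ``r`` downsampled
by ``2^r`` from the full-resolution level 0.  Pyramids here are built by 2x2
block averaging, which is how scanners' pyramid levels are conventionally
produced and keeps intensities consistent across levels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SlideImage", "SlidePyramid", "block_downsample", "build_pyramid"]


@dataclass
class SlideImage:
    """One slice's image at a single pyramid level.

    ``pixels`` is 2-D (grayscale) or 3-D (RGB); ``level`` is the pyramid
    level; ``spacing`` the optional µm/pixel at that level; ``slice_index``
    the position in the stack.
    """

    pixels: np.ndarray
    level: int = 0
    spacing: float | None = None
    slice_index: int = 0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim not in (2, 3) or min(self.pixels.shape[:2]) < 1:
            raise ValueError("slide image must be a nonempty 2-D or 3-D array")
        if self.level < 0:
            raise ValueError("pyramid level must be >= 0")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.pixels.shape

    @property
    def is_gray(self) -> bool:
        return self.pixels.ndim == 2


@dataclass
class SlidePyramid:
    """All resolution levels of one slice, level 0 first."""

    levels: list[SlideImage] = field(default_factory=list)
    slice_index: int = 0

    def __post_init__(self) -> None:
        for r, img in enumerate(self.levels):
            if img.level != r:
                raise ValueError(f"pyramid level {r} holds an image tagged level {img.level}")
            expect = _level_shape(self.levels[0].pixels.shape[:2], r)
            got = img.pixels.shape[:2]
            if any(abs(e - g) > 1 for e, g in zip(expect, got)):
                raise ValueError(
                    f"level-{r} shape {got} inconsistent with level-0 shape "
                    f"{self.levels[0].pixels.shape[:2]}"
                )

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    def __getitem__(self, r: int) -> SlideImage:
        return self.levels[r]


def _level_shape(shape0: tuple[int, int], r: int) -> tuple[int, int]:
    return tuple(int(np.ceil(s / 2**r)) for s in shape0)


def block_downsample(pixels: np.ndarray) -> np.ndarray:
    """2x2 block-mean downsampling; odd edges are padded by replication."""
    pixels = np.asarray(pixels, dtype=float)
    h, w = pixels.shape[:2]
    ph, pw = h % 2, w % 2
    if ph or pw:
        pad = [(0, ph), (0, pw)] + [(0, 0)] * (pixels.ndim - 2)
        pixels = np.pad(pixels, pad, mode="edge")
    h, w = pixels.shape[:2]
    out = pixels.reshape(h // 2, 2, w // 2, 2, *pixels.shape[2:]).mean(axis=(1, 3))
    return out


def build_pyramid(
    level0: np.ndarray, n_levels: int, slice_index: int = 0, spacing: float | None = None
) -> SlidePyramid:
    """Build an ``n_levels``-deep pyramid from a full-resolution image."""
    if n_levels < 1:
        raise ValueError("a pyramid needs at least one level")
    imgs = [SlideImage(np.asarray(level0, dtype=float), 0, spacing, slice_index)]
    for r in range(1, n_levels):
        px = block_downsample(imgs[-1].pixels)
        sp = spacing * 2**r if spacing is not None else None
        imgs.append(SlideImage(px, r, sp, slice_index))
    return SlidePyramid(imgs, slice_index)
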