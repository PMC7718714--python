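"""Pyramid, mask and transform I/O.

Canonical on-disk layout is one directory per slice holding one plain TIFF
per pyramid level::

    stack/
      slice_000/level_0.tif ... level_3.tif
      slice_001/...

Missing levels are synthesized by block-mean downsampling (with a warning).
Transforms serialize to JSON with full float precision; masks are written
as single-channel PNG/TIFF with 0 = background.
"""

from __future__ import annotations

import json
import logging
import re
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

from .attention import (LevelRegistration, PairRegistration, ROIBox,
                        StackRegistrationResult)
from .evaluation import LumenMaskStack
from .image import SlideImage, SlidePyramid, block_downsample
from .transforms import RigidTransform

__all__ = [
    "load_slide_stack", "save_slide_stack",
    "save_transforms", "load_transforms",
    "load_mask_stack", "save_mask_stack",
    "load_roi", "save_roi",
]

log = logging.getLogger(__name__)

TRANSFORM_SCHEMA = 1


# ----------------------------------------------------------------- pyramids
def load_slide_stack(path: str | Path, n_levels: int | None = None) -> list[SlidePyramid]:
    """Read ordered slide pyramids from the ``slice_*/level_*.tif`` layout."""
    root = Path(path)
    slice_dirs = sorted(
        (d for d in root.glob("slice_*") if d.is_dir()),
        key=lambda d: int(re.search(r"(\d+)$", d.name).group(1)),
    )
    if not slice_dirs:
        raise FileNotFoundError(f"no slice_* directories found under {root}")
    pyramids = []
    for d in slice_dirs:
        idx = int(re.search(r"(\d+)$", d.name).group(1))
        level_files = sorted(
            d.glob("level_*.tif*"),
            key=lambda f: int(re.search(r"level_(\d+)", f.name).group(1)),
        )
        if not level_files:
            raise FileNotFoundError(f"no level_*.tif files in {d}")
        imgs = []
        for f in level_files:
            r = int(re.search(r"level_(\d+)", f.name).group(1))
            try:
                px = tifffile.imread(str(f))
            except Exception as exc:
                raise OSError(f"unreadable slide file {f}: {exc}") from exc
            imgs.append(SlideImage(np.asarray(px, dtype=float), r, slice_index=idx))
        want = n_levels or len(imgs)
        while len(imgs) < want:
            log.warning("%s: level %d missing; synthesizing by block-mean downsampling",
                        d.name, len(imgs))
            px = block_downsample(imgs[-1].pixels)
            imgs.append(SlideImage(px, len(imgs), slice_index=idx))
        pyramids.append(SlidePyramid(imgs, idx))
    shapes = {p[0].pixels.shape for p in pyramids}
    if len(shapes) > 1:
        raise ValueError(f"inconsistent level-0 shapes across slices: {shapes}")
    return pyramids


def save_slide_stack(pyramids: list[SlidePyramid], path: str | Path) -> None:
    root = Path(path)
    for pyr in pyramids:
        d = root / f"slice_{pyr.slice_index:03d}"
        d.mkdir(parents=True, exist_ok=True)
        for img in pyr.levels:
            tifffile.imwrite(str(d / f"level_{img.level}.tif"),
                             img.pixels.astype(np.float32))


# ---------------------------------------------------------------- transforms
def _level_to_dict(lv: LevelRegistration) -> dict:
    return {
        "level": lv.level,
        "chosen_transform": lv.chosen_transform.to_dict(),
        "candidate_count": lv.candidate_count,
        "best_ssd": lv.best_ssd,
        "match_count": lv.match_count,
        "flags": list(lv.flags),
        "matches_used": [
            {"p_fixed": list(m.p_fixed), "p_moving": list(m.p_moving),
             "descriptor_distance": m.descriptor_distance}
            for m in lv.matches_used
        ],
    }


def save_transforms(result: StackRegistrationResult, path: str | Path) -> None:
    """Serialize a stack registration result to JSON (full float precision)."""
    doc = {
        "schema_version": TRANSFORM_SCHEMA,
        "roi0": None if result.roi0 is None else {
            "center_x": result.roi0.center_x, "center_y": result.roi0.center_y,
            "width": result.roi0.width, "height": result.roi0.height,
            "level": result.roi0.level,
        },
        "config": result.config,
        "per_slice": [
            {
                "slice_index": rec.slice_index,
                "rough": rec.rough.to_dict(),
                "composed_roi": rec.composed_roi.to_dict(),
                "flags": list(rec.flags),
                "levels": [_level_to_dict(lv) for lv in rec.levels],
            }
            for rec in result.per_slice
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True))


def load_transforms(path: str | Path) -> StackRegistrationResult:
    """Inverse of :func:`save_transforms`; load(save(x)) preserves matrices."""
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"corrupt transform file {path}: {exc}") from exc
    version = doc.get("schema_version")
    if version != TRANSFORM_SCHEMA:
        raise ValueError(f"unsupported transform schema version {version!r}")
    from .attention import KeypointMatch

    per_slice = []
    for rec in doc["per_slice"]:
        levels = [
            LevelRegistration(
                lv["level"],
                RigidTransform.from_dict(lv["chosen_transform"]),
                lv["candidate_count"],
                lv["best_ssd"],
                [KeypointMatch(tuple(m["p_fixed"]), tuple(m["p_moving"]),
                               m["descriptor_distance"]) for m in lv["matches_used"]],
                lv.get("match_count", 0),
                tuple(lv.get("flags", ())),
            )
            for lv in rec["levels"]
        ]
        per_slice.append(PairRegistration(
            rec["slice_index"],
            RigidTransform.from_dict(rec["rough"]),
            RigidTransform.from_dict(rec["composed_roi"]),
            levels,
            tuple(rec.get("flags", ())),
        ))
    roi = None
    if doc.get("roi0"):
        r = doc["roi0"]
        roi = ROIBox(r["center_x"], r["center_y"], r["width"], r["height"], r["level"])
    return StackRegistrationResult(per_slice, roi, doc.get("config", {}))


# --------------------------------------------------------------------- masks
def load_mask_stack(path: str | Path) -> LumenMaskStack:
    """Read per-slice binary masks (``mask_{i}.png``/``.tif``, 0 = background)."""
    root = Path(path)
    files = sorted(
        [f for f in root.iterdir()
         if f.suffix.lower() in (".png", ".tif", ".tiff") and re.search(r"\d+", f.stem)],
        key=lambda f: int(re.search(r"(\d+)", f.stem).group(1)),
    )
    if not files:
        raise FileNotFoundError(f"no mask images found under {root}")
    masks = [np.asarray(iio.imread(f)) > 0 for f in files]
    idx = [int(re.search(r"(\d+)", f.stem).group(1)) for f in files]
    return LumenMaskStack(masks, idx)


def save_mask_stack(masks: LumenMaskStack, path: str | Path) -> None:
    root = Path(path)
    root.mkdir(parents=True, exist_ok=True)
    for m, i in zip(masks.masks, masks.slice_indices):
        iio.imwrite(root / f"mask_{i:03d}.png", (m.astype(np.uint8) * 255))


# ----------------------------------------------------------------------- ROI
def load_roi(path: str | Path) -> ROIBox:
    """Read an ROI definition (YAML/JSON) given at any level; convert to level 0."""
    import yaml

    d = yaml.safe_load(Path(path).read_text())
    level = int(d.get("level", 0))
    f = 2**level
    return ROIBox(float(d["center_x"]) * f, float(d["center_y"]) * f,
                  int(d["width"]), int(d["height"]), 0)


def save_roi(roi: ROIBox, path: str | Path) -> None:
    import yaml

    Path(path).write_text(yaml.safe_dump({
        "center_x": float(roi.center_x), "center_y": float(roi.center_y),
        "width": int(roi.width), "height": int(roi.height), "level": int(roi.level),
    }))
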