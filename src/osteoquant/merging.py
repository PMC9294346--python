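"""Deduplication of overlapping-tile detections by ellipse fusion.

When a well is tiled with 50% overlap, one cell can be detected in up to
four segments.  To reduce those duplicates to one count, each detected box
is shrunk by 20% in width and height, the inscribed ellipse is rasterized
onto a well-sized binary canvas, connected ellipse regions are fused, and
one output box (the tight box of the fused region) is emitted per region.
Shrinking before filling separates compact neighbouring cells whose full
boxes would otherwise touch.

Rasterization rule: a pixel is set iff its center (j+0.5, i+0.5) lies inside
some shrunk ellipse.  Connectivity is 8-connected.  An ellipse semi-axis
that shrinks below 0.5 px still fills the single pixel nearest the center.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .annotation_io import DetectionRecord

__all__ = [
    "DEFAULT_SHRINK_FACTOR",
    "MergedRegion",
    "shrink_box",
    "rasterize_ellipses",
    "merge_detections",
    "regions_to_records",
]

DEFAULT_SHRINK_FACTOR = 0.2
_STRUCT8 = np.ones((3, 3), dtype=int)


@dataclass
class MergedRegion:
    """One fused connected region and the detections that contributed to it."""

    component_id: int
    pixel_count: int
    cx: float
    cy: float
    w: float
    h: float
    contributing_detection_ids: list[int]


def shrink_box(box: DetectionRecord, factor: float = DEFAULT_SHRINK_FACTOR) -> DetectionRecord:
    """Scale a box's width and height by (1 - factor), keeping its center."""
    if not 0.0 <= factor < 1.0:
        raise ValueError("shrink factor must be in [0, 1)")
    return replace(box, w=box.w * (1.0 - factor), h=box.h * (1.0 - factor))


def _ellipse_window(
    cx: float, cy: float, a: float, b: float, width: int, height: int
):
    """Pixel-center-inside test restricted to the ellipse's bounding window.

    Returns (i0, j0, inside_mask) with the window clipped to the canvas, or
    None when no pixel center falls inside.
    """
    if a < 0.5 or b < 0.5:
        # degenerate axis: the single pixel nearest the center
        if 0 <= cx < width and 0 <= cy < height:
            j = int(np.clip(np.floor(cx), 0, width - 1))
            i = int(np.clip(np.floor(cy), 0, height - 1))
            return i, j, np.ones((1, 1), dtype=bool)
        return None
    j0 = max(0, int(np.floor(cx - a - 0.5)))
    j1 = min(width - 1, int(np.ceil(cx + a + 0.5)))
    i0 = max(0, int(np.floor(cy - b - 0.5)))
    i1 = min(height - 1, int(np.ceil(cy + b + 0.5)))
    if j1 < j0 or i1 < i0:
        return None
    dx = (np.arange(j0, j1 + 1) + 0.5 - cx) / a
    dy = (np.arange(i0, i1 + 1) + 0.5 - cy) / b
    inside = dy[:, None] ** 2 + dx[None, :] ** 2 <= 1.0
    if not inside.any():
        return None
    return i0, j0, inside


def rasterize_ellipses(
    boxes: list[DetectionRecord],
    width_px: int,
    height_px: int,
) -> np.ndarray:
    """Union of the ellipses inscribed in the (already shrunk) boxes.

    Boxes are clipped at the canvas edges; a box fully outside the canvas is
    skipped with a warning.
    """
    mask = np.zeros((height_px, width_px), dtype=bool)
    for box in boxes:
        win = _ellipse_window(box.cx, box.cy, box.w / 2.0, box.h / 2.0,
                              width_px, height_px)
        if win is None:
            warnings.warn(
                f"detection at ({box.cx:.1f}, {box.cy:.1f}) lies fully outside "
                f"the {width_px} x {height_px} canvas; skipped",
                stacklevel=2,
            )
            continue
        i0, j0, inside = win
        h, w = inside.shape
        mask[i0 : i0 + h, j0 : j0 + w] |= inside
    return mask


def merge_detections(
    records: list[DetectionRecord],
    width_px: int,
    height_px: int,
    shrink_factor: float = DEFAULT_SHRINK_FACTOR,
) -> list[MergedRegion]:
    """Fuse overlapping detections of the same cell into single regions.

    Returns one region per 8-connected component of the shrunk-ellipse mask,
    with the region's tight bounding box (well frame) and the ids (indices
    into ``records``) of the detections whose ellipse intersects it.  The
    number of regions never exceeds the number of input detections.
    """
    shrunk = [shrink_box(r, shrink_factor) for r in records]
    mask = rasterize_ellipses(shrunk, width_px, height_px)
    labels, n = ndimage.label(mask, structure=_STRUCT8)
    if n == 0:
        return []
    contributors: dict[int, list[int]] = {k: [] for k in range(1, n + 1)}
    for det_id, box in enumerate(shrunk):
        win = _ellipse_window(box.cx, box.cy, box.w / 2.0, box.h / 2.0,
                              width_px, height_px)
        if win is None:
            continue
        i0, j0, inside = win
        h, w = inside.shape
        touched = np.unique(labels[i0 : i0 + h, j0 : j0 + w][inside])
        for comp in touched:
            if comp > 0:
                contributors[int(comp)].append(det_id)
    regions: list[MergedRegion] = []
    counts = np.bincount(labels.ravel())
    for comp_id, sl in enumerate(ndimage.find_objects(labels), start=1):
        ys, xs = sl
        regions.append(
            MergedRegion(
                component_id=comp_id,
                pixel_count=int(counts[comp_id]),
                cx=(xs.start + xs.stop) / 2.0,
                cy=(ys.start + ys.stop) / 2.0,
                w=float(xs.stop - xs.start),
                h=float(ys.stop - ys.start),
                contributing_detection_ids=contributors[comp_id],
            )
        )
    return regions


def regions_to_records(regions: list[MergedRegion]) -> list[DetectionRecord]:
    """Convert merged regions back to detection records (confidence 1.0)."""
    return [
        DetectionRecord(cx=r.cx, cy=r.cy, w=r.w, h=r.h, confidence=1.0, frame="well")
        for r in regions
    ]
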