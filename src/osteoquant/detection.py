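"""Detector contract and the classical reference detector.

The pipeline does not bundle a neural network: any callable with the
signature ``detector(segment_raster) -> list[DetectionRecord]`` (records in
segment frame) can be run over a well, and detections produced externally
can be imported through :func:`osteoquant.annotation_io.read_detections`.

The bundled reference detector is a deterministic classical pipeline
(grayscale -> global threshold -> connected components -> area filter ->
tight boxes) intended for desk-scale testing of the surrounding machinery.
TRAP-stained osteoclasts are darker than the brightfield background, so the
foreground is the set of pixels *below* the intensity threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable

import numpy as np
from scipy import ndimage

from .annotation_io import DetectionRecord, sort_detections
from .tiles import SegmentGrid, WellImage, extract_segment, to_global

__all__ = ["DetectorParams", "WellDetections", "ReferenceDetector", "run_well"]

#: standard luma weights for RGB -> grayscale
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass(frozen=True)
class DetectorParams:
    """Tuning knobs of the reference detector.

    intensity_threshold is a fraction of the 8-bit dynamic range: pixels with
    luma < threshold * 255 are foreground.  Components with area outside
    [min_area_px, max_area_px] are discarded.  Confidence is assigned by
    ``confidence_rule``: ``area_scaled`` = component area / max_area_px
    (capped at 1), monotone in area; ``contrast_scaled`` = mean darkness of
    the component below the threshold, as a fraction of the threshold level.
    """

    intensity_threshold: float = 0.7
    min_area_px: int = 50
    max_area_px: int = 5000
    confidence_rule: str = "area_scaled"

    def __post_init__(self) -> None:
        if not 0.0 < self.intensity_threshold <= 1.0:
            raise ValueError("intensity_threshold must be in (0, 1]")
        if not 0 < self.min_area_px < self.max_area_px:
            raise ValueError("need 0 < min_area_px < max_area_px")
        if self.confidence_rule not in ("area_scaled", "contrast_scaled"):
            raise ValueError(f"unknown confidence rule {self.confidence_rule!r}")


@dataclass
class WellDetections:
    """All retained detections for one well, in well-frame coordinates."""

    well_id: str
    mode: str  # "overlap" or "nonoverlap"
    records: list[DetectionRecord]


def _to_gray(raster: np.ndarray) -> np.ndarray:
    if raster.ndim == 3:
        return raster[..., :3].astype(np.float64) @ _LUMA
    return raster.astype(np.float64)


class ReferenceDetector:
    """Deterministic threshold/connected-components detector for dark blobs."""

    def __init__(self, params: DetectorParams | None = None):
        self.params = params or DetectorParams()

    def __call__(self, raster: np.ndarray) -> list[DetectionRecord]:
        return self.detect(raster)

    def detect(self, raster: np.ndarray) -> list[DetectionRecord]:
        if raster.size == 0:
            raise ValueError("empty raster")
        p = self.params
        gray = _to_gray(raster)
        level = p.intensity_threshold * 255.0
        fg = gray < level
        # 8-connectivity
        labels, n = ndimage.label(fg, structure=np.ones((3, 3), dtype=int))
        if n == 0:
            return []
        records: list[DetectionRecord] = []
        slices = ndimage.find_objects(labels)
        areas = np.bincount(labels.ravel())
        for comp_id, sl in enumerate(slices, start=1):
            area = int(areas[comp_id])
            if not (p.min_area_px <= area <= p.max_area_px):
                continue
            ys, xs = sl
            w = xs.stop - xs.start
            h = ys.stop - ys.start
            cx = (xs.start + xs.stop) / 2.0
            cy = (ys.start + ys.stop) / 2.0
            if p.confidence_rule == "area_scaled":
                conf = min(1.0, area / p.max_area_px)
            else:
                comp_mask = labels[sl] == comp_id
                mean_val = float(gray[sl][comp_mask].mean())
                conf = min(1.0, max(0.0, (level - mean_val) / level))
            records.append(
                DetectionRecord(cx=cx, cy=cy, w=float(w), h=float(h),
                                confidence=conf, frame="segment")
            )
        return sort_detections(records)


def run_well(
    well: WellImage,
    grid: SegmentGrid,
    detector: Callable[[np.ndarray], list[DetectionRecord]],
    detection_threshold: float = 0.0,
    pad_value: int = 0,
) -> WellDetections:
    """Run a detector over every segment of a well and pool the detections.

    Detections with confidence below ``detection_threshold`` are discarded;
    surviving segment-frame boxes are mapped to the well frame.  Boxes whose
    center lands outside the well (possible only in the padded margin of
    edge segments) are dropped.  The mode is ``overlap`` when the grid
    overlaps, else ``nonoverlap``; overlap-mode results should be passed
    through the ellipse-fusion merger before counting.
    """
    if not 0.0 <= detection_threshold <= 1.0:
        raise ValueError("detection_threshold must be in [0, 1]")
    records: list[DetectionRecord] = []
    for ref in grid.refs():
        raster = extract_segment(well, ref, pad_value=pad_value)
        try:
            segment_records = detector(raster)
        except Exception as exc:
            raise RuntimeError(
                f"detector failed on segment r{ref.row}_c{ref.col} "
                f"of well {well.well_id!r}: {exc}"
            ) from exc
        for r in segment_records:
            if r.confidence < detection_threshold:
                continue
            gx, gy = to_global(ref, r.cx, r.cy)
            if not (0 <= gx < well.width_px and 0 <= gy < well.height_px):
                continue
            records.append(replace(r, cx=gx, cy=gy, frame="well", row=ref.row, col=ref.col))
    mode = "overlap" if grid.overlap_frac > 0 else "nonoverlap"
    return WellDetections(well_id=well.well_id, mode=mode, records=sort_detections(records))
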