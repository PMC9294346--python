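"""Tiling of whole-well images into fixed-size, optionally overlapping segments.

A well image (one microscope scan of a culture well, on the order of 10^4 px
per side) is decomposed into square segments of ``segment_size_px`` pixels
whose origins lie on a regular lattice with spacing ``stride_px =
segment_size_px * (1 - overlap_frac)``.  Segments whose window overruns the
right/bottom image edge are zero-padded on extraction rather than shifted
inward, which keeps the well->segment coordinate map affine and makes the
segment count ``ceil(width/stride) * ceil(height/stride)``.

Human annotations arrive as point marks (one click per osteoclast); ground
truth boxes are synthesized around each mark with a fixed side length equal
to a small fraction of the well width, and clipped wherever they extend past
a segment border.  Clipped boxes are kept regardless of remaining area.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
from PIL import Image
import tifffile

__all__ = [
    "WellImage",
    "SegmentGrid",
    "SegmentRef",
    "PointMark",
    "GTBox",
    "grid_dims",
    "extract_segment",
    "to_global",
    "to_local",
    "box_side_from_width",
    "assign_labels",
    "load_well_image",
    "save_segments",
]

DEFAULT_SEGMENT_SIZE = 416
DEFAULT_OVERLAP = 0.5
#: default bounding-box side as a fraction of well-image width
DEFAULT_BOX_FRACTION = 0.009756


@dataclass
class WellImage:
    """An 8-bit RGB or grayscale raster of one culture well.

    Pixel coordinates are 0-based, origin at top-left, x rightward,
    y downward.
    """

    pixels: np.ndarray
    well_id: str = "well"
    experiment_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim not in (2, 3):
            raise ValueError("pixels must be a 2D (gray) or 3D (RGB) array")
        if self.height_px < 1 or self.width_px < 1:
            raise ValueError("well image must have positive dimensions")

    @property
    def height_px(self) -> int:
        return int(self.pixels.shape[0])

    @property
    def width_px(self) -> int:
        return int(self.pixels.shape[1])


@dataclass(frozen=True)
class SegmentGrid:
    """The overlapping tile lattice over a well image."""

    width_px: int
    height_px: int
    segment_size_px: int = DEFAULT_SEGMENT_SIZE
    overlap_frac: float = DEFAULT_OVERLAP
    stride_px: int = field(init=False)
    n_cols: int = field(init=False)
    n_rows: int = field(init=False)

    def __post_init__(self) -> None:
        if self.width_px < 1 or self.height_px < 1:
            raise ValueError("image dimensions must be >= 1")
        if self.segment_size_px < 1:
            raise ValueError("segment size must be >= 1")
        if not 0.0 <= self.overlap_frac < 1.0:
            raise ValueError("overlap_frac must lie in [0, 1)")
        stride = self.segment_size_px * (1.0 - self.overlap_frac)
        if abs(stride - round(stride)) > 1e-9 or round(stride) < 1:
            raise ValueError(
                f"overlap {self.overlap_frac} with segment size "
                f"{self.segment_size_px} gives a non-integer stride {stride}"
            )
        object.__setattr__(self, "stride_px", int(round(stride)))
        object.__setattr__(
            self, "n_cols", math.ceil(self.width_px / self.stride_px)
        )
        object.__setattr__(
            self, "n_rows", math.ceil(self.height_px / self.stride_px)
        )

    @property
    def n_segments(self) -> int:
        return self.n_cols * self.n_rows

    def refs(self):
        """Iterate all segment references in row-major order."""
        for row in range(self.n_rows):
            for col in range(self.n_cols):
                yield SegmentRef(row, col, self)

    def ref(self, row: int, col: int) -> "SegmentRef":
        return SegmentRef(row, col, self)

    def refs_containing(self, x: float, y: float) -> list["SegmentRef"]:
        """All segments whose half-open window [origin, origin+size) contains (x, y)."""
        s, size = self.stride_px, self.segment_size_px
        # col*stride <= x < col*stride + size  =>  (x - size)/s < col <= x/s
        col_lo = max(0, math.floor((x - size) / s) + 1)
        col_hi = min(self.n_cols - 1, math.floor(x / s))
        row_lo = max(0, math.floor((y - size) / s) + 1)
        row_hi = min(self.n_rows - 1, math.floor(y / s))
        return [
            SegmentRef(r, c, self)
            for r in range(row_lo, row_hi + 1)
            for c in range(col_lo, col_hi + 1)
        ]


@dataclass(frozen=True)
class SegmentRef:
    """One tile position in a :class:`SegmentGrid`."""

    row: int
    col: int
    grid: SegmentGrid

    def __post_init__(self) -> None:
        if not (0 <= self.row < self.grid.n_rows):
            raise ValueError(f"row {self.row} outside grid (n_rows={self.grid.n_rows})")
        if not (0 <= self.col < self.grid.n_cols):
            raise ValueError(f"col {self.col} outside grid (n_cols={self.grid.n_cols})")

    @property
    def origin_x(self) -> int:
        return self.col * self.grid.stride_px

    @property
    def origin_y(self) -> int:
        return self.row * self.grid.stride_px

    @property
    def key(self) -> tuple[int, int]:
        return (self.row, self.col)


@dataclass(frozen=True)
class PointMark:
    """A human click annotation: the pixel coordinate of one counted cell."""

    x: float
    y: float
    annotator_id: str = ""


@dataclass(frozen=True)
class GTBox:
    """A ground-truth bounding box in center/size form.

    ``frame`` records whether coordinates are in the well frame or a
    segment's local frame.
    """

    cx: float
    cy: float
    w: float
    h: float
    frame: str = "well"
    source_mark: Optional[PointMark] = None

    def __post_init__(self) -> None:
        if self.w <= 0 or self.h <= 0:
            raise ValueError(f"box must have positive size, got w={self.w}, h={self.h}")

    @property
    def x0(self) -> float:
        return self.cx - self.w / 2.0

    @property
    def x1(self) -> float:
        return self.cx + self.w / 2.0

    @property
    def y0(self) -> float:
        return self.cy - self.h / 2.0

    @property
    def y1(self) -> float:
        return self.cy + self.h / 2.0


def grid_dims(
    width_px: int,
    height_px: int,
    segment_size_px: int = DEFAULT_SEGMENT_SIZE,
    overlap_frac: float = DEFAULT_OVERLAP,
) -> SegmentGrid:
    """Compute the segment lattice for a well image.

    With the default 416-px segments at 50% overlap, a 10,248 x 9,122 well
    yields 50 x 44 = 2,200 segments; without overlap the same well yields
    25 x 22 = 550.
    """
    return SegmentGrid(width_px, height_px, segment_size_px, overlap_frac)


def extract_segment(
    well: WellImage,
    ref: SegmentRef,
    pad_value: int = 0,
) -> np.ndarray:
    """Copy one segment window out of the well raster.

    The output is always ``segment_size_px`` square; area beyond the image's
    right/bottom edges is filled with ``pad_value``.
    """
    size = ref.grid.segment_size_px
    ox, oy = ref.origin_x, ref.origin_y
    h, w = well.height_px, well.width_px
    if well.pixels.ndim == 3:
        out = np.full((size, size, well.pixels.shape[2]), pad_value, dtype=well.pixels.dtype)
    else:
        out = np.full((size, size), pad_value, dtype=well.pixels.dtype)
    y_end = min(oy + size, h)
    x_end = min(ox + size, w)
    out[: y_end - oy, : x_end - ox] = well.pixels[oy:y_end, ox:x_end]
    return out


def to_global(ref: SegmentRef, x_local: float, y_local: float) -> tuple[float, float]:
    """Map a segment-frame point into the well frame."""
    return (ref.origin_x + x_local, ref.origin_y + y_local)


def to_local(ref: SegmentRef, x: float, y: float) -> tuple[float, float]:
    """Map a well-frame point into the segment frame (inverse of :func:`to_global`)."""
    return (x - ref.origin_x, y - ref.origin_y)


def box_side_from_width(well_width_px: int, fraction: float = DEFAULT_BOX_FRACTION) -> int:
    """Side length (px) of the synthesized ground-truth boxes.

    Most osteoclasts fit inside a square whose side is ~0.98% of the well
    width: 100 px for a 10,248-px well, 81 px for an 8,320-px well.  Rounds
    half away from zero so those printed values are reproduced exactly.
    """
    if well_width_px < 1:
        raise ValueError("well width must be >= 1")
    if fraction <= 0:
        raise ValueError("fraction must be positive")
    side = math.floor(fraction * well_width_px + 0.5)
    if side < 1:
        raise ValueError(
            f"box side rounds to {side} px for width {well_width_px}; "
            "box degenerates"
        )
    return side


def _clip_box_to_segment(
    cx: float, cy: float, side: float, size: int, mark: PointMark
) -> Optional[GTBox]:
    x0 = max(0.0, cx - side / 2.0)
    x1 = min(float(size), cx + side / 2.0)
    y0 = max(0.0, cy - side / 2.0)
    y1 = min(float(size), cy + side / 2.0)
    if x1 - x0 <= 0 or y1 - y0 <= 0:
        return None
    return GTBox(
        cx=(x0 + x1) / 2.0,
        cy=(y0 + y1) / 2.0,
        w=x1 - x0,
        h=y1 - y0,
        frame="segment",
        source_mark=mark,
    )


def assign_labels(
    marks: list[PointMark],
    grid: SegmentGrid,
    box_side_px: int,
) -> dict[tuple[int, int], list[GTBox]]:
    """Synthesize per-segment ground-truth boxes from point marks.

    Each mark generates one box, centered on the mark with side
    ``box_side_px``, in *every* segment whose window contains the mark (up to
    4 at 50% overlap), clipped to the segment.  Boxes extending past a
    segment perimeter are reduced to fit; clipped boxes are kept regardless
    of remaining area.  Returns a map keyed by (row, col) covering every
    segment of the grid (empty lists where no mark falls).
    """
    labels: dict[tuple[int, int], list[GTBox]] = {
        (r, c): [] for r in range(grid.n_rows) for c in range(grid.n_cols)
    }
    for mark in marks:
        if not (0 <= mark.x < grid.width_px and 0 <= mark.y < grid.height_px):
            raise ValueError(
                f"mark ({mark.x}, {mark.y}) lies outside the "
                f"{grid.width_px} x {grid.height_px} well"
            )
        refs = grid.refs_containing(mark.x, mark.y)
        for ref in refs:
            lx, ly = to_local(ref, mark.x, mark.y)
            box = _clip_box_to_segment(lx, ly, float(box_side_px), grid.segment_size_px, mark)
            if box is not None:
                labels[ref.key].append(box)
    return labels


def load_well_image(path: str | Path, well_id: str | None = None,
                    experiment_id: str = "") -> WellImage:
    """Read a TIF or PNG well raster from disk."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        pixels = tifffile.imread(path)
    else:
        pixels = np.asarray(Image.open(path))
    return WellImage(pixels, well_id=well_id or path.stem, experiment_id=experiment_id)


def save_segments(well: WellImage, grid: SegmentGrid, out_dir: str | Path,
                  pad_value: int = 0) -> list[Path]:
    """Write every segment as ``{well_id}_r{row}_c{col}.png``; returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for ref in grid.refs():
        raster = extract_segment(well, ref, pad_value=pad_value)
        p = out_dir / f"{well.well_id}_r{ref.row}_c{ref.col}.png"
        Image.fromarray(raster).save(p)
        paths.append(p)
    return paths
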