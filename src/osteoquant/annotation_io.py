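"""Readers and writers for every annotation and detection format in the pipeline.

Formats:

* Fiji multi-point CSV — one (x, y) pixel coordinate per counted cell,
  comma-separated, optional header row, extra columns ignored.
* Darknet label files — one text file per segment, each line
  ``0 cx cy w h`` with all four values normalized by the segment size and
  printed to 6 decimals (the ecosystem's de-facto convention).
* PASCAL VOC XML (LabelImg output) — corner boxes; corners are interpreted
  as 1-based pixel-boundary coordinates, so a (xmin=1, xmax=101) object is
  100 px wide with its center at x = 50.0 in the 0-based frame.
* JSON-lines detection records — the import path for externally produced
  detector output (segment id + box + confidence).

Every writer/reader pair is a lossless round trip at the stated precision.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterable, Optional
import xml.etree.ElementTree as ET

from .tiles import GTBox, PointMark

__all__ = [
    "DetectionRecord",
    "read_fiji_marks",
    "write_fiji_marks",
    "write_darknet_labels",
    "write_darknet_label_file",
    "read_darknet_labels",
    "read_voc_xml",
    "read_detections",
    "write_detections",
    "sort_detections",
]


@dataclass(frozen=True)
class DetectionRecord:
    """A scored box, in segment frame (with its segment's row/col) or well frame."""

    cx: float
    cy: float
    w: float
    h: float
    confidence: float
    frame: str = "well"          # "well" or "segment"
    row: Optional[int] = None    # segment indices when frame == "segment"
    col: Optional[int] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError(f"confidence {self.confidence} outside [0, 1]")
        if self.w <= 0 or self.h <= 0:
            raise ValueError("detection box must have positive size")


def sort_detections(records: Iterable[DetectionRecord]) -> list[DetectionRecord]:
    """Deterministic ranking: confidence descending, ties by (cx, cy) ascending."""
    return sorted(records, key=lambda r: (-r.confidence, r.cx, r.cy))


# ---------------------------------------------------------------------------
# Fiji multi-point CSV


def read_fiji_marks(path: str | Path, annotator_id: str = "") -> list[PointMark]:
    """Parse a Fiji multi-point export into point marks.

    Rows are ``x,y`` in well-frame pixels; a single non-numeric header row is
    tolerated; extra columns are ignored.  An empty data section yields an
    empty list (a well may legitimately contain zero cells).
    """
    marks: list[PointMark] = []
    with open(path, newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh), start=1):
            row = [c.strip() for c in row if c.strip() != ""]
            if not row:
                continue
            try:
                x, y = float(row[0]), float(row[1])
            except (ValueError, IndexError):
                if lineno == 1:  # header
                    continue
                raise ValueError(
                    f"{path}: line {lineno} is not a numeric x,y row: {row!r}"
                ) from None
            marks.append(PointMark(x, y, annotator_id=annotator_id))
    return marks


def write_fiji_marks(marks: Iterable[PointMark], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["x", "y"])
        for m in marks:
            writer.writerow([repr(float(m.x)), repr(float(m.y))])


# ---------------------------------------------------------------------------
# Darknet labels


def _normalize_box(box: GTBox, segment_size_px: int) -> tuple[float, float, float, float]:
    vals = (
        box.cx / segment_size_px,
        box.cy / segment_size_px,
        box.w / segment_size_px,
        box.h / segment_size_px,
    )
    for v in vals:
        if not 0.0 <= v <= 1.0 + 1e-9:
            raise ValueError(
                f"box {box} normalizes outside [0, 1] for segment size "
                f"{segment_size_px}; clip it to the segment first"
            )
    return vals


def write_darknet_label_file(
    boxes: Iterable[GTBox], segment_size_px: int, path: str | Path
) -> None:
    """Write one segment's labels: each line ``0 cx_n cy_n w_n h_n`` (6 decimals).

    A segment with zero boxes gets an empty file.
    """
    lines = []
    for box in boxes:
        cx, cy, w, h = _normalize_box(box, segment_size_px)
        lines.append(f"0 {cx:.6f} {cy:.6f} {w:.6f} {h:.6f}")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def write_darknet_labels(
    labels: dict[tuple[int, int], list[GTBox]],
    segment_size_px: int,
    out_dir: str | Path,
    well_id: str = "well",
) -> list[Path]:
    """Write one label file per segment, named ``{well_id}_r{row}_c{col}.txt``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for (row, col), boxes in sorted(labels.items()):
        p = out_dir / f"{well_id}_r{row}_c{col}.txt"
        write_darknet_label_file(boxes, segment_size_px, p)
        paths.append(p)
    return paths


def read_darknet_labels(path: str | Path, segment_size_px: int) -> list[GTBox]:
    """Inverse of :func:`write_darknet_label_file` (exact to ~1e-6 x segment size)."""
    boxes: list[GTBox] = []
    text = Path(path).read_text()
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 5:
            raise ValueError(f"{path}: line {lineno} has {len(parts)} fields, expected 5")
        _, cx, cy, w, h = parts
        boxes.append(
            GTBox(
                cx=float(cx) * segment_size_px,
                cy=float(cy) * segment_size_px,
                w=float(w) * segment_size_px,
                h=float(h) * segment_size_px,
                frame="segment",
            )
        )
    return boxes


# ---------------------------------------------------------------------------
# PASCAL VOC XML (LabelImg)


def read_voc_xml(path: str | Path) -> list[GTBox]:
    """Read LabelImg-style VOC boxes as center/size in the 0-based pixel frame.

    Corner convention: xmin/ymin/xmax/ymax are 1-based boundary coordinates,
    so width = xmax - xmin and the 0-based center is (xmin + xmax)/2 - 1.
    """
    root = ET.parse(path).getroot()
    boxes: list[GTBox] = []
    for obj in root.iter("object"):
        bb = obj.find("bndbox")
        if bb is None:
            raise ValueError(f"{path}: object without bndbox")
        xmin = float(bb.findtext("xmin"))
        ymin = float(bb.findtext("ymin"))
        xmax = float(bb.findtext("xmax"))
        ymax = float(bb.findtext("ymax"))
        if xmax <= xmin or ymax <= ymin:
            raise ValueError(
                f"{path}: degenerate box xmin={xmin} xmax={xmax} ymin={ymin} ymax={ymax}"
            )
        boxes.append(
            GTBox(
                cx=(xmin + xmax) / 2.0 - 1.0,
                cy=(ymin + ymax) / 2.0 - 1.0,
                w=xmax - xmin,
                h=ymax - ymin,
                frame="well",
            )
        )
    return boxes


# ---------------------------------------------------------------------------
# JSON-lines detections


def write_detections(records: Iterable[DetectionRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in records:
            d = asdict(r)
            if d["row"] is None:
                del d["row"]
            if d["col"] is None:
                del d["col"]
            fh.write(json.dumps(d) + "\n")


def read_detections(path: str | Path) -> list[DetectionRecord]:
    """Read JSON-lines detection records; lossless inverse of :func:`write_detections`."""
    records: list[DetectionRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                d = json.loads(line)
                records.append(DetectionRecord(**d))
            except (json.JSONDecodeError, TypeError, ValueError) as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from exc
    return records
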