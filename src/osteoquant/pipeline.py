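"""End-to-end orchestration: tile -> detect -> (merge) -> threshold -> count -> agree.

The pipeline defaults mirror the published operating point of the original
counting study: 416-px segments, 50% overlap for label generation, a
bounding-box side of 0.9756% of the well width, IoU 0.1 for matching, an F1
sweep in 0.05 steps, and *non-overlapping* segments for counting (overlap
counting plus ellipse merging deviated more from the annotators and is kept
behind a flag).  When no detection threshold is configured, it is chosen by
the F1 sweep on the first well, mirroring validation-set threshold tuning.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional

import pandas as pd

from . import agreement, evaluation
from .annotation_io import DetectionRecord
from .detection import DetectorParams, ReferenceDetector, run_well
from .merging import merge_detections
from .tiles import (
    GTBox,
    PointMark,
    WellImage,
    box_side_from_width,
    grid_dims,
)

__all__ = [
    "PipelineConfig",
    "QuantifyReport",
    "run_quantify",
    "truth_boxes_from_marks",
    "iterations_for_epochs",
    "epochs_for_iterations",
]


def iterations_for_epochs(n_segments: int, epochs: float, batch_size: int = 64) -> int:
    """Training iterations needed to cover ``epochs`` passes over the segments.

    One iteration consumes one batch; partial final batches still take an
    iteration, so the count rounds up: e.g. two epochs over 354,320 training
    segments at batch 64 is 11,073 iterations.
    """
    if n_segments < 1 or batch_size < 1 or epochs <= 0:
        raise ValueError("need positive segment count, batch size and epochs")
    import math

    return math.ceil(epochs * n_segments / batch_size)


def epochs_for_iterations(n_segments: int, iterations: int, batch_size: int = 64) -> float:
    """Fractional dataset passes performed by ``iterations`` batches."""
    if n_segments < 1 or batch_size < 1 or iterations < 0:
        raise ValueError("need positive segment count and batch size")
    return iterations * batch_size / n_segments


@dataclass(frozen=True)
class PipelineConfig:
    """Every tunable of the quantification pipeline, with published defaults."""

    segment_size_px: int = 416
    overlap_frac: float = 0.0          # counting mode; use 0.5 for label generation
    box_fraction: float = 0.009756
    iou_threshold: float = 0.1
    sweep_step: float = 0.05
    detection_threshold: Optional[float] = None  # None: choose by F1 sweep
    shrink_factor: float = 0.2
    detector_params: DetectorParams = field(default_factory=DetectorParams)
    seed: int = 0


@dataclass
class QuantifyReport:
    config: PipelineConfig
    detection_threshold: float
    mode: str
    count_pairs: list[agreement.WellCountPair]
    stats: Optional[agreement.AgreementStats]
    per_experiment_rmse: dict[str, float]

    def to_dict(self) -> dict:
        cfg = dataclasses.asdict(self.config)
        stats = None
        if self.stats is not None:
            stats = dataclasses.asdict(self.stats)
            stats["excluded_pairs"] = [
                {"well_id": p.well_id, "reason": reason}
                for p, reason in self.stats.excluded_pairs
            ]
        return {
            "config": cfg,
            "detection_threshold": self.detection_threshold,
            "mode": self.mode,
            "counts": [dataclasses.asdict(p) for p in self.count_pairs],
            "agreement": stats,
            "per_experiment_rmse": self.per_experiment_rmse,
        }


def truth_boxes_from_marks(
    marks: list[PointMark], well_width_px: int, box_fraction: float = 0.009756
) -> list[GTBox]:
    """Well-frame fixed-size ground-truth boxes centered on the marks."""
    side = float(box_side_from_width(well_width_px, box_fraction))
    return [GTBox(m.x, m.y, side, side, frame="well", source_mark=m) for m in marks]


def run_quantify(
    config: PipelineConfig,
    wells: list[WellImage],
    marks_by_well: dict[str, list[PointMark]],
    detector: Optional[Callable] = None,
    out_dir: Optional[str | Path] = None,
) -> QuantifyReport:
    """Quantify every well and compare automated with annotated counts.

    Writes (when ``out_dir`` is given) a per-well counts CSV, a metrics JSON
    with a full config echo, and a run log, so a run is reproducible from
    its report alone.
    """
    if not wells:
        raise ValueError("no wells supplied")
    detector = detector or ReferenceDetector(config.detector_params)
    mode = "overlap" if config.overlap_frac > 0 else "nonoverlap"
    log: list[str] = [f"config: {dataclasses.asdict(config)}"]

    threshold = config.detection_threshold
    if threshold is None:
        # tune on the first well, the pipeline's stand-in for a validation set
        w0 = wells[0]
        grid0 = grid_dims(w0.width_px, w0.height_px,
                          config.segment_size_px, config.overlap_frac)
        dets0 = run_well(w0, grid0, detector, 0.0).records
        gts0 = truth_boxes_from_marks(marks_by_well[w0.well_id],
                                      w0.width_px, config.box_fraction)
        if gts0:
            _, threshold = evaluation.sweep_thresholds(
                dets0, gts0, config.iou_threshold, config.sweep_step)
        else:
            threshold = 0.0
        log.append(f"detection threshold from F1 sweep on {w0.well_id!r}: {threshold}")
    detections_by_well: dict[str, list[DetectionRecord]] = {}
    well_dims: dict[str, tuple[int, int]] = {}
    experiment_by_well: dict[str, str] = {}
    for well in wells:
        if well.well_id not in marks_by_well:
            raise ValueError(f"no marks for well {well.well_id!r}")
        grid = grid_dims(well.width_px, well.height_px,
                         config.segment_size_px, config.overlap_frac)
        result = run_well(well, grid, detector, threshold)
        detections_by_well[well.well_id] = result.records
        well_dims[well.well_id] = (well.width_px, well.height_px)
        experiment_by_well[well.well_id] = well.experiment_id
        log.append(f"{well.well_id}: {len(result.records)} detections ({result.mode})")

    pairs = agreement.count_wells(
        detections_by_well,
        {w.well_id: marks_by_well[w.well_id] for w in wells},
        mode=mode,
        well_dims=well_dims,
        experiment_by_well=experiment_by_well,
        shrink_factor=config.shrink_factor,
    )
    stats = None
    usable = [p for p in pairs if p.count_a + p.count_b > 0]
    if len(usable) >= 3:
        try:
            stats = agreement.bland_altman(pairs)
        except ValueError as exc:
            log.append(f"agreement stats unavailable: {exc}")
    per_exp = {}
    if pairs:
        per_exp = agreement.per_experiment_rmse(pairs)

    report = QuantifyReport(
        config=config,
        detection_threshold=float(threshold),
        mode=mode,
        count_pairs=pairs,
        stats=stats,
        per_experiment_rmse=per_exp,
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        pd.DataFrame([dataclasses.asdict(p) for p in pairs]).to_csv(
            out / "counts.csv", index=False)
        (out / "metrics.json").write_text(json.dumps(report.to_dict(), indent=2))
        (out / "run.log").write_text("\n".join(log) + "\n")
    return report
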