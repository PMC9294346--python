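"""Seeded synthetic well images with known ground truth.

The generator emulates TRAP-stained brightfield well scans at the level the
pipeline logic cares about, not photorealistically: a light, mildly textured
background carrying dark elliptical multinucleated-cell-like bodies (each
with a handful of brighter nucleus dots), sub-cell-sized dark clutter specks
standing in for mononuclear debris, and an optional global dimming factor
reproducing the "dark experiment" imaging condition.  Cell width defaults to
1% of the well width, matching the fixed-fraction bounding-box rule used for
real annotations; per-well cell counts can be fixed or sampled over the
0–1,500 range observed across real experiments.

Every output is a pure function of the config seed: the same config renders
bit-identical images, marks and boxes.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
from PIL import Image

from .annotation_io import write_darknet_labels, write_fiji_marks
from .tiles import (
    GTBox,
    PointMark,
    WellImage,
    assign_labels,
    box_side_from_width,
    grid_dims,
)

__all__ = ["SynthConfig", "SynthWell", "generate_well", "generate_experiment"]

# body/nucleus colors as RGB multipliers of the background level
_BODY_TINT = np.array([0.75, 0.45, 0.70])   # purple TRAP-stained cytoplasm
_NUCLEUS_TINT = np.array([0.70, 0.70, 1.05])  # blue nuclear stain

#: count spec: an int, or ("uniform", lo, hi) / ("poisson", lam) sampled per well
CountSpec = Union[int, tuple]


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of one synthetic well rendering."""

    width_px: int = 2080
    height_px: int = 1664
    n_cells: CountSpec = 200
    cell_width_mean_px: Optional[float] = None  # default: 1% of width
    cell_width_cv: float = 0.18
    axis_ratio_range: tuple[float, float] = (0.6, 0.95)
    background_level: float = 0.85
    darkness_factor: float = 1.0
    clutter_density: float = 30.0  # specks per megapixel
    min_sep_factor: float = 0.6    # centroid separation, in cell widths
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width_px < 1 or self.height_px < 1:
            raise ValueError("well dimensions must be positive")
        if not 0.0 < self.background_level <= 1.0:
            raise ValueError("background_level must be in (0, 1]")
        if not 0.0 < self.darkness_factor <= 1.0:
            raise ValueError("darkness_factor must be in (0, 1]")

    @property
    def cell_width(self) -> float:
        return self.cell_width_mean_px if self.cell_width_mean_px is not None \
            else 0.01 * self.width_px


@dataclass
class SynthWell:
    """A rendered well plus its ground truth (marks at cell centroids)."""

    image: WellImage
    truth_marks: list[PointMark]
    truth_boxes: list[GTBox]
    config: SynthConfig


def _realize_count(spec: CountSpec, rng: np.random.Generator) -> int:
    if isinstance(spec, (int, np.integer)):
        return int(spec)
    kind = spec[0]
    if kind == "uniform":
        return int(rng.integers(spec[1], spec[2] + 1))
    if kind == "poisson":
        return int(rng.poisson(spec[1]))
    raise ValueError(f"unknown count spec {spec!r}")


def _place_centers(
    n: int, width: int, height: int, min_sep: float, margin: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Rejection-sample n centers >= min_sep apart, >= margin from the edges."""
    if n == 0:
        return np.empty((0, 2))
    lo_x, hi_x = margin, width - margin
    lo_y, hi_y = margin, height - margin
    if hi_x <= lo_x or hi_y <= lo_y:
        raise ValueError("well too small for the requested cell size")
    centers: list[np.ndarray] = []
    attempts, max_attempts = 0, max(2000, n * 300)
    sep2 = min_sep * min_sep
    while len(centers) < n:
        attempts += 1
        if attempts > max_attempts:
            raise ValueError(
                f"could not place {n} cells with separation {min_sep:.1f}px "
                f"in {width}x{height}; lower n_cells or min_sep_factor"
            )
        c = np.array([rng.uniform(lo_x, hi_x), rng.uniform(lo_y, hi_y)])
        if all(((c - p) ** 2).sum() >= sep2 for p in centers):
            centers.append(c)
    return np.array(centers)


def _paint_ellipse(img: np.ndarray, cx: float, cy: float, a: float, b: float,
                   theta: float, tint: np.ndarray, softness: float = 1.0) -> None:
    """Blend a tint over a rotated ellipse, with a soft edge."""
    height, width = img.shape[:2]
    r = max(a, b) + 2
    j0, j1 = max(0, int(cx - r)), min(width, int(cx + r) + 1)
    i0, i1 = max(0, int(cy - r)), min(height, int(cy + r) + 1)
    if j0 >= j1 or i0 >= i1:
        return
    jj = np.arange(j0, j1) + 0.5 - cx
    ii = np.arange(i0, i1) + 0.5 - cy
    x = jj[None, :]
    y = ii[:, None]
    ct, st = np.cos(theta), np.sin(theta)
    u = (x * ct + y * st) / a
    v = (-x * st + y * ct) / b
    d = u * u + v * v
    # soft alpha: 1 inside, fading over ~softness px at the rim
    alpha = np.clip((1.0 - d) * max(a, b) / softness, 0.0, 1.0)
    patch = img[i0:i1, j0:j1, :]
    patch *= 1.0 - alpha[..., None] * (1.0 - tint[None, None, :])


def generate_well(config: SynthConfig, well_id: str = "synth",
                  experiment_id: str = "") -> SynthWell:
    """Render one synthetic well; deterministic per config seed."""
    rng = np.random.default_rng(config.seed)
    w, h = config.width_px, config.height_px
    level = config.background_level * 255.0

    img = np.empty((h, w, 3), dtype=np.float64)
    img[:] = level
    img += rng.normal(0.0, 0.015 * 255.0, size=(h, w, 1))  # texture noise

    n = _realize_count(config.n_cells, rng)
    cw = config.cell_width
    margin = 1.1 * cw
    centers = _place_centers(n, w, h, config.min_sep_factor * cw, margin, rng)

    marks: list[PointMark] = []
    boxes: list[GTBox] = []
    for cx, cy in centers:
        width_i = float(np.clip(rng.normal(cw, config.cell_width_cv * cw),
                                0.5 * cw, 1.9 * cw))
        ratio = rng.uniform(*config.axis_ratio_range)
        theta = rng.uniform(0.0, np.pi)
        a, b = width_i / 2.0, width_i * ratio / 2.0
        _paint_ellipse(img, cx, cy, a, b, theta, _BODY_TINT, softness=1.5)
        # 3+ nuclei: the defining feature of an osteoclast
        for _ in range(int(rng.integers(3, 7))):
            r = rng.uniform(0.0, 0.55)
            phi = rng.uniform(0.0, 2 * np.pi)
            nx = cx + r * a * np.cos(phi) * np.cos(theta) - r * b * np.sin(phi) * np.sin(theta)
            ny = cy + r * a * np.cos(phi) * np.sin(theta) + r * b * np.sin(phi) * np.cos(theta)
            nr = rng.uniform(0.06, 0.11) * width_i
            _paint_ellipse(img, nx, ny, nr, nr, 0.0, _NUCLEUS_TINT, softness=0.8)
        # tight axis-aligned extent of the rotated ellipse
        ext_x = 2.0 * np.sqrt((a * np.cos(theta)) ** 2 + (b * np.sin(theta)) ** 2)
        ext_y = 2.0 * np.sqrt((a * np.sin(theta)) ** 2 + (b * np.cos(theta)) ** 2)
        marks.append(PointMark(float(cx), float(cy)))
        boxes.append(GTBox(float(cx), float(cy), ext_x, ext_y, frame="well"))

    n_clutter = int(round(config.clutter_density * w * h / 1e6))
    for _ in range(n_clutter):
        sx, sy = rng.uniform(0, w), rng.uniform(0, h)
        sr = rng.uniform(0.8, 2.0)
        _paint_ellipse(img, sx, sy, sr, sr, 0.0, _BODY_TINT, softness=0.8)

    img *= config.darkness_factor
    pixels = np.clip(img, 0.0, 255.0).astype(np.uint8)
    return SynthWell(
        image=WellImage(pixels, well_id=well_id, experiment_id=experiment_id),
        truth_marks=marks,
        truth_boxes=boxes,
        config=config,
    )


def generate_experiment(
    n_wells: int,
    config: SynthConfig,
    out_dir: Optional[str | Path] = None,
    experiment_id: str = "exp1",
    segment_size_px: int = 416,
    overlap_frac: float = 0.5,
) -> list[SynthWell]:
    """Generate a batch of wells; optionally write images + annotation files.

    Per-well counts follow the config's sampling spec; per-well seeds are
    derived deterministically from the config seed.  When ``out_dir`` is
    given, each well is written as a PNG plus a Fiji-style marks CSV and
    per-segment Darknet label files in the pipeline's standard dialects.
    """
    if n_wells < 1:
        raise ValueError("n_wells must be >= 1")
    child_seeds = np.random.SeedSequence(config.seed).generate_state(n_wells) % (2**31)
    wells: list[SynthWell] = []
    for i in range(n_wells):
        well_id = f"{experiment_id}_well{i:02d}"
        cfg_i = replace(config, seed=int(child_seeds[i]))
        sw = generate_well(cfg_i, well_id=well_id, experiment_id=experiment_id)
        wells.append(sw)
        if out_dir is not None:
            out = Path(out_dir)
            out.mkdir(parents=True, exist_ok=True)
            Image.fromarray(sw.image.pixels).save(out / f"{well_id}.png")
            write_fiji_marks(sw.truth_marks, out / f"{well_id}_marks.csv")
            grid = grid_dims(cfg_i.width_px, cfg_i.height_px, segment_size_px, overlap_frac)
            side = box_side_from_width(cfg_i.width_px)
            labels = assign_labels(sw.truth_marks, grid, side)
            write_darknet_labels(labels, segment_size_px, out / "labels", well_id=well_id)
    return wells
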