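# Methods

## Tiling model

A well image is an 8-bit raster with 0-based pixel coordinates, origin
top-left. Segments of side `s` (default 416 px) are placed at origins
`(col·t, row·t)` with stride `t = s·(1 − overlap)`; the stride must be a
positive integer (416 at 50% overlap gives t = 208), and non-integral
strides are rejected rather than rounded. Columns and rows number
`ceil(width/t)` and `ceil(height/t)`, so windows overrunning the right or
bottom edge are kept and zero-padded on extraction rather than shifted
inward. This keeps the well↔segment coordinate map affine — a detection at
local (x, y) in segment (r, c) is at well (x + c·t, y + r·t) — at the cost
of partially padded edge segments. Window membership is half-open
`[origin, origin + s)` in both axes, so a point on a shared boundary belongs
to the later segment only.

Ground-truth boxes are squares of side `round_half_away(0.009756·width)`
centered on each click mark, replicated into every segment whose window
contains the mark (up to 4 at 50% overlap) and clipped to the segment.
Clipped boxes are kept whatever their remaining area; partial-cell labels at
segment borders are a known, accepted error source of the tiling approach.

## Detector contract

Detection is a pluggable callable per segment. The bundled reference
detector is deliberately classical and deterministic: luma conversion
(0.299, 0.587, 0.114), global threshold at `intensity_threshold` × 255
(default 0.7; stained cells are darker than the brightfield background, so
foreground = below threshold), 8-connected components, area filter
(defaults 50–5000 px), one tight box per surviving component. Confidence is
`area / max_area` capped at 1 (`area_scaled`, the default, monotone in
component size) or mean relative darkness (`contrast_scaled`). The area
bounds are absolute pixel counts: they assume cell bodies of roughly
100–600 px (cell width ≈ 20 px), and must be rescaled if cells are rendered
or imaged at a different pixel scale.

Detections below the operating threshold are discarded before counting;
detections whose center falls in the zero-padded margin of an edge segment
(outside the well raster) are dropped. The pad value for extraction is 0;
a padded region is far larger than `max_area_px` and is rejected by the
area filter, but a cell merging with the pad at an edge can be lost — an
edge effect shared with any fixed-window tiling.

## Ellipse-fusion deduplication

For overlap-mode counting, each detected box is shrunk by 20% in width and
height about its center, the inscribed ellipse is rasterized (a pixel is
set iff its center `(j+0.5, i+0.5)` satisfies the ellipse inequality; a
semi-axis below 0.5 px fills the single nearest pixel), and 8-connected
regions of the union mask become one output each, with the region's tight
bounding box. The output boxes are *not* re-inflated by 1/0.8: they exist
for counting, not display. Shrinking separates compact neighbouring cells
whose full boxes touch; two 100-px boxes fuse when their centers are 79 px
apart and stay separate at 81 px (the shrunk semi-axes are 40 px, and the
pixel-center rule leaves a one-column gap at 81).

Re-merging the output of a merge is a no-op when fused regions are
near-elliptical — the case the algorithm is designed for, duplicate
detections of the same cell from overlapping tiles. It is not idempotent
for arbitrary chains of elongated overlapping boxes: the tight box of an
irregular fused region can inscribe an ellipse that spills beyond the
region and bridges to a neighbour. The counting pipeline never feeds merge
output back through the merger.

## Evaluation

Matching is the VOC protocol: detections in confidence-descending order
(ties broken by lower cx, then cy, for determinism), each assigned to its
highest-IoU not-yet-matched ground-truth box and flagged TP if that IoU
reaches the threshold, else FP — so duplicate detections of one cell are
FPs. The default IoU threshold is 0.1, permissive because synthesized boxes
are only loosely centered on click marks; 0.5 is available and can only
demote TPs (asserted as a property). AP is computed exactly: precision and
recall at every rank, envelope `p̃(r) = max_{r'≥r} p(r')` via a reverse
running maximum, AP = Σ Δrecall · p̃. With one class, mAP = AP. The
threshold sweep evaluates P/R/F1 at 0, 0.05, …, 1.0 (both endpoints),
keeping detections with confidence ≥ threshold; precision with no
detections and F1 with P + R = 0 are defined as 0; the best threshold is
the F1 argmax with ties to the lower threshold.

## Count agreement

Differences between paired per-well counts are expressed as a percentage of
the pair mean. Bias is their arithmetic mean, limits of agreement
bias ± 1.96·SD (sample SD, ddof 1). Confidence intervals use the
t-quantile forms: bias ± t(0.975, n−1)·SD/√n, and each LoA ±
t(0.975, n−1)·√(3·SD²/n). Normality of the differences is the
D'Agostino–Pearson omnibus test, reported as NaN below n = 8 where the test
is undefined. A pair with both counts zero has an undefined difference and
is excluded with a reason; pairs beyond an explicit `exclusion_pct` bound
are likewise excluded and listed — exclusion is never silent and never
automatic. RMSE and Pearson r are computed on raw counts; Pearson requires
two pairs and non-degenerate variance.

The default counting mode is non-overlap: on validation data the
overlap+merge route deviated more from manual counts than direct counting
on non-overlapping segments, so overlap counting is kept behind a flag.

## Synthetic wells

The generator emulates what the pipeline logic branches on, not histology:
a light textured background (level 0.85 of dynamic range, 1.5% Gaussian
noise), elliptical cell bodies in a darker purple tint with 3–6 brighter
nucleus dots, axis ratio 0.6–0.95, random orientation; cell width is
Gaussian around 1% of the well width (CV 0.18, clipped to 0.5–1.9×);
sub-threshold-area clutter specks (30 per megapixel) stand in for
mononuclear debris; `darkness_factor` scales the whole frame (0.4
reproduces a dark imaging condition under which an unadapted intensity
threshold makes the background itself foreground and recall collapses).
Centroids are rejection-sampled at least 0.6 cell widths apart with a
1.1-cell-width edge margin; truth marks sit at the centroids and truth
boxes are the tight axis-aligned extents of the rotated ellipses. Every
output is a pure function of the config seed; batch generation derives
per-well seeds from a seed sequence.

Default test wells are 2,080 × 1,664 px (10 × 8 strides at 50% overlap) so
a full pipeline run takes seconds; the tiling arithmetic itself is pure and
is exercised at the full 10,248 × 9,122 scale. Per-well counts can be fixed
or sampled (uniform or Poisson) across the 0–1,500 range seen in real
experiments.

What passing synthetic tests does **not** show: robustness to stain
variability, touching/overlapping cell clusters (the generator enforces
separation by default), debris larger than the clutter scale, uneven
illumination, or the accuracy of any particular trained detector on real
images — the reference detector exists to exercise the pipeline, and real
detectors plug in through the same contract or the detection-import path.

## Numerical choices

- Box-side rounding is half-away-from-zero (99.98 → 100, 81.17 → 81).
- Darknet labels print 6 decimals; read-back is exact to 1e-6 of the
  segment size.
- VOC XML corners are read as 1-based boundary coordinates: width =
  xmax − xmin, center = (xmin + xmax)/2 − 1 in the 0-based frame.
- Detection ranking ties break by (confidence desc, cx, cy) everywhere, so
  matching and sweeps are deterministic.
- Connectivity is 8-connected in both the detector and the merger.

## Training bookkeeping

Iteration/epoch conversion for batch training is provided as arithmetic
only (`iterations_for_epochs`, `epochs_for_iterations`): iterations =
`ceil(epochs · n_segments / batch)`; e.g. two epochs over 354,320 segments
at batch 64 is 11,073 iterations. No training loop is included — network
training and inference are out of scope, detectors are external.
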