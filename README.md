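# osteoquant

Automated quantification of osteoclasts (OCs) in whole-well microscopy
images. Osteoclasts are multinucleated, TRAP-positive bone-resorbing cells;
counting them in cultured wells is usually done by trained annotators
clicking each cell in a ~10,000-px-per-side brightfield scan — slow and
operator-biased. `osteoquant` implements the full automated counting
pipeline around a pluggable object detector:

1. **Tiling** — decompose a well image into 416 × 416-px segments on a
   stride lattice, `stride = 416 × (1 − overlap)`; with 50% overlap a
   10,248 × 9,122 well yields `ceil(10248/208) × ceil(9122/208)` = 50 × 44 =
   2,200 segments, so every cell is seen whole at least once.
2. **Label synthesis** — human annotations are point clicks, one per cell.
   Each mark becomes a square box of side `round(0.009756 × well_width)`
   (100 px for a 10,248-px well, 81 px for 8,320), clipped at segment
   borders, written as Darknet-format label files.
3. **Detection** — any callable `detector(segment) -> detections` runs over
   all segments; a deterministic classical reference detector
   (luma threshold → 8-connected components → area filter) is bundled, and
   externally produced detections can be imported from JSON-lines.
4. **Deduplication** — with overlapping tiles one cell is detected up to
   four times. Each box is shrunk 20% in width and height, the inscribed
   ellipses are rasterized, connected ellipses are fused, and one box per
   fused region is kept.
5. **Evaluation** — detections are matched to ground truth greedily by
   confidence at IoU ≥ 0.1 (duplicates of a matched box count as false
   positives); AP is the exact area under the monotone precision-recall
   envelope (PASCAL VOC2010); the operating threshold is chosen by an F1
   sweep in 0.05 steps.
6. **Agreement** — automated vs. manual per-well counts are compared by
   RMSE, Pearson r, and Bland–Altman analysis on percentage-of-mean
   differences d = (a − b)/((a+b)/2)·100: bias = mean(d), limits of
   agreement = bias ± 1.96 SD, with t-based confidence intervals
   (bias ± t·SD/√n; LoA ± t·√(3 SD²/n)) and a D'Agostino–Pearson normality
   check.

A seeded synthetic-well generator renders elliptical multinucleated-cell
bodies with known ground truth, so the whole pipeline is testable end to end
without real images, a GPU, or downloads.

## Worked example

Generate four synthetic wells and quantify them with the reference detector
on non-overlapping segments (the default counting mode):

```bash
osteoquant simulate --out data --n-wells 4 --seed 7 --counts 30,120
osteoquant quantify --images data --out run --overlap 0.0 --seed 7
```

which prints (abridged):

```json
{
  "detection_threshold": 0.0,
  "mode": "nonoverlap",
  "counts": [
    {"well_id": "exp1_well00", "count_a": 48, "count_b": 47},
    {"well_id": "exp1_well01", "count_a": 47, "count_b": 46},
    {"well_id": "exp1_well02", "count_a": 80, "count_b": 80},
    {"well_id": "exp1_well03", "count_a": 69, "count_b": 68}
  ],
  "agreement": {
    "n_pairs": 4, "rmse": 0.866, "pearson_r": 1.0,
    "bias_pct": 1.429, "loa_low_pct": -0.538, "loa_high_pct": 3.396
  }
}
```

`count_a` is the automated count, `count_b` the number of ground-truth
marks. Here the detector finds each well's cells almost exactly (RMSE
0.87 cells, r = 1.00) with a +1.4% mean bias — the automated pipeline
slightly overcounts, chiefly when a cell straddling a segment border is
detected in both halves. `run/` holds `counts.csv`, `metrics.json` (with a
full config echo for reproducibility) and `run.log`.

Other subcommands expose the individual stages: `tile`, `labels`, `detect`,
`merge`, `evaluate`, `count`, `agree` (`osteoquant --help`).

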