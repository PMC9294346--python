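"""Per-well count agreement: RMSE, Pearson correlation, Bland–Altman.

Automated and manual per-well osteoclast counts are compared as paired
measurements.  Differences are expressed as a percentage of the pair mean,
d = (a - b) / ((a + b)/2) * 100, which keeps wells with very different cell
loads comparable.  The Bland–Altman bias is the mean of those differences
and the limits of agreement (LoA) are bias ± 1.96 SD; under normality they
bracket ~95% of the differences.  Confidence intervals follow Giavarina's
formulation: bias ± t(0.975, n-1)·SD/√n for the bias and
LoA ± t(0.975, n-1)·√(3·SD²/n) for each limit.  Normality of the
differences is checked with the D'Agostino–Pearson omnibus test.

Pairs with an undefined difference (both counts zero) or with |d| beyond an
explicit exclusion bound are excluded and reported, never silently dropped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
from scipy import stats

from .annotation_io import DetectionRecord
from .merging import merge_detections
from .tiles import PointMark

__all__ = [
    "WellCountPair",
    "AgreementStats",
    "pct_diff",
    "rmse",
    "pearson",
    "bland_altman",
    "count_wells",
    "per_experiment_rmse",
    "bland_altman_plot",
]

Z_95 = 1.96


@dataclass(frozen=True)
class WellCountPair:
    """Paired per-well counts, e.g. model (a) vs annotator (b)."""

    well_id: str
    count_a: int
    count_b: int
    experiment_id: str = ""

    def __post_init__(self) -> None:
        if self.count_a < 0 or self.count_b < 0:
            raise ValueError("counts must be non-negative")


@dataclass
class AgreementStats:
    n_pairs: int
    rmse: float
    pearson_r: float
    bias_pct: float
    sd_pct: float
    loa_low_pct: float
    loa_high_pct: float
    ci_bias: tuple[float, float]
    ci_loa_low: tuple[float, float]
    ci_loa_high: tuple[float, float]
    normality_p: float
    excluded_pairs: list[tuple[WellCountPair, str]] = field(default_factory=list)


def pct_diff(count_a: int, count_b: int) -> tuple[float, float]:
    """Pair mean and difference as a percentage of that mean.

    (5 detected, 1 annotated) -> mean 3.0, difference +133.3%.
    """
    mean = (count_a + count_b) / 2.0
    if mean <= 0:
        raise ValueError("percentage difference undefined when both counts are zero")
    return mean, (count_a - count_b) / mean * 100.0


def rmse(pairs: Iterable[WellCountPair]) -> float:
    """Root-mean-squared error between the raw paired counts."""
    diffs = np.array([p.count_a - p.count_b for p in pairs], dtype=float)
    if diffs.size == 0:
        raise ValueError("rmse needs at least one pair")
    return float(np.sqrt(np.mean(diffs**2)))


def pearson(pairs: Iterable[WellCountPair]) -> float:
    """Pearson correlation between the raw paired counts."""
    pairs = list(pairs)
    if len(pairs) < 2:
        raise ValueError("pearson needs at least two pairs")
    a = np.array([p.count_a for p in pairs], dtype=float)
    b = np.array([p.count_b for p in pairs], dtype=float)
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("pearson undefined for a zero-variance count series")
    return float(stats.pearsonr(a, b).statistic)


def bland_altman(
    pairs: Iterable[WellCountPair],
    exclusion_pct: Optional[float] = None,
) -> AgreementStats:
    """Bland–Altman agreement analysis on percentage-of-mean differences.

    ``exclusion_pct`` excludes pairs whose |difference| exceeds the bound
    (e.g. 100 to drop a (5, 1) outlier at 133.3%); exclusions are listed in
    the result.  Requires >= 3 usable pairs.  The normality p-value is NaN
    when fewer than 8 differences are available (the omnibus test is
    undefined below that).
    """
    pairs = list(pairs)
    usable: list[WellCountPair] = []
    diffs: list[float] = []
    excluded: list[tuple[WellCountPair, str]] = []
    for p in pairs:
        if p.count_a + p.count_b == 0:
            excluded.append((p, "undefined difference (both counts zero)"))
            continue
        _, d = pct_diff(p.count_a, p.count_b)
        if exclusion_pct is not None and abs(d) > exclusion_pct:
            excluded.append((p, f"|difference| {abs(d):.1f}% exceeds bound {exclusion_pct:g}%"))
            continue
        usable.append(p)
        diffs.append(d)
    n = len(usable)
    if n < 3:
        raise ValueError(f"bland_altman needs >= 3 usable pairs, got {n}")
    d = np.asarray(diffs)
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    loa_low = bias - Z_95 * sd
    loa_high = bias + Z_95 * sd
    t = float(stats.t.ppf(0.975, n - 1))
    half_bias = t * sd / math.sqrt(n)
    half_loa = t * math.sqrt(3.0 * sd * sd / n)
    normality_p = float(stats.normaltest(d).pvalue) if n >= 8 else float("nan")
    return AgreementStats(
        n_pairs=n,
        rmse=rmse(usable),
        pearson_r=pearson(usable) if n >= 2 else float("nan"),
        bias_pct=bias,
        sd_pct=sd,
        loa_low_pct=loa_low,
        loa_high_pct=loa_high,
        ci_bias=(bias - half_bias, bias + half_bias),
        ci_loa_low=(loa_low - half_loa, loa_low + half_loa),
        ci_loa_high=(loa_high - half_loa, loa_high + half_loa),
        normality_p=normality_p,
        excluded_pairs=excluded,
    )


def count_wells(
    detections_by_well: dict[str, list[DetectionRecord]],
    marks_by_well: dict[str, list[PointMark]],
    mode: str,
    well_dims: Optional[dict[str, tuple[int, int]]] = None,
    experiment_by_well: Optional[dict[str, str]] = None,
    shrink_factor: float = 0.2,
) -> list[WellCountPair]:
    """Pair automated counts against annotator mark counts, well by well.

    In ``nonoverlap`` mode the automated count is the number of (already
    threshold-filtered) detections; in ``overlap`` mode detections are first
    fused through the ellipse merger (``well_dims`` maps well_id ->
    (width, height) and is required).  Every well id present in either input
    must be present in both.
    """
    if mode not in ("overlap", "nonoverlap"):
        raise ValueError(f"unknown counting mode {mode!r}")
    det_ids = set(detections_by_well)
    mark_ids = set(marks_by_well)
    if det_ids != mark_ids:
        missing = det_ids.symmetric_difference(mark_ids)
        raise ValueError(f"unmatched well ids between detections and marks: {sorted(missing)}")
    out: list[WellCountPair] = []
    for well_id in sorted(det_ids):
        records = detections_by_well[well_id]
        if mode == "overlap":
            if well_dims is None or well_id not in well_dims:
                raise ValueError("overlap mode needs well_dims for every well")
            w, h = well_dims[well_id]
            n_auto = len(merge_detections(records, w, h, shrink_factor))
        else:
            n_auto = len(records)
        out.append(
            WellCountPair(
                well_id=well_id,
                count_a=n_auto,
                count_b=len(marks_by_well[well_id]),
                experiment_id=(experiment_by_well or {}).get(well_id, ""),
            )
        )
    return out


def per_experiment_rmse(pairs: Iterable[WellCountPair]) -> dict[str, float]:
    """RMSE computed separately for each experiment id."""
    groups: dict[str, list[WellCountPair]] = {}
    for p in pairs:
        groups.setdefault(p.experiment_id, []).append(p)
    return {exp: rmse(ps) for exp, ps in sorted(groups.items())}


def bland_altman_plot(stats_: AgreementStats, pairs: Iterable[WellCountPair], path) -> None:
    """Write a Bland–Altman scatter with bias, LoA lines and CI bands."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    means, diffs = [], []
    for p in pairs:
        if p.count_a + p.count_b == 0:
            continue
        m, d = pct_diff(p.count_a, p.count_b)
        means.append(m)
        diffs.append(d)
    fig, ax = plt.subplots(figsize=(6, 4.5))
    ax.scatter(means, diffs, s=18, color="tab:blue", zorder=3)
    for y, style, label in [
        (stats_.bias_pct, dict(color="k", ls="--"), f"bias {stats_.bias_pct:.1f}%"),
        (stats_.loa_low_pct, dict(color="r", ls="--"), f"LoA {stats_.loa_low_pct:.1f}%"),
        (stats_.loa_high_pct, dict(color="r", ls="--"), f"LoA {stats_.loa_high_pct:.1f}%"),
    ]:
        ax.axhline(y, **style, lw=1)
    for lo, hi in (stats_.ci_bias, stats_.ci_loa_low, stats_.ci_loa_high):
        ax.axhspan(lo, hi, color="grey", alpha=0.25, zorder=1)
    ax.set_xlabel("mean of paired counts")
    ax.set_ylabel("difference (% of mean)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
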