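"""Threshold optimization and spatial-overlap statistics for CVR maps.

A voxel is called responsive when its metric value is >= the threshold
(one-sided: vasodilatory responses are modeled as positive).  Agreement
between a thresholded map and a reference labeling is summarized by a 2x2
contingency table and its accuracy (TP+TN)/(TP+TN+FP+FN) and Dice
2TP/(2TP+FP+FN).

Three analyses build on this: a 1D threshold sweep against the gray-matter
reference within the GWM-VOI, a 2D cross-metric accuracy surface within
cortical gray matter (resting-state as predictor of breath-hold), and
split-run self-concordance.  Moving both thresholds toward their extremes
forces all voxels into a single cell, biasing accuracy to exactly 1 or 0
at the surface corners.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .containers import CvrMap, TissueLabelVolume

__all__ = [
    "ContingencyTable",
    "SweepResult1D",
    "AccuracySurface",
    "ConcordanceResult",
    "UnthresholdedComparison",
    "accuracy",
    "dice",
    "classify_vs_mask",
    "percentile_grid",
    "sweep_thresholds",
    "sweep_vs_gray",
    "cross_metric_surface",
    "self_concordance",
    "unthresholded_compare",
]


@dataclass(frozen=True)
class ContingencyTable:
    """TP/TN/FP/FN cell counts (or percentages) for one threshold (pair)."""

    tp: float
    tn: float
    fp: float
    fn: float

    @property
    def total(self) -> float:
        return self.tp + self.tn + self.fp + self.fn

    @property
    def accuracy(self) -> float:
        if self.total == 0:
            raise ValueError("accuracy undefined for an empty table")
        return (self.tp + self.tn) / self.total

    @property
    def dice(self) -> float:
        denom = 2.0 * self.tp + self.fp + self.fn
        if denom == 0:
            raise ValueError("Dice undefined: no positives in either labeling")
        return 2.0 * self.tp / denom

    def as_percent(self) -> "ContingencyTable":
        """The four cells expressed as percentages of the total."""
        if self.total == 0:
            raise ValueError("cannot express an empty table as percentages")
        f = 100.0 / self.total
        return ContingencyTable(self.tp * f, self.tn * f, self.fp * f, self.fn * f)


def accuracy(table: ContingencyTable) -> float:
    """Overall agreement rate (TP+TN)/(TP+TN+FP+FN)."""
    return table.accuracy


def dice(table: ContingencyTable) -> float:
    """Overlap coefficient 2TP/(2TP+FP+FN)."""
    return table.dice


def _metric_values(metric) -> np.ndarray:
    return metric.values if isinstance(metric, CvrMap) else np.asarray(metric, dtype=float)


def classify_vs_mask(
    metric,
    threshold: float,
    reference: np.ndarray,
    voi: np.ndarray,
) -> ContingencyTable:
    """Cross-classify thresholded metric vs a binary reference within a VOI.

    TP = responsive AND reference, TN = neither, FP = responsive only,
    FN = reference only; counts are restricted to ``voi``.
    """
    voi = np.asarray(voi, dtype=bool)
    if not voi.any():
        raise ValueError("empty VOI")
    vals = _metric_values(metric)[voi]
    ref = np.asarray(reference, dtype=bool)[voi]
    pred = vals >= threshold
    tp = int(np.count_nonzero(pred & ref))
    fp = int(np.count_nonzero(pred & ~ref))
    fn = int(np.count_nonzero(~pred & ref))
    tn = int(np.count_nonzero(~pred & ~ref))
    return ContingencyTable(tp, tn, fp, fn)


def percentile_grid(values: np.ndarray, n: int = 101) -> np.ndarray:
    """Strictly increasing threshold grid at the 0th..100th percentiles."""
    vals = np.asarray(values, dtype=float)
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("no finite values to build a grid from")
    grid = np.unique(np.percentile(vals, np.linspace(0.0, 100.0, n)))
    if grid.size < 2:
        raise ValueError("metric is constant; threshold grid degenerate")
    return grid


@dataclass
class SweepResult1D:
    """Accuracy/Dice along an ordered threshold grid, with the accuracy argmax."""

    thresholds: np.ndarray
    accuracy: np.ndarray
    dice: np.ndarray
    tables: list[ContingencyTable]
    argmax_threshold: float
    max_accuracy: float

    @property
    def argmax_index(self) -> int:
        return int(np.argmax(self.accuracy))


def sweep_thresholds(
    metric,
    reference: np.ndarray,
    voi: np.ndarray,
    grid: np.ndarray | None = None,
) -> SweepResult1D:
    """Classify against ``reference`` at every threshold of the grid.

    Ties in accuracy resolve toward the smallest (most inclusive)
    threshold.  The default grid spans the 0th-100th percentiles of the
    metric within the VOI in 101 steps.
    """
    voi = np.asarray(voi, dtype=bool)
    vals = _metric_values(metric)
    if grid is None:
        grid = percentile_grid(vals[voi])
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0 or np.any(np.diff(grid) <= 0):
        raise ValueError("threshold grid must be non-empty and strictly increasing")
    tables = [classify_vs_mask(vals, th, reference, voi) for th in grid]
    acc = np.array([t.accuracy for t in tables])
    dce = np.array(
        [t.dice if (2 * t.tp + t.fp + t.fn) > 0 else np.nan for t in tables]
    )
    i = int(np.argmax(acc))  # first max = smallest threshold
    return SweepResult1D(grid, acc, dce, tables, float(grid[i]), float(acc[i]))


def sweep_vs_gray(
    metric: CvrMap,
    tissue: TissueLabelVolume,
    grid: np.ndarray | None = None,
) -> SweepResult1D:
    """1D threshold sweep of a CVR map against gray matter in the GWM-VOI."""
    if not tissue.gray_mask.any() or not tissue.white_mask.any():
        raise ValueError("tissue volume must contain both gray and white matter")
    voi = tissue.gwm_mask & metric.voi_mask
    return sweep_thresholds(metric, tissue.gray_mask, voi, grid)


@dataclass
class AccuracySurface:
    """Cross-metric accuracy/Dice over a 2D grid of threshold pairs.

    Matrices are indexed ``[i_bh, j_rs]``.  ``corners`` holds the four
    forced-classification accuracies: A1 (both thresholds above all
    values, all TN), A2 (resting below / breath-hold above, all FP), A3
    (resting above / breath-hold below, all FN), A4 (both below, all TP).
    ``saddle_accuracy`` is the accuracy at the pair of independently
    optimized 1D thresholds, when supplied.
    """

    bh_thresholds: np.ndarray
    rs_thresholds: np.ndarray
    accuracy: np.ndarray
    dice: np.ndarray
    corners: dict[str, float]
    saddle_thresholds: tuple[float, float] | None = None
    saddle_accuracy: float | None = None
    saddle_table: ContingencyTable | None = None


def _cross_classify(
    rs_vals: np.ndarray, bh_vals: np.ndarray, rs_thr: float, bh_thr: float
) -> ContingencyTable:
    rs_pos = rs_vals >= rs_thr
    bh_pos = bh_vals >= bh_thr
    tp = int(np.count_nonzero(rs_pos & bh_pos))
    fp = int(np.count_nonzero(rs_pos & ~bh_pos))
    fn = int(np.count_nonzero(~rs_pos & bh_pos))
    tn = int(np.count_nonzero(~rs_pos & ~bh_pos))
    return ContingencyTable(tp, tn, fp, fn)


def cross_metric_surface(
    bh: CvrMap,
    rs: CvrMap,
    gm_voi: np.ndarray,
    bh_grid: np.ndarray | None = None,
    rs_grid: np.ndarray | None = None,
    saddle_thresholds: tuple[float, float] | None = None,
) -> AccuracySurface:
    """Accuracy/Dice of resting-state as predictor of breath-hold, per pair.

    For each (breath-hold, resting) threshold pair, voxels within the
    gray-matter VOI are classified TP/TN/FP/FN with the resting metric as
    predictor and the breath-hold metric as reference.
    """
    gm_voi = np.asarray(gm_voi, dtype=bool)
    if not gm_voi.any():
        raise ValueError("empty gray-matter VOI")
    b = bh.values[gm_voi]
    r = rs.values[gm_voi]
    if bh_grid is None:
        bh_grid = percentile_grid(b)
    if rs_grid is None:
        rs_grid = percentile_grid(r)
    bh_grid = np.asarray(bh_grid, dtype=float)
    rs_grid = np.asarray(rs_grid, dtype=float)
    if bh_grid.size < 2 or rs_grid.size < 2:
        raise ValueError("degenerate threshold grid")
    n = b.size
    Bpos = (b[None, :] >= bh_grid[:, None]).astype(np.float64)  # (n_bh, n)
    Rpos = (r[None, :] >= rs_grid[:, None]).astype(np.float64)  # (n_rs, n)
    TP = Bpos @ Rpos.T  # [i_bh, j_rs]
    bh_tot = Bpos.sum(axis=1)
    rs_tot = Rpos.sum(axis=1)
    FN = bh_tot[:, None] - TP
    FP = rs_tot[None, :] - TP
    TN = n - TP - FN - FP
    acc = (TP + TN) / n
    denom = 2 * TP + FP + FN
    with np.errstate(invalid="ignore", divide="ignore"):
        dce = np.where(denom > 0, 2 * TP / denom, np.nan)
    corners = {
        "A1": _cross_classify(r, b, np.inf, np.inf).accuracy,
        "A2": _cross_classify(r, b, -np.inf, np.inf).accuracy,
        "A3": _cross_classify(r, b, np.inf, -np.inf).accuracy,
        "A4": _cross_classify(r, b, -np.inf, -np.inf).accuracy,
    }
    surface = AccuracySurface(bh_grid, rs_grid, acc, dce, corners)
    if saddle_thresholds is not None:
        bh_thr, rs_thr = saddle_thresholds
        table = _cross_classify(r, b, rs_thr, bh_thr)
        surface.saddle_thresholds = (float(bh_thr), float(rs_thr))
        surface.saddle_accuracy = table.accuracy
        surface.saddle_table = table
    return surface


@dataclass
class ConcordanceResult:
    """Split-run agreement of two maps of the same metric."""

    table: ContingencyTable
    threshold1: float
    threshold2: float

    @property
    def accuracy(self) -> float:
        return self.table.accuracy

    @property
    def dice(self) -> float:
        return self.table.dice


def self_concordance(
    map_run1: CvrMap,
    map_run2: CvrMap,
    tissue: TissueLabelVolume,
    voi: np.ndarray | None = None,
    grid: np.ndarray | None = None,
) -> ConcordanceResult:
    """Cross-classify two independent runs of the same metric.

    Each run's map is thresholded at its own 1D-optimal threshold (from
    the sweep against gray matter within the GWM-VOI), then run 1 is
    cross-classified against run 2 within ``voi`` (default: cortical gray
    matter where both maps are defined).
    """
    if map_run1.metric_kind != map_run2.metric_kind:
        raise ValueError("self-concordance requires maps of the same metric kind")
    thr1 = sweep_vs_gray(map_run1, tissue, grid).argmax_threshold
    thr2 = sweep_vs_gray(map_run2, tissue, grid).argmax_threshold
    if voi is None:
        voi = tissue.gray_mask & map_run1.voi_mask & map_run2.voi_mask
    voi = np.asarray(voi, dtype=bool)
    if not voi.any():
        raise ValueError("empty VOI")
    table = _cross_classify(
        map_run1.values[voi], map_run2.values[voi], thr1, thr2
    )
    return ConcordanceResult(table, thr1, thr2)


@dataclass
class UnthresholdedComparison:
    """Continuous comparison of the two normalized metrics over the GM-VOI."""

    pearson_r: float
    difference: np.ndarray  # 3D: normalized resting - normalized breath-hold
    bh_norm: np.ndarray  # normalized breath-hold values over the VOI (1D)
    rs_norm: np.ndarray
    scatter_mask: np.ndarray  # central-95% voxels for plotting (1D bool)


def _robust_normalize(x: np.ndarray, lo_pct: float = 1.0, hi_pct: float = 99.0) -> np.ndarray:
    lo, hi = np.percentile(x, [lo_pct, hi_pct])
    if hi <= lo:
        raise ValueError("metric is (nearly) constant; normalization undefined")
    return np.clip((x - lo) / (hi - lo), 0.0, 1.0)


def unthresholded_compare(
    bh: CvrMap, rs: CvrMap, gm_voi: np.ndarray
) -> UnthresholdedComparison:
    """Correlate and difference the unthresholded metrics within gray matter.

    Each metric is robustly normalized (1st-99th percentile mapped to
    [0, 1], clipped outside) over the VOI; the Pearson correlation is
    computed across voxels and the per-voxel difference map is normalized
    resting minus normalized breath-hold.  The scatter mask keeps the
    central 95% of voxels of both metrics for plotting.
    """
    gm_voi = np.asarray(gm_voi, dtype=bool)
    if not gm_voi.any():
        raise ValueError("empty VOI")
    b = bh.values[gm_voi]
    r = rs.values[gm_voi]
    bn = _robust_normalize(b)
    rn = _robust_normalize(r)
    if np.std(bn) == 0 or np.std(rn) == 0:
        raise ValueError("constant map; correlation undefined")
    pearson_r = float(stats.pearsonr(bn, rn).statistic)
    diff = np.full(gm_voi.shape, np.nan)
    diff[gm_voi] = rn - bn
    b_lo, b_hi = np.percentile(bn, [2.5, 97.5])
    r_lo, r_hi = np.percentile(rn, [2.5, 97.5])
    scatter = (bn >= b_lo) & (bn <= b_hi) & (rn >= r_lo) & (rn <= r_hi)
    return UnthresholdedComparison(pearson_r, diff, bn, rn, scatter)
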