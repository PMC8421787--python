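"""End-to-end driver: runs in, classification tables and surfaces out.

The pipeline executes the full comparison for one subject:

1. truncate and mean-100 scale all runs;
2. breath-hold metric — personal-waveform estimation and multi-lag beta
   map per run, then the two-run average;
3. resting metric — per-voxel ALFF, averaged over the two runs;
4. 1D threshold sweeps of each metric against gray matter (GWM-VOI);
5. the 2D cross-metric accuracy surface within cortical gray matter with
   its saddle value at the pair of 1D-optimal thresholds;
6. split-run self-concordance for both metrics and the unthresholded
   correlation/difference comparison.

Reports are a per-subject CSV of classification rows (TP/TN/FP/FN/Acc as
integer percent, Dice to one decimal) plus a full-precision JSON summary.
Everything is deterministic for a fixed input and configuration; the
configuration hash is recorded in every output.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import metrics, nifti_io, overlap, respiratory
from .containers import BoldRun, CvrMap, TissueLabelVolume
from .containers import map_from_voi as containers_map_from_voi
from .phantom import PhantomSubject, build_breathhold_timing

logger = logging.getLogger("cvrconcord")

__all__ = [
    "PipelineConfig",
    "RunManifest",
    "SubjectResult",
    "analyze_runs",
    "analyze_subject",
    "format_report",
    "aggregate_reports",
    "write_report",
    "run_pipeline",
]


@dataclass(frozen=True)
class PipelineConfig:
    """Every tunable of the analysis, with the defaults used throughout.

    ``average_mode`` selects whether the two breath-hold runs are combined
    by averaging their beta maps ("maps", default) or their time series
    before fitting ("timeseries").  ``rs_mode`` selects whether the
    resting metric uses the mean of both runs ("mean") or the first run
    only ("single").
    """

    pct_top: float = 0.01
    max_lag_tr: int = 4
    smoother_w_med: float = 0.70
    smoother_w_max: float = 0.15
    smoother_w_min: float = 0.15
    f_low: float = 0.01
    f_high: float = 0.08
    detrend: bool = True
    grid_n: int = 101
    average_mode: str = "maps"
    rs_mode: str = "mean"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    @property
    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]

    @property
    def smoother(self) -> respiratory.SmootherWeights:
        return respiratory.SmootherWeights(
            self.smoother_w_med, self.smoother_w_max, self.smoother_w_min
        )

    @property
    def alff_params(self) -> metrics.AlffParams:
        return metrics.AlffParams(self.f_low, self.f_high, self.detrend)


@dataclass
class RunManifest:
    """Paths and metadata locating one subject's inputs on disk."""

    subject_id: str
    bh_runs: list[Path]
    rs_runs: list[Path]
    tissue: Path
    tr: float = 2.0
    seed: int | None = None

    def validate(self) -> None:
        for p in [*self.bh_runs, *self.rs_runs, self.tissue]:
            if not Path(p).exists():
                raise FileNotFoundError(p)


@dataclass
class SubjectResult:
    """All derived objects for one subject."""

    subject_id: str
    config: PipelineConfig
    bh_map: CvrMap
    rs_map: CvrMap
    bh_run_maps: list[CvrMap]
    rs_run_maps: list[CvrMap]
    waveforms: list
    sweep_bh: overlap.SweepResult1D
    sweep_rs: overlap.SweepResult1D
    surface: overlap.AccuracySurface
    concord_bh: overlap.ConcordanceResult
    concord_rs: overlap.ConcordanceResult
    unthresholded: overlap.UnthresholdedComparison
    rows: pd.DataFrame  # full-precision classification rows


def _stage(name: str, t0: float, **counts) -> None:
    extra = " ".join(f"{k}={v}" for k, v in counts.items())
    logger.info("stage=%s elapsed=%.2fs %s", name, time.perf_counter() - t0, extra)


def _row(comparison: str, table: overlap.ContingencyTable) -> dict:
    pct = table.as_percent()
    return {
        "comparison": comparison,
        "tp_pct": pct.tp,
        "tn_pct": pct.tn,
        "fp_pct": pct.fp,
        "fn_pct": pct.fn,
        "acc_pct": 100.0 * table.accuracy,
        "dice_pct": 100.0 * table.dice,
    }


def analyze_runs(
    bh_runs: list[BoldRun],
    rs_runs: list[BoldRun],
    tissue: TissueLabelVolume,
    config: PipelineConfig = PipelineConfig(),
    subject_id: str = "subject",
) -> SubjectResult:
    """Run the full comparison for one subject given raw (untruncated) runs."""
    t0 = time.perf_counter()
    timing = build_breathhold_timing(bh_runs[0].tr)

    # --- preprocessing -------------------------------------------------
    bh_scaled: list[BoldRun] = []
    rs_scaled: list[BoldRun] = []
    invalid = np.zeros(tissue.labels.shape, dtype=bool)
    for run in bh_runs:
        trunc = metrics.truncate_breathhold(run)
        scaled, bad = metrics.scale_to_mean_100(trunc)
        bh_scaled.append(scaled)
        invalid |= bad
    for run in rs_runs:
        trunc = metrics.truncate_resting(run)
        scaled, bad = metrics.scale_to_mean_100(trunc)
        rs_scaled.append(scaled)
        invalid |= bad
    gwm = tissue.gwm_mask & ~invalid
    gm = tissue.gray_mask & ~invalid
    _stage("preprocess", t0, gwm_voxels=int(gwm.sum()))

    # --- breath-hold metric -------------------------------------------
    t0 = time.perf_counter()
    keep = metrics.breathhold_keep_slice(timing.n_volumes)
    regressor = respiratory.initial_regressor(timing)[keep]
    waveforms = []
    bh_run_maps: list[CvrMap] = []
    if config.average_mode == "timeseries":
        mean_data = np.mean([r.data for r in bh_scaled], axis=0)
        fit_runs = [BoldRun(mean_data, bh_scaled[0].tr)]
    elif config.average_mode == "maps":
        fit_runs = bh_scaled
    else:
        raise ValueError(f"unknown average_mode {config.average_mode!r}")
    fits = []
    for run in fit_runs:
        wf = respiratory.estimate_personal_waveform(
            run,
            regressor,
            gwm,
            pct=config.pct_top,
            max_lag_tr=config.max_lag_tr,
            weights=config.smoother,
        )
        waveforms.append(wf)
        betas, r2 = respiratory.lagged_beta_fits(run, wf, gwm, config.max_lag_tr)
        fits.append((betas, r2))
        best = np.argmax(r2, axis=1)
        bh_run_maps.append(
            containers_map_from_voi(
                betas[np.arange(betas.shape[0]), best],
                gwm,
                "breathhold_beta",
                lag_values=best,
            )
        )
    if len(fits) == 2:
        # two-run average: per-voxel lag from the pooled goodness of fit
        # across runs, beta = mean of the per-run betas at that lag
        r2_sum = fits[0][1] + fits[1][1]
        best = np.argmax(r2_sum, axis=1)
        idx = np.arange(best.size)
        beta = (fits[0][0][idx, best] + fits[1][0][idx, best]) / 2.0
        bh_map = containers_map_from_voi(
            beta, gwm, "breathhold_beta", lag_values=best
        )
    else:
        bh_map = bh_run_maps[0]
    _stage("breathhold_metric", t0, runs=len(bh_run_maps))

    # --- resting metric ------------------------------------------------
    t0 = time.perf_counter()
    rs_run_maps = [
        metrics.resting_cvre_map(r, gwm, config.alff_params) for r in rs_scaled
    ]
    if config.rs_mode == "single" or len(rs_scaled) == 1:
        rs_map = rs_run_maps[0]
    elif config.rs_mode == "mean":
        rs_map = metrics.resting_cvre_map(rs_scaled, gwm, config.alff_params)
    else:
        raise ValueError(f"unknown rs_mode {config.rs_mode!r}")
    _stage("resting_metric", t0, runs=len(rs_run_maps))

    # --- threshold optimization vs gray matter ------------------------
    t0 = time.perf_counter()
    grid_kw = None  # percentile grids are rebuilt per metric
    sweep_bh = overlap.sweep_vs_gray(bh_map, tissue)
    sweep_rs = overlap.sweep_vs_gray(rs_map, tissue)
    _stage(
        "sweep_vs_gray",
        t0,
        bh_opt=f"{sweep_bh.argmax_threshold:.4g}",
        rs_opt=f"{sweep_rs.argmax_threshold:.4g}",
    )

    # --- cross-metric surface and saddle ------------------------------
    t0 = time.perf_counter()
    surface = overlap.cross_metric_surface(
        bh_map,
        rs_map,
        gm,
        saddle_thresholds=(sweep_bh.argmax_threshold, sweep_rs.argmax_threshold),
    )
    _stage("cross_metric_surface", t0, gm_voxels=int(gm.sum()))

    # --- concordance and unthresholded comparison ---------------------
    t0 = time.perf_counter()
    if len(bh_run_maps) == 2:
        concord_bh = overlap.self_concordance(bh_run_maps[0], bh_run_maps[1], tissue)
    else:
        concord_bh = overlap.self_concordance(bh_map, bh_map, tissue)
    if len(rs_run_maps) == 2:
        concord_rs = overlap.self_concordance(rs_run_maps[0], rs_run_maps[1], tissue)
    else:
        concord_rs = overlap.self_concordance(rs_map, rs_map, tissue)
    unthr = overlap.unthresholded_compare(bh_map, rs_map, gm)
    _stage("concordance", t0)

    gray = tissue.gray_mask
    rows = pd.DataFrame(
        [
            _row(
                "RS-vs-GM",
                overlap.classify_vs_mask(
                    rs_map, sweep_rs.argmax_threshold, gray, gwm
                ),
            ),
            _row(
                "BH-vs-GM",
                overlap.classify_vs_mask(
                    bh_map, sweep_bh.argmax_threshold, gray, gwm
                ),
            ),
            _row("RS-vs-BH", surface.saddle_table),
        ]
    )
    return SubjectResult(
        subject_id=subject_id,
        config=config,
        bh_map=bh_map,
        rs_map=rs_map,
        bh_run_maps=bh_run_maps,
        rs_run_maps=rs_run_maps,
        waveforms=waveforms,
        sweep_bh=sweep_bh,
        sweep_rs=sweep_rs,
        surface=surface,
        concord_bh=concord_bh,
        concord_rs=concord_rs,
        unthresholded=unthr,
        rows=rows,
    )


def analyze_subject(
    subject: PhantomSubject,
    config: PipelineConfig = PipelineConfig(),
    subject_id: str | None = None,
) -> SubjectResult:
    """Convenience wrapper running the pipeline on an in-memory phantom."""
    sid = subject_id or f"phantom-seed{subject.spec.seed}"
    return analyze_runs(subject.bh_runs, subject.rs_runs, subject.tissue, config, sid)


def format_report(rows: pd.DataFrame) -> pd.DataFrame:
    """Render classification rows at reporting precision.

    TP/TN/FP/FN and accuracy are rounded to integer percent, Dice to one
    decimal, mirroring the conventional table layout.
    """
    out = rows.copy()
    for col in ("tp_pct", "tn_pct", "fp_pct", "fn_pct", "acc_pct"):
        out[col] = out[col].round(0).astype(int)
    out["dice_pct"] = out["dice_pct"].round(1)
    return out


def aggregate_reports(per_subject: pd.DataFrame) -> pd.DataFrame:
    """Append an "Ave ± SD" row (mean and sample SD of each percent column).

    ``per_subject`` must hold one row per subject for a single comparison,
    with a ``subject`` column and the six percent columns.
    """
    cols = ["tp_pct", "tn_pct", "fp_pct", "fn_pct", "acc_pct", "dice_pct"]
    out = per_subject.copy()
    summary = {"subject": "Ave ± SD"}
    for col in cols:
        mean = per_subject[col].mean()
        sd = per_subject[col].std(ddof=1)
        summary[col] = f"{mean:.1f} ± {sd:.1f}"
    return pd.concat([out, pd.DataFrame([summary])], ignore_index=True)


def _sweep_dict(sweep: overlap.SweepResult1D) -> dict:
    return {
        "thresholds": sweep.thresholds.tolist(),
        "accuracy": sweep.accuracy.tolist(),
        "dice": np.where(np.isnan(sweep.dice), None, sweep.dice).tolist(),
        "argmax_threshold": sweep.argmax_threshold,
        "max_accuracy": sweep.max_accuracy,
    }


def write_report(result: SubjectResult, outdir: str | Path) -> dict[str, Path]:
    """Write the CSV classification table, JSON summary, and metric maps."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    table = format_report(result.rows)
    table.insert(0, "subject", result.subject_id)
    paths["classification"] = outdir / "classification.csv"
    table.to_csv(paths["classification"], index=False)

    surface = result.surface
    summary = {
        "subject_id": result.subject_id,
        "config_hash": result.config.config_hash,
        "config": result.config.to_dict(),
        "rows": result.rows.to_dict(orient="records"),
        "bh_optimal_threshold": result.sweep_bh.argmax_threshold,
        "rs_optimal_threshold": result.sweep_rs.argmax_threshold,
        "bh_max_accuracy": result.sweep_bh.max_accuracy,
        "rs_max_accuracy": result.sweep_rs.max_accuracy,
        "saddle_accuracy": surface.saddle_accuracy,
        "surface_corners": surface.corners,
        "self_concordance_accuracy": {
            "breathhold": result.concord_bh.accuracy,
            "resting": result.concord_rs.accuracy,
        },
        "unthresholded_pearson_r": result.unthresholded.pearson_r,
    }
    paths["summary"] = outdir / "summary.json"
    paths["summary"].write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")

    sweeps = {
        "config_hash": result.config.config_hash,
        "bh_vs_gray": _sweep_dict(result.sweep_bh),
        "rs_vs_gray": _sweep_dict(result.sweep_rs),
    }
    paths["sweeps"] = outdir / "sweeps.json"
    paths["sweeps"].write_text(json.dumps(sweeps, indent=2, sort_keys=True) + "\n")

    surf = {
        "config_hash": result.config.config_hash,
        "bh_thresholds": surface.bh_thresholds.tolist(),
        "rs_thresholds": surface.rs_thresholds.tolist(),
        "accuracy": surface.accuracy.tolist(),
        "corners": surface.corners,
        "saddle_accuracy": surface.saddle_accuracy,
        "saddle_thresholds": surface.saddle_thresholds,
    }
    paths["surface"] = outdir / "surface.json"
    paths["surface"].write_text(json.dumps(surf, indent=2, sort_keys=True) + "\n")

    paths["bh_map"] = nifti_io.write_map(result.bh_map, outdir / "bh_beta_map.nii.gz")
    paths["rs_map"] = nifti_io.write_map(result.rs_map, outdir / "rs_alff_map.nii.gz")
    if result.bh_map.best_lag is not None:
        paths["bh_lag"] = nifti_io.write_volume(
            result.bh_map.best_lag.astype(np.int16), outdir / "bh_best_lag.nii.gz"
        )
    if result.waveforms:
        wf = result.waveforms[0]
        wf_df = pd.DataFrame(
            {"time_s": np.arange(wf.values.size) * wf.tr, "value": wf.values}
        )
        paths["waveform"] = outdir / "personal_waveform.csv"
        wf_df.to_csv(paths["waveform"], index=False)
    return paths


def run_pipeline(
    manifest: RunManifest,
    config: PipelineConfig = PipelineConfig(),
    outdir: str | Path = "cvr_report",
) -> SubjectResult:
    """Load a subject from disk, run the analysis, and write the report."""
    manifest.validate()
    bh_runs = [nifti_io.read_bold(p) for p in manifest.bh_runs]
    rs_runs = [nifti_io.read_bold(p) for p in manifest.rs_runs]
    tissue = nifti_io.read_tissue(manifest.tissue)
    shapes = {r.spatial_shape for r in [*bh_runs, *rs_runs]} | {tissue.labels.shape}
    if len(shapes) != 1:
        raise ValueError(f"manifest volumes have mismatched grids: {shapes}")
    result = analyze_runs(bh_runs, rs_runs, tissue, config, manifest.subject_id)
    write_report(result, outdir)
    return result
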