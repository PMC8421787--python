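"""Preprocessing contracts and the resting-state ALFF ("CVRe") metric.

Truncation drops scanner-equilibration and partially captured epochs so
that both acquisitions contribute a comparable number of usable samples
(100 breath-hold volumes, 210 resting volumes at TR = 2 s).  Each voxel's
time series is then scaled to mean 100 (clipped to [0, 200]) so that
amplitudes are percent-of-baseline units.

ALFF is the summed single-sided DFT amplitude of a voxel's series within
0.01-0.08 Hz, used directly as the resting-state estimate of
cerebrovascular reactivity ("CVRe").
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.signal import detrend as _linear_detrend

from .containers import BoldRun, CvrMap, map_from_voi

__all__ = [
    "AlffParams",
    "BH_DROP_START",
    "BH_DROP_END",
    "breathhold_keep_slice",
    "truncate_breathhold",
    "truncate_resting",
    "scale_to_mean_100",
    "alff",
    "alff_map",
    "resting_cvre_map",
    "average_breathhold_runs",
]

#: Volumes removed from the front of a breath-hold run at TR = 2 s:
#: 2 equilibration volumes (4 s) plus the next 10 volumes (20 s).
BH_DROP_START = 12
#: Volumes removed from the end (last breath-hold response not fully captured).
BH_DROP_END = 20
#: Volumes removed from the front of a resting run (4 s equilibration).
RS_DROP_START = 2


@dataclass(frozen=True)
class AlffParams:
    """Band limits (Hz) and detrending switch for the ALFF estimate."""

    f_low: float = 0.01
    f_high: float = 0.08
    detrend: bool = True

    def validate(self, tr: float) -> None:
        nyquist = 1.0 / (2.0 * tr)
        if not 0 < self.f_low < self.f_high < nyquist:
            raise ValueError(
                f"band [{self.f_low}, {self.f_high}] Hz invalid for TR={tr}s "
                f"(Nyquist {nyquist} Hz)"
            )


def breathhold_keep_slice(n_volumes: int) -> slice:
    """The retained index range of a full-length breath-hold series.

    Useful for applying the identical truncation to model regressors that
    were built for the full acquisition.
    """
    if n_volumes < BH_DROP_START + BH_DROP_END + 1:
        raise ValueError(
            f"breath-hold run of {n_volumes} volumes is too short: truncation "
            f"removes the first {BH_DROP_START} and last {BH_DROP_END} volumes"
        )
    return slice(BH_DROP_START, n_volumes - BH_DROP_END)


def truncate_breathhold(run: BoldRun) -> BoldRun:
    """Drop equilibration+ramp-up volumes and the truncated final response.

    A 132-volume acquisition yields exactly 100 volumes.  Requires TR = 2 s
    metadata, for which the fixed volume counts are defined.
    """
    if not math.isclose(run.tr, 2.0):
        raise ValueError(f"breath-hold truncation rule is defined for TR=2 s, got {run.tr}")
    keep = breathhold_keep_slice(run.n_volumes)
    return BoldRun(run.data[..., keep], run.tr)


def truncate_resting(run: BoldRun, keep: int = 210) -> BoldRun:
    """Drop the 2 equilibration volumes, then keep the first ``keep`` volumes."""
    if run.n_volumes < keep + RS_DROP_START:
        raise ValueError(
            f"resting run of {run.n_volumes} volumes cannot supply {keep} volumes "
            f"after removing the first {RS_DROP_START}"
        )
    return BoldRun(run.data[..., RS_DROP_START : RS_DROP_START + keep], run.tr)


def scale_to_mean_100(run: BoldRun) -> tuple[BoldRun, np.ndarray]:
    """Scale each voxel series to mean 100, clipped to [0, 200].

    Returns the scaled run and a boolean volume flagging voxels whose mean
    was not positive; such voxels are zeroed and should be excluded from
    analysis VOIs.
    """
    data = run.data.astype(float)
    means = data.mean(axis=3)
    invalid = ~(means > 0)
    safe = np.where(invalid, 1.0, means)
    scaled = np.clip(100.0 * data / safe[..., None], 0.0, 200.0)
    scaled[invalid] = 0.0
    return BoldRun(scaled, run.tr), invalid


def _band_mask(n: int, tr: float, params: AlffParams) -> np.ndarray:
    freqs = np.fft.rfftfreq(n, d=tr)
    band = (freqs >= params.f_low) & (freqs <= params.f_high)
    if not band.any():
        raise ValueError(
            f"no DFT bin falls in [{params.f_low}, {params.f_high}] Hz for "
            f"n={n}, TR={tr}s"
        )
    return band


def alff(series, tr: float, params: AlffParams = AlffParams()) -> float:
    """Amplitude of low-frequency fluctuations of one time series.

    The series is mean-removed (and linearly detrended when
    ``params.detrend``), Fourier transformed, and the single-sided
    amplitudes ``2|X_k|/N`` are summed over bins with
    ``f_low <= f_k <= f_high`` (inclusive band edges).  A pure in-band
    sinusoid of amplitude A whose frequency hits a DFT bin returns A.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise ValueError("alff expects a 1D series; use alff_map for volumes")
    params.validate(tr)
    band = _band_mask(x.size, tr, params)
    x = _linear_detrend(x) if params.detrend else x - x.mean()
    amps = 2.0 * np.abs(np.fft.rfft(x)) / x.size
    return float(amps[band].sum())


def alff_map(data: np.ndarray, tr: float, params: AlffParams = AlffParams()) -> np.ndarray:
    """Vectorized ALFF along the last axis of ``data`` (..., t)."""
    params.validate(tr)
    n = data.shape[-1]
    band = _band_mask(n, tr, params)
    x = data.astype(float)
    x = _linear_detrend(x, axis=-1) if params.detrend else x - x.mean(axis=-1, keepdims=True)
    amps = 2.0 * np.abs(np.fft.rfft(x, axis=-1)) / n
    return amps[..., band].sum(axis=-1)


def resting_cvre_map(
    runs: BoldRun | list[BoldRun],
    voi: np.ndarray,
    params: AlffParams = AlffParams(),
) -> CvrMap:
    """Per-voxel ALFF over the VOI; mean across runs when two are given.

    Runs must already be truncated and scaled, and must share grid and TR.
    """
    if isinstance(runs, BoldRun):
        runs = [runs]
    if not runs:
        raise ValueError("at least one run required")
    voi = np.asarray(voi, dtype=bool)
    first = runs[0]
    for r in runs[1:]:
        if r.spatial_shape != first.spatial_shape:
            raise ValueError("runs have mismatched grids")
        if not math.isclose(r.tr, first.tr):
            raise ValueError("runs have mismatched TR")
    per_run = [alff_map(r.data[voi], r.tr, params) for r in runs]
    return map_from_voi(np.mean(per_run, axis=0), voi, "resting_alff")


def average_breathhold_runs(map1: CvrMap, map2: CvrMap) -> CvrMap:
    """Voxel-wise mean of two breath-hold beta maps.

    The per-voxel lag of the averaged map is the mean of the two per-run
    lags rounded half-down (ties toward the smaller delay).
    """
    if map1.values.shape != map2.values.shape:
        raise ValueError("maps have mismatched grids")
    if not np.array_equal(map1.voi_mask, map2.voi_mask):
        raise ValueError("maps have mismatched VOIs")
    if map1.metric_kind != map2.metric_kind:
        raise ValueError("cannot average maps of different metric kinds")
    voi = map1.voi_mask
    beta = (map1.voi_values + map2.voi_values) / 2.0
    lag_values = None
    if map1.best_lag is not None and map2.best_lag is not None:
        lsum = map1.best_lag[voi] + map2.best_lag[voi]
        lag_values = np.ceil(lsum / 2.0 - 0.5).astype(int)
    return map_from_voi(beta, voi, map1.metric_kind, lag_values=lag_values)
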