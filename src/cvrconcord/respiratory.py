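"""Breath-hold CVR estimation via a personalized respiratory waveform.

The breath-hold CVR metric for a voxel is the amplitude (beta) of the
subject's respiratory response waveform fitted to that voxel's BOLD time
series by least squares, allowing the waveform to be delayed by 0-4 TR to
absorb regional hemodynamic latency differences.

The waveform itself is estimated empirically.  A generic respiratory
response function (RRF),

    RRF(t) = 0.6 t^2.1 exp(-t/1.5) - 0.0023 t^3.54 exp(-t/4.25),

convolved with the breath-hold task timing gives an initial regressor; the
top fraction of voxels most correlated with it (over the same lag range)
are averaged, aligned to zero lag, and smoothed with a three-point order
statistic filter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .containers import BoldRun, CvrMap, PersonalRespWaveform, TaskTiming, map_from_voi

__all__ = [
    "RrfParams",
    "DEFAULT_RRF",
    "SmootherWeights",
    "DEFAULT_SMOOTHER",
    "PRINTED_SMOOTHER",
    "rrf",
    "sample_rrf_params",
    "initial_regressor",
    "osfilt_smooth",
    "select_top_correlated",
    "estimate_personal_waveform",
    "breathhold_cvr_map",
]


@dataclass(frozen=True)
class RrfParams:
    """Constants of the two-gamma-like respiratory response function.

    The positive lobe ``a1 * t**p1 * exp(-t/tau1)`` models the early BOLD
    rise after a breath hold; the slower negative lobe ``a2 * t**p2 *
    exp(-t/tau2)`` models the undershoot.  Time constants are in seconds.
    """

    a1: float = 0.6
    p1: float = 2.1
    tau1: float = 1.5
    a2: float = 0.0023
    p2: float = 3.54
    tau2: float = 4.25

    def __post_init__(self) -> None:
        for name in ("a1", "p1", "tau1", "a2", "p2", "tau2"):
            if not getattr(self, name) > 0:
                raise ValueError(f"RRF constant {name} must be positive")


DEFAULT_RRF = RrfParams()


@dataclass(frozen=True)
class SmootherWeights:
    """Coefficients of the three-point order statistic filter.

    Output at time t is ``w_med * median + w_max * max + w_min * min`` of
    the window (x[t-1], x[t], x[t+1]).  Unit-sum weights preserve the
    scale of a constant signal.
    """

    w_med: float = 0.70
    w_max: float = 0.15
    w_min: float = 0.15


DEFAULT_SMOOTHER = SmootherWeights()
#: As-printed variant whose weights sum to 2 (doubles a constant signal);
#: available for reproduction purposes, not used by default.
PRINTED_SMOOTHER = SmootherWeights(0.70, 1.15, 0.15)


def rrf(t, params: RrfParams = DEFAULT_RRF) -> np.ndarray:
    """Evaluate the generic respiratory response function at time(s) ``t``.

    Parameters
    ----------
    t : float or array-like
        Time in seconds since the respiratory event; must be >= 0.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("RRF is defined for t >= 0 only")
    pos = params.a1 * t**params.p1 * np.exp(-t / params.tau1)
    neg = params.a2 * t**params.p2 * np.exp(-t / params.tau2)
    out = pos - neg
    return out if out.ndim else float(out)


def sample_rrf_params(rng: np.random.Generator, jitter: float = 0.2) -> RrfParams:
    """Draw subject-specific RRF constants, each scaled by U(1-jitter, 1+jitter).

    Emulates individual differences in the latency and time course of the
    breath-hold response.
    """
    base = RrfParams()
    factors = rng.uniform(1.0 - jitter, 1.0 + jitter, size=6)
    return RrfParams(
        a1=base.a1 * factors[0],
        p1=base.p1 * factors[1],
        tau1=base.tau1 * factors[2],
        a2=base.a2 * factors[3],
        p2=base.p2 * factors[4],
        tau2=base.tau2 * factors[5],
    )


def initial_regressor(
    timing: TaskTiming,
    params: RrfParams = DEFAULT_RRF,
    tr: float | None = None,
    support_s: float = 60.0,
) -> np.ndarray:
    """Convolve the breath-hold indicator with the sampled RRF.

    The RRF is sampled at t = 0, TR, 2 TR, ... over ``support_s`` seconds
    (long enough to capture both lobes) and the discrete convolution is
    truncated to the run length.
    """
    tr = timing.tr if tr is None else tr
    if not math.isclose(tr, timing.tr):
        raise ValueError(f"tr={tr} does not match timing tr={timing.tr}")
    kernel = rrf(np.arange(0.0, support_s + tr / 2, tr), params)
    full = np.convolve(timing.hold_indicator, kernel)
    return full[: timing.n_volumes]


def osfilt_smooth(series, weights: SmootherWeights = DEFAULT_SMOOTHER) -> np.ndarray:
    """Three-point order statistic smoothing with edge replication."""
    x = np.asarray(series, dtype=float)
    if x.ndim != 1 or x.size < 3:
        raise ValueError("order-statistic filter needs a 1D series of length >= 3")
    padded = np.concatenate([x[:1], x, x[-1:]])
    win = np.lib.stride_tricks.sliding_window_view(padded, 3)
    return (
        weights.w_med * np.median(win, axis=1)
        + weights.w_max * win.max(axis=1)
        + weights.w_min * win.min(axis=1)
    )


def _lagged_correlations(
    Y: np.ndarray, regressor: np.ndarray, lags
) -> np.ndarray:
    """Pearson correlation of each row of Y with the regressor delayed by
    each integer lag (negative lags advance it), on the overlapping samples.

    Returns an array of shape (n_voxels, len(lags)); rows with zero
    variance in the overlap give NaN for that lag.
    """
    lags = list(lags)
    n, T = Y.shape
    out = np.full((n, len(lags)), np.nan)
    for col, lag in enumerate(lags):
        if lag >= 0:
            x = regressor[: T - lag]
            y = Y[:, lag:]
        else:
            x = regressor[-lag:]
            y = Y[:, : T + lag]
        xc = x - x.mean()
        sxx = xc @ xc
        yc = y - y.mean(axis=1, keepdims=True)
        syy = np.einsum("ij,ij->i", yc, yc)
        sxy = yc @ xc
        with np.errstate(invalid="ignore", divide="ignore"):
            out[:, col] = sxy / np.sqrt(sxx * syy)
    return out


def _continuous_delays(
    Y: np.ndarray, template: np.ndarray, lags: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Continuous delay of each row of Y relative to the template.

    The Pearson-correlation peak over the integer lag grid is refined by
    parabolic interpolation of its two neighbors, yielding a sub-sample
    delay estimate.  Returns ``(tau, peak_corr)``; rows with no finite
    correlation get tau 0 and peak NaN.
    """
    corr = _lagged_correlations(Y, template, lags)
    allnan = ~np.isfinite(corr).any(axis=1)
    corr = np.nan_to_num(corr, nan=-np.inf)
    peak = np.argmax(corr, axis=1)
    rows = np.arange(peak.size)
    peak_corr = corr[rows, peak]
    tau = lags[peak].astype(float)
    y0 = corr[rows, np.maximum(peak - 1, 0)]
    y1 = peak_corr
    y2 = corr[rows, np.minimum(peak + 1, len(lags) - 1)]
    interior = (
        (peak > 0)
        & (peak < len(lags) - 1)
        & ~allnan
        & np.isfinite(y0)
        & np.isfinite(y2)
    )
    if interior.any():
        with np.errstate(invalid="ignore", divide="ignore"):
            denom = y0 - 2.0 * y1 + y2
            delta = np.where(denom < 0, 0.5 * (y0 - y2) / denom, 0.0)
        tau[interior] += np.clip(delta[interior], -0.5, 0.5)
    tau[allnan] = 0.0
    peak_corr = np.where(allnan, np.nan, peak_corr)
    return tau, peak_corr


def _shift_series(x: np.ndarray, delay: float) -> np.ndarray:
    """Advance a series by ``delay`` samples (negative delays it), with
    linear interpolation between samples and edge replication."""
    t = np.arange(x.size, dtype=float)
    return np.interp(t + delay, t, x)


def select_top_correlated(
    run: BoldRun,
    regressor: np.ndarray,
    voi: np.ndarray,
    pct: float = 0.01,
    max_lag_tr: int = 4,
) -> np.ndarray:
    """Indices of the VOI voxels most correlated with the initial regressor.

    A voxel's score is its maximum Pearson correlation with the regressor
    over integer delays 0..max_lag_tr TR; only positive correlations
    qualify.  Constant-valued voxels are ineligible.  Returns
    ``ceil(pct * n_eligible)`` voxel coordinates, shape (k, 3), ordered by
    decreasing score with deterministic (index-order) tie breaking.
    """
    if not 0 < pct <= 1:
        raise ValueError("pct must lie in (0, 1]")
    voi = np.asarray(voi, dtype=bool)
    if not voi.any():
        raise ValueError("empty VOI")
    regressor = np.asarray(regressor, dtype=float)
    if regressor.size != run.n_volumes:
        raise ValueError(
            f"regressor length {regressor.size} != run length {run.n_volumes}"
        )
    coords = np.argwhere(voi)
    Y = run.data[voi].astype(float)
    corr = _lagged_correlations(Y, regressor, range(max_lag_tr + 1))
    score = np.max(np.where(np.isnan(corr), -np.inf, corr), axis=1)
    eligible = np.isfinite(score) & (Y.std(axis=1) > 0) & (score > 0)
    n_eligible = int(eligible.sum())
    if n_eligible == 0:
        raise ValueError("no eligible voxels correlate positively with the regressor")
    k = math.ceil(pct * n_eligible)
    score = np.where(eligible, score, -np.inf)
    order = np.argsort(-score, kind="stable")
    return coords[order[:k]]


def estimate_personal_waveform(
    run: BoldRun,
    regressor: np.ndarray,
    voi: np.ndarray,
    pct: float = 0.01,
    max_lag_tr: int = 4,
    weights: SmootherWeights = DEFAULT_SMOOTHER,
) -> PersonalRespWaveform:
    """Estimate the subject's breath-hold response waveform.

    The top ``pct`` most correlated VOI voxels are aligned to a common
    delay before averaging: per-voxel delays are measured by parabolic-
    refined cross-correlation over ±max_lag_tr (first against the
    strongest source voxel, then against the aligned template) and each
    series is advanced by its continuous delay, so the template is never
    a half-sample mixture of shifted responses.  The template is then
    anchored at the earliest delay cohort among all clearly responding
    VOI voxels (the handful of selected voxels need not sample the
    earliest delay), so that the subsequent 0..max_lag regression scan
    reads out each voxel's delay relative to the subject's own earliest
    response.  Shifts use linear interpolation with edge replication, so
    the waveform keeps the run length.  The average is finally smoothed
    with the order statistic filter.
    """
    sel = select_top_correlated(run, regressor, voi, pct=pct, max_lag_tr=max_lag_tr)
    Y = run.data[sel[:, 0], sel[:, 1], sel[:, 2]].astype(float)
    lags = np.arange(-max_lag_tr, max_lag_tr + 1)

    def _aligned_mean(tau: np.ndarray) -> np.ndarray:
        shifts = tau - tau.min()
        return np.mean([_shift_series(y, s) for y, s in zip(Y, shifts)], axis=0)

    # pass 1: align against the strongest source voxel (rows of Y are
    # ordered by decreasing correlation score); pass 2: refine against
    # the resulting template
    tau1, _ = _continuous_delays(Y, Y[0], lags)
    mean_series = _aligned_mean(tau1)
    tau2, _ = _continuous_delays(Y, mean_series, lags)
    mean_series = _aligned_mean(tau2)

    # anchor the waveform at the earliest clearly responding cohort of
    # the whole VOI; a robust low percentile keeps isolated falsely-early
    # voxels from shifting the waveform
    tau_all, peak_all = _continuous_delays(
        run.data[voi].astype(float), mean_series, lags
    )
    good = np.isfinite(peak_all) & (peak_all >= 0.6)
    if good.any():
        tg = tau_all[good]
        edge = np.percentile(tg, 5.0)
        cohort = tg[np.abs(tg - edge) <= 0.5]
        anchor = float(np.median(cohort)) if cohort.size else float(edge)
        if abs(anchor) > 1e-9:
            # the earliest cohort sits at delay ``anchor`` relative to the
            # template; advancing the template by -anchor brings it to 0
            mean_series = _shift_series(mean_series, -anchor)
    smoothed = osfilt_smooth(mean_series, weights)
    return PersonalRespWaveform(smoothed, run.tr, n_source_voxels=sel.shape[0])


def lagged_beta_fits(
    run: BoldRun,
    waveform: PersonalRespWaveform,
    voi: np.ndarray,
    max_lag_tr: int = 4,
) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares fits of the delayed waveform at every candidate lag.

    For each VOI voxel (flattened, C order) and each delay lag in
    0..max_lag_tr TR the model ``y[lag:] = intercept + beta *
    waveform[:T-lag]`` is fitted on the overlapping samples.  Returns
    ``(betas, r2)``, each of shape (n_voi_voxels, max_lag_tr + 1).
    """
    voi = np.asarray(voi, dtype=bool)
    w = waveform.values
    if w.size != run.n_volumes:
        raise ValueError(
            f"waveform length {w.size} != run length {run.n_volumes}"
        )
    if np.std(w) == 0:
        raise ValueError("waveform has zero variance; regression undefined")
    Y = run.data[voi].astype(float)
    n, T = Y.shape
    betas = np.zeros((n, max_lag_tr + 1))
    r2 = np.zeros((n, max_lag_tr + 1))
    for lag in range(max_lag_tr + 1):
        x = w[: T - lag]
        y = Y[:, lag:]
        xc = x - x.mean()
        sxx = xc @ xc
        yc = y - y.mean(axis=1, keepdims=True)
        syy = np.einsum("ij,ij->i", yc, yc)
        sxy = yc @ xc
        betas[:, lag] = sxy / sxx
        with np.errstate(invalid="ignore", divide="ignore"):
            r2[:, lag] = np.where(syy > 0, sxy**2 / (sxx * syy), 0.0)
    return betas, r2


def breathhold_cvr_map(
    run: BoldRun,
    waveform: PersonalRespWaveform,
    voi: np.ndarray,
    max_lag_tr: int = 4,
) -> CvrMap:
    """Multi-lag least-squares fit of the personal waveform to every voxel.

    The delay maximizing the coefficient of determination wins (ties
    toward the smallest lag) and its beta becomes the voxel's breath-hold
    CVR metric.
    """
    voi = np.asarray(voi, dtype=bool)
    betas, r2 = lagged_beta_fits(run, waveform, voi, max_lag_tr)
    best = np.argmax(r2, axis=1)  # first occurrence = smallest lag on ties
    beta_best = betas[np.arange(betas.shape[0]), best]
    return map_from_voi(beta_best, voi, "breathhold_beta", lag_values=best)
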