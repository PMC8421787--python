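"""Seeded synthetic BOLD subjects with known cerebrovascular ground truth.

The phantom supplies everything the analysis consumes — tissue labels,
breath-hold and resting acquisitions, and the truth fields they were
generated from — so every downstream stage can be tested for parameter
recovery without any data download.

Geometry is deliberately non-anatomical: a connected gray-matter shell
around a white-matter core (concentric ellipsoids) inside an excluded
background.  The analysis only needs labeled compartments with the
assumed contrast: CVR responsiveness confined predominantly to gray
matter, gray matter carrying more low-frequency fluctuation power than
white, and per-voxel hemodynamic delays of 0-4 TR.

Signals are generated in percent-of-baseline units around a baseline of
100, i.e. already on the scale that mean-100 amplitude scaling produces,
with additive white Gaussian noise per voxel.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .containers import (
    LABEL_GRAY,
    LABEL_WHITE,
    PHASE_HOLD,
    PHASE_INHALE,
    PHASE_REST,
    BoldRun,
    TaskTiming,
    TissueLabelVolume,
)
from .respiratory import RrfParams, initial_regressor, sample_rrf_params

__all__ = [
    "LesionSpec",
    "PhantomSpec",
    "PhantomTruth",
    "PhantomSubject",
    "build_breathhold_timing",
    "generate_tissue_volume",
    "generate_truth",
    "generate_breathhold_run",
    "generate_resting_run",
    "simulate_subject",
    "write_subject",
]

#: Breath-hold block durations in seconds.
EQUILIBRATION_S = 4.0
REST_S = 40.0
INHALE_S = 4.0
HOLD_S = 16.0
TAIL_S = 20.0
N_EPOCHS = 4

#: Resting acquisition length in volumes at TR = 2 s (604 s).
RESTING_VOLUMES = 302


def build_breathhold_timing(tr: float = 2.0) -> TaskTiming:
    """Per-volume phase labels for the standard breath-hold paradigm.

    4 s equilibration, then four epochs of 40 s rest / 4 s inhale / 16 s
    hold, then a 20 s rest tail: 264 s total, 132 volumes at TR = 2 s.
    The TR must evenly tile every block duration.
    """
    if not tr > 0:
        raise ValueError("tr must be positive")
    for dur in (EQUILIBRATION_S, REST_S, INHALE_S, HOLD_S, TAIL_S):
        n = dur / tr
        if abs(n - round(n)) > 1e-9:
            raise ValueError(
                f"TR={tr}s does not evenly divide the {dur}s task block"
            )

    def vols(seconds: float) -> int:
        return int(round(seconds / tr))

    labels: list[int] = []
    equil: list[bool] = []
    labels += [PHASE_REST] * vols(EQUILIBRATION_S)
    equil += [True] * vols(EQUILIBRATION_S)
    for _ in range(N_EPOCHS):
        labels += [PHASE_REST] * vols(REST_S)
        labels += [PHASE_INHALE] * vols(INHALE_S)
        labels += [PHASE_HOLD] * vols(HOLD_S)
        equil += [False] * vols(REST_S + INHALE_S + HOLD_S)
    labels += [PHASE_REST] * vols(TAIL_S)
    equil += [False] * vols(TAIL_S)
    return TaskTiming(np.array(labels), np.array(equil), tr)


@dataclass(frozen=True)
class LesionSpec:
    """Spherical zero-CVR region emulating neurovascular uncoupling."""

    center: tuple[float, float, float]  # voxel coordinates
    radius: float  # voxels


@dataclass(frozen=True)
class PhantomSpec:
    """All knobs of one synthetic subject; the seed fixes every draw.

    Amplitudes are in percent-of-baseline signal units (baseline 100).
    ``cvr_contrast`` is the gray:white ratio of true CVR amplitude; the
    default ``None`` confines responsiveness strictly to gray matter
    (white amplitude 0).  ``noise_sd`` defaults to 20% of the gray-matter
    CVR amplitude.  ``rs_noise_sd`` overrides the broadband noise level of
    the resting runs only (``None`` = same as ``noise_sd``), allowing
    controlled task-vs-rest noise comparisons.  ``metric_coupling`` in
    [0, 1] correlates the gray-matter CVR and ALFF amplitude variability
    (0 = independent truth fields, 1 = proportional), emulating a shared
    underlying vascular structure for the two metrics.
    """

    shape: tuple[int, int, int] = (32, 32, 32)
    tr: float = 2.0
    gm_fraction: float = 0.55
    cvr_amplitude: float = 2.0
    cvr_contrast: float | None = None
    alff_amplitude: float = 2.0
    alff_contrast: float = 2.5
    amplitude_cv: float = 0.1
    metric_coupling: float = 0.0
    max_lag_tr: int = 4
    rrf_jitter: float = 0.2
    noise_sd: float = 0.4
    rs_noise_sd: float | None = None
    baseline: float = 100.0
    lesion: LesionSpec | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("cvr_amplitude", "alff_amplitude", "baseline"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not 0 < self.gm_fraction <= 1:
            raise ValueError("gm_fraction must lie in (0, 1]")


@dataclass
class PhantomTruth:
    """Ground-truth fields a phantom subject was generated from."""

    cvr_amplitude: np.ndarray  # 3D, >= 0; 0 outside responsive_mask
    lag_map: np.ndarray  # 3D int, TR units, 0..max_lag
    alff_amplitude: np.ndarray  # 3D, >= 0
    responsive_mask: np.ndarray  # 3D bool: ground-truth "CVR intact"

    def __post_init__(self) -> None:
        self.responsive_mask = np.asarray(self.responsive_mask, dtype=bool)
        if np.any(self.cvr_amplitude[~self.responsive_mask] != 0):
            raise ValueError("cvr_amplitude must be 0 outside responsive_mask")
        if np.any(self.cvr_amplitude < 0) or np.any(self.alff_amplitude < 0):
            raise ValueError("amplitudes must be non-negative")


@dataclass
class PhantomSubject:
    """One fully simulated subject: masks, truth, and all four runs."""

    spec: PhantomSpec
    tissue: TissueLabelVolume
    truth: PhantomTruth
    rrf_params: RrfParams
    timing: TaskTiming
    bh_runs: list[BoldRun]
    rs_runs: list[BoldRun]


def _ellipsoid_mask(shape: tuple[int, int, int], semi_axes: np.ndarray) -> np.ndarray:
    grids = np.meshgrid(
        *[(np.arange(n) - (n - 1) / 2.0) for n in shape], indexing="ij"
    )
    r2 = sum((g / a) ** 2 for g, a in zip(grids, semi_axes))
    return r2 <= 1.0


def generate_tissue_volume(spec: PhantomSpec) -> TissueLabelVolume:
    """Concentric-ellipsoid tissue labels: gray shell around a white core.

    The inner (white) ellipsoid is scaled so the gray fraction of the
    gray+white volume matches ``spec.gm_fraction`` up to voxelization
    error.  Deterministic for a given spec.
    """
    shape = tuple(spec.shape)
    if len(shape) != 3 or min(shape) < 8:
        raise ValueError(f"phantom grid must be at least 8 voxels per axis, got {shape}")
    outer_axes = 0.85 * (np.array(shape) - 1) / 2.0
    outer = _ellipsoid_mask(shape, outer_axes)
    # continuum volume ratio inner/outer = s^3 = 1 - gm_fraction
    s = (1.0 - spec.gm_fraction) ** (1.0 / 3.0)
    labels = np.zeros(shape, dtype=np.int16)
    labels[outer] = LABEL_GRAY
    if s > 0:
        white = _ellipsoid_mask(shape, np.maximum(outer_axes * s, 1e-9))
        labels[white & outer] = LABEL_WHITE
    return TissueLabelVolume(labels)


def _jittered_field(
    rng: np.random.Generator, mask: np.ndarray, level: float, cv: float
) -> np.ndarray:
    out = np.zeros(mask.shape)
    n = int(mask.sum())
    out[mask] = np.clip(level * (1.0 + cv * rng.standard_normal(n)), 0.0, None)
    return out


def generate_truth(
    spec: PhantomSpec, tissue: TissueLabelVolume, rng: np.random.Generator
) -> PhantomTruth:
    """Draw per-voxel truth fields consistent with the tissue labels.

    Gray matter receives CVR amplitude ``spec.cvr_amplitude`` and ALFF
    amplitude ``spec.alff_amplitude`` (both with ``amplitude_cv``
    lognormal-free Gaussian variability, clipped at 0); white matter
    receives the respective contrast-reduced levels.  An optional lesion
    zeroes CVR amplitude, marking those voxels non-responsive.
    """
    gm, wm = tissue.gray_mask, tissue.white_mask
    n_gm = int(gm.sum())
    z_cvr = rng.standard_normal(n_gm)
    cvr = np.zeros(tissue.labels.shape)
    cvr[gm] = np.clip(
        spec.cvr_amplitude * (1.0 + spec.amplitude_cv * z_cvr), 0.0, None
    )
    if spec.cvr_contrast is not None:
        cvr += _jittered_field(
            rng, wm, spec.cvr_amplitude / spec.cvr_contrast, spec.amplitude_cv
        )
    # gray-matter ALFF variability optionally shares the CVR truth's
    # spatial structure
    c = spec.metric_coupling
    z_alff = c * z_cvr + np.sqrt(max(1.0 - c**2, 0.0)) * rng.standard_normal(n_gm)
    alff_amp = np.zeros(tissue.labels.shape)
    alff_amp[gm] = np.clip(
        spec.alff_amplitude * (1.0 + spec.amplitude_cv * z_alff), 0.0, None
    )
    alff_amp += _jittered_field(
        rng, wm, spec.alff_amplitude / spec.alff_contrast, spec.amplitude_cv
    )
    if spec.lesion is not None:
        grids = np.meshgrid(*[np.arange(n) for n in cvr.shape], indexing="ij")
        d2 = sum((g - c) ** 2 for g, c in zip(grids, spec.lesion.center))
        cvr[d2 <= spec.lesion.radius**2] = 0.0
    responsive = cvr > 0
    lag = np.zeros(cvr.shape, dtype=int)
    lag[responsive] = rng.integers(0, spec.max_lag_tr + 1, size=int(responsive.sum()))
    return PhantomTruth(cvr, lag, alff_amp, responsive)


def generate_breathhold_run(
    spec: PhantomSpec,
    truth: PhantomTruth,
    timing: TaskTiming,
    rrf_params: RrfParams,
    rng: np.random.Generator,
) -> BoldRun:
    """Simulate one breath-hold acquisition.

    Voxel series = baseline + cvr_amplitude * (task regressor delayed by
    the voxel's lag) + white Gaussian noise.  The regressor is the
    hold-phase indicator convolved with the subject's RRF and normalized
    to unit maximum absolute value, so ``cvr_amplitude`` is the peak
    response excursion in percent-of-baseline units.
    """
    if truth.cvr_amplitude.shape != tuple(spec.shape):
        raise ValueError("truth fields not aligned to the phantom grid")
    T = timing.n_volumes
    reg = initial_regressor(timing, rrf_params, spec.tr)
    peak = np.max(np.abs(reg))
    if peak > 0:
        reg = reg / peak
    shifted = np.zeros((spec.max_lag_tr + 1, T))
    for lag in range(spec.max_lag_tr + 1):
        shifted[lag, lag:] = reg[: T - lag]
    signal = truth.cvr_amplitude[..., None] * shifted[truth.lag_map]
    noise = rng.normal(0.0, spec.noise_sd, size=signal.shape) if spec.noise_sd > 0 else 0.0
    data = spec.baseline + signal + noise
    return BoldRun(data, spec.tr)


def generate_resting_run(
    spec: PhantomSpec,
    truth: PhantomTruth,
    rng: np.random.Generator,
    n_volumes: int = RESTING_VOLUMES,
) -> BoldRun:
    """Simulate one resting acquisition (302 volumes at TR = 2 s).

    Each voxel with nonzero ALFF amplitude receives an independent random
    fluctuation band-limited to 0.01-0.08 Hz, normalized so its summed
    single-sided in-band amplitude equals 1, then scaled by the voxel's
    truth amplitude; broadband Gaussian noise is added everywhere.
    """
    shape = tuple(spec.shape)
    noise_sd = spec.noise_sd if spec.rs_noise_sd is None else spec.rs_noise_sd
    voi = truth.alff_amplitude > 0
    n_vox = int(voi.sum())
    data = np.full(shape + (n_volumes,), spec.baseline)
    if n_vox:
        freqs = np.fft.rfftfreq(n_volumes, d=spec.tr)
        band = (freqs >= 0.01) & (freqs <= 0.08)
        z = rng.standard_normal((n_vox, n_volumes))
        Z = np.fft.rfft(z, axis=1) * band
        x = np.fft.irfft(Z, n=n_volumes, axis=1)
        inband_amp = 2.0 * np.abs(Z[:, band]).sum(axis=1) / n_volumes
        inband_amp[inband_amp == 0] = 1.0
        x /= inband_amp[:, None]
        data[voi] += truth.alff_amplitude[voi, None] * x
    if noise_sd > 0:
        data = data + rng.normal(0.0, noise_sd, size=data.shape)
    return BoldRun(data, spec.tr)


def simulate_subject(spec: PhantomSpec) -> PhantomSubject:
    """Generate one complete subject: tissue, truth, two runs per task.

    All randomness descends from ``spec.seed`` through independent
    substreams, so identical specs give bit-identical subjects and the
    two runs of each task carry independent noise.
    """
    streams = np.random.SeedSequence(spec.seed).spawn(6)
    rngs = [np.random.default_rng(s) for s in streams]
    tissue = generate_tissue_volume(spec)
    truth = generate_truth(spec, tissue, rngs[0])
    rrf_params = sample_rrf_params(rngs[1], spec.rrf_jitter)
    timing = build_breathhold_timing(spec.tr)
    bh_runs = [
        generate_breathhold_run(spec, truth, timing, rrf_params, rngs[i])
        for i in (2, 3)
    ]
    rs_runs = [generate_resting_run(spec, truth, rngs[i]) for i in (4, 5)]
    return PhantomSubject(spec, tissue, truth, rrf_params, timing, bh_runs, rs_runs)


def write_subject(subject: PhantomSubject, outdir: str | Path) -> dict[str, Path]:
    """Write a subject to NIfTI volumes plus a JSON spec sidecar."""
    from . import nifti_io

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for i, run in enumerate(subject.bh_runs, start=1):
        paths[f"bh_run{i}"] = nifti_io.write_bold(
            run, outdir / f"bh_run{i}.nii.gz", subject.tissue.voxel_dims
        )
    for i, run in enumerate(subject.rs_runs, start=1):
        paths[f"rs_run{i}"] = nifti_io.write_bold(
            run, outdir / f"rs_run{i}.nii.gz", subject.tissue.voxel_dims
        )
    paths["tissue"] = nifti_io.write_labels(
        subject.tissue, outdir / "tissue.nii.gz"
    )
    vd = subject.tissue.voxel_dims
    paths["truth_cvr"] = nifti_io.write_volume(
        subject.truth.cvr_amplitude, outdir / "truth_cvr.nii.gz", vd
    )
    paths["truth_lag"] = nifti_io.write_volume(
        subject.truth.lag_map.astype(np.int16), outdir / "truth_lag.nii.gz", vd
    )
    paths["truth_alff"] = nifti_io.write_volume(
        subject.truth.alff_amplitude, outdir / "truth_alff.nii.gz", vd
    )
    paths["truth_responsive"] = nifti_io.write_volume(
        subject.truth.responsive_mask.astype(np.uint8),
        outdir / "truth_responsive.nii.gz",
        vd,
    )
    spec_dict = dataclasses.asdict(subject.spec)
    spec_dict["shape"] = list(spec_dict["shape"])
    if spec_dict["lesion"] is not None:
        spec_dict["lesion"]["center"] = list(spec_dict["lesion"]["center"])
    sidecar = outdir / "phantom_spec.json"
    sidecar.write_text(json.dumps(spec_dict, indent=2, sort_keys=True) + "\n")
    paths["spec"] = sidecar
    return paths
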