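"""Core in-memory containers shared across the pipeline.

All volumes follow the NIfTI axis convention ``(x, y, z)`` with time last,
so a 4D BOLD run is ``(x, y, z, t)``.  Tissue labels are integer coded:
0 = excluded, 1 = gray matter, 2 = white matter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

LABEL_EXCLUDED = 0
LABEL_GRAY = 1
LABEL_WHITE = 2

#: Breath-hold task phase codes (per acquired volume).
PHASE_REST = 0
PHASE_INHALE = 1
PHASE_HOLD = 2


@dataclass
class BoldRun:
    """One 4D BOLD acquisition.

    Parameters
    ----------
    data : ndarray, shape (x, y, z, t)
        Signal values; any float dtype.
    tr : float
        Repetition time in seconds (the sampling interval).
    """

    data: np.ndarray
    tr: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError(
                f"BoldRun requires a 4D (x, y, z, t) array, got ndim={self.data.ndim}"
            )
        if not self.tr > 0:
            raise ValueError(f"TR must be positive, got {self.tr}")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]


@dataclass
class TissueLabelVolume:
    """Per-voxel tissue labels defining the analysis volumes of interest.

    The gray/white-matter VOI ("GWM-VOI") is the union of gray and white
    labels; the gray-matter VOI ("GM-VOI") is the gray label alone.
    """

    labels: np.ndarray
    voxel_dims: tuple[float, float, float] = (3.0, 3.0, 3.0)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("tissue labels must be a 3D volume")
        bad = np.setdiff1d(np.unique(self.labels), [LABEL_EXCLUDED, LABEL_GRAY, LABEL_WHITE])
        if bad.size:
            raise ValueError(f"tissue labels outside {{0,1,2}}: {bad.tolist()}")

    @property
    def gray_mask(self) -> np.ndarray:
        return self.labels == LABEL_GRAY

    @property
    def white_mask(self) -> np.ndarray:
        return self.labels == LABEL_WHITE

    @property
    def gwm_mask(self) -> np.ndarray:
        """Union of gray and white matter (the GWM-VOI)."""
        return self.labels != LABEL_EXCLUDED


@dataclass
class TaskTiming:
    """Per-volume phase labels for a block-design breath-hold task."""

    labels: np.ndarray  # one of PHASE_REST / PHASE_INHALE / PHASE_HOLD per volume
    equilibration: np.ndarray  # bool per volume: scanner equilibration period
    tr: float

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int8)
        self.equilibration = np.asarray(self.equilibration, dtype=bool)
        if self.labels.shape != self.equilibration.shape:
            raise ValueError("labels and equilibration flags must align")

    @property
    def n_volumes(self) -> int:
        return self.labels.size

    @property
    def duration_s(self) -> float:
        return self.n_volumes * self.tr

    @property
    def hold_indicator(self) -> np.ndarray:
        """Binary regressor input: 1 during breath-hold volumes, else 0."""
        return (self.labels == PHASE_HOLD).astype(float)


@dataclass
class PersonalRespWaveform:
    """A subject's empirically estimated breath-hold response time series."""

    values: np.ndarray
    tr: float
    n_source_voxels: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("waveform must be a 1D time series")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("waveform contains non-finite values")


@dataclass
class CvrMap:
    """A per-voxel scalar CVR metric defined over a volume of interest.

    ``values`` is finite exactly on ``voi_mask`` and NaN elsewhere.
    ``best_lag`` (breath-hold maps only) holds the optimal shift in TR
    units, with -1 outside the VOI.
    """

    values: np.ndarray
    voi_mask: np.ndarray
    metric_kind: str  # "breathhold_beta" or "resting_alff"
    best_lag: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.voi_mask = np.asarray(self.voi_mask, dtype=bool)
        if self.values.shape != self.voi_mask.shape:
            raise ValueError("values and voi_mask must share a grid")
        finite = np.isfinite(self.values)
        if not np.array_equal(finite, self.voi_mask):
            raise ValueError("map values must be finite exactly on the VOI")
        if self.best_lag is not None:
            self.best_lag = np.asarray(self.best_lag)
            if self.best_lag.shape != self.values.shape:
                raise ValueError("best_lag grid mismatch")

    @property
    def voi_values(self) -> np.ndarray:
        """Metric values flattened over the VOI (C order)."""
        return self.values[self.voi_mask]


def map_from_voi(
    voi_values: np.ndarray,
    voi_mask: np.ndarray,
    metric_kind: str,
    lag_values: np.ndarray | None = None,
) -> CvrMap:
    """Assemble a :class:`CvrMap` from values given on the flattened VOI."""
    values = np.full(voi_mask.shape, np.nan)
    values[voi_mask] = voi_values
    best_lag = None
    if lag_values is not None:
        best_lag = np.full(voi_mask.shape, -1, dtype=int)
        best_lag[voi_mask] = lag_values
    return CvrMap(values, voi_mask, metric_kind, best_lag)
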