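"""NIfTI-1 readers and writers for runs, maps, and tissue labels."""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np

from .containers import BoldRun, CvrMap, TissueLabelVolume

__all__ = [
    "read_bold",
    "write_bold",
    "read_tissue",
    "write_labels",
    "read_map",
    "write_map",
    "write_volume",
]


def _load(path: str | Path) -> nib.Nifti1Image:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several format errors
        raise ValueError(f"{path} is not a readable NIfTI file: {exc}") from exc
    return img


def _affine(voxel_dims: tuple[float, float, float]) -> np.ndarray:
    return np.diag(list(voxel_dims) + [1.0])


def read_bold(path: str | Path) -> BoldRun:
    """Read a 4D BOLD run; the TR is taken from the header's time zoom."""
    img = _load(path)
    if img.ndim != 4:
        raise ValueError(f"{path}: expected a 4D run, got {img.ndim}D")
    tr = float(img.header.get_zooms()[3])
    if not tr > 0:
        raise ValueError(f"{path}: header carries no positive TR")
    return BoldRun(np.asarray(img.dataobj, dtype=np.float64), tr)


def write_bold(
    run: BoldRun,
    path: str | Path,
    voxel_dims: tuple[float, float, float] = (3.0, 3.0, 3.0),
) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(run.data.astype(np.float32), _affine(voxel_dims))
    img.header.set_zooms(tuple(voxel_dims) + (run.tr,))
    img.header.set_xyzt_units("mm", "sec")
    nib.save(img, str(path))
    return path


def read_tissue(path: str | Path) -> TissueLabelVolume:
    """Read a 3D tissue-label volume (values must be 0, 1, or 2)."""
    img = _load(path)
    if img.ndim != 3:
        raise ValueError(f"{path}: expected a 3D label volume, got {img.ndim}D")
    labels = np.asarray(img.dataobj)
    if not np.all(np.isin(labels, [0, 1, 2])):
        raise ValueError(f"{path}: tissue labels outside {{0,1,2}}")
    zooms = img.header.get_zooms()[:3]
    return TissueLabelVolume(labels.astype(np.int16), tuple(float(z) for z in zooms))


def write_labels(tissue: TissueLabelVolume, path: str | Path) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(
        tissue.labels.astype(np.int16), _affine(tissue.voxel_dims)
    )
    nib.save(img, str(path))
    return path


def write_volume(
    volume: np.ndarray,
    path: str | Path,
    voxel_dims: tuple[float, float, float] = (3.0, 3.0, 3.0),
) -> Path:
    """Write an arbitrary 3D volume (truth fields, masks, difference maps)."""
    path = Path(path)
    vol = np.asarray(volume)
    if vol.ndim != 3:
        raise ValueError("write_volume expects a 3D array")
    nib.save(nib.Nifti1Image(vol, _affine(voxel_dims)), str(path))
    return path


def read_map(path: str | Path, metric_kind: str) -> CvrMap:
    """Read a 3D metric map; NaN voxels are outside the VOI."""
    img = _load(path)
    if img.ndim != 3:
        raise ValueError(f"{path}: expected a 3D map, got {img.ndim}D")
    values = np.asarray(img.dataobj, dtype=np.float64)
    return CvrMap(values, np.isfinite(values), metric_kind)


def write_map(
    cvr_map: CvrMap,
    path: str | Path,
    voxel_dims: tuple[float, float, float] = (3.0, 3.0, 3.0),
) -> Path:
    return write_volume(cvr_map.values.astype(np.float32), path, voxel_dims)
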