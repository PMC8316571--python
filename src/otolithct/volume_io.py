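"""CT volume input/output and the coordinate contract.

Every grid in the package uses the same convention:

* axis order ``(slice, row, column)``, 0-based indices;
* ``spacing_mm`` gives the voxel pitch per axis, in that order;
* world coordinates are voxel *centers*:
  ``world = origin_mm + index * spacing_mm`` (elementwise, mm).

Hounsfield units are clamped to ``[-1024, 3100]`` on read; the upper bound
is the largest CT value of any calcium compound handled by the classifier
(calcium oxide), the lower bound is air.

NIfTI-1 is the canonical interchange format; DICOM series are read-only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np

__all__ = [
    "HU_MIN",
    "HU_MAX",
    "CTVolume",
    "Mask",
    "read_volume",
    "write_volume",
    "index_to_world",
    "world_to_index",
    "inplane_spacing",
]

HU_MIN = -1024.0
HU_MAX = 3100.0


def _check_grid(shape: tuple, spacing: tuple) -> None:
    if len(shape) != 3 or any(s < 1 for s in shape):
        raise ValueError(f"grid must have 3 axes, each >= 1, got shape {shape}")
    if len(spacing) != 3 or any(not (s > 0) for s in spacing):
        raise ValueError(f"spacing components must be > 0, got {spacing}")


@dataclass
class CTVolume:
    """A 3D scalar grid of Hounsfield units with voxel geometry.

    Parameters
    ----------
    voxels
        HU values, axis order (slice, row, column).
    spacing_mm
        Voxel pitch per axis (slice, row, column), mm.
    origin_mm
        World coordinates (mm) of the center of voxel (0, 0, 0).
    """

    voxels: np.ndarray
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        _check_grid(self.voxels.shape, tuple(self.spacing_mm))
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        self.origin_mm = tuple(float(o) for o in self.origin_mm)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))

    def copy(self) -> "CTVolume":
        return replace(self, voxels=self.voxels.copy())


@dataclass
class Mask:
    """A boolean grid aligned to a :class:`CTVolume`."""

    data: np.ndarray
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)
        _check_grid(self.data.shape, tuple(self.spacing_mm))
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        self.origin_mm = tuple(float(o) for o in self.origin_mm)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def count(self) -> int:
        return int(self.data.sum())

    def like(self, data: np.ndarray) -> "Mask":
        """New mask on the same grid."""
        return Mask(data, self.spacing_mm, self.origin_mm)


def inplane_spacing(fov_mm: float, matrix: int) -> float:
    """In-plane pixel pitch of an acquisition: FOV / matrix (mm)."""
    if fov_mm <= 0 or matrix < 1:
        raise ValueError("FOV must be positive and matrix >= 1")
    return fov_mm / matrix


# ---------------------------------------------------------------------------
# NIfTI
# ---------------------------------------------------------------------------

def _write_nifti(volume: CTVolume, path: Path) -> None:
    # nibabel's (i, j, k) is our (column, row, slice); keep a diagonal
    # affine so the round trip is exact.
    sz, sy, sx = volume.spacing_mm
    oz, oy, ox = volume.origin_mm
    affine = np.diag([sx, sy, sz, 1.0])
    affine[:3, 3] = [ox, oy, oz]
    img = nib.Nifti1Image(volume.voxels.transpose(2, 1, 0), affine)
    nib.save(img, str(path))


def _read_nifti(path: Path) -> CTVolume:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 2:  # single-slice file
        data = data[:, :, None]
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D volume, got {data.ndim} axes")
    zooms = img.header.get_zooms()[:3]
    if any(not (z > 0) for z in zooms):
        raise ValueError(f"{path}: non-positive voxel spacing in header")
    trans = np.asarray(img.affine)[:3, 3]
    voxels = np.clip(data.transpose(2, 1, 0), HU_MIN, HU_MAX)
    if np.issubdtype(data.dtype, np.integer):
        voxels = voxels.astype(data.dtype)
    return CTVolume(
        voxels=voxels,
        spacing_mm=(float(zooms[2]), float(zooms[1]), float(zooms[0])),
        origin_mm=(float(trans[2]), float(trans[1]), float(trans[0])),
    )


# ---------------------------------------------------------------------------
# DICOM (read-only)
# ---------------------------------------------------------------------------

def _read_dicom_dir(path: Path) -> CTVolume:
    import pydicom

    files = sorted(p for p in path.iterdir() if p.is_file())
    datasets = []
    for f in files:
        try:
            ds = pydicom.dcmread(str(f))
        except Exception:
            continue  # skip non-DICOM files in the directory
        if not hasattr(ds, "PixelData"):
            continue
        datasets.append((f, ds))
    if not datasets:
        raise ValueError(f"{path}: no DICOM image files found")

    modality = getattr(datasets[0][1], "Modality", "CT")
    if modality != "CT":
        warnings.warn(f"{path}: modality {modality!r} is not CT; proceeding")

    orientations = set()
    for f, ds in datasets:
        iop = getattr(ds, "ImageOrientationPatient", None)
        if iop is not None:
            orientations.add(tuple(round(float(v), 6) for v in iop))
    if len(orientations) > 1:
        raise ValueError(f"{path}: inconsistent image orientation across series")

    def sort_key(item):
        f, ds = item
        ipp = getattr(ds, "ImagePositionPatient", None)
        if ipp is not None:
            return float(ipp[2])
        return float(getattr(ds, "InstanceNumber", 0))

    datasets.sort(key=sort_key)

    slices = []
    positions = []
    for f, ds in datasets:
        ps = getattr(ds, "PixelSpacing", None)
        if ps is None:
            raise ValueError(f"{f}: missing PixelSpacing")
        slope = getattr(ds, "RescaleSlope", None)
        intercept = getattr(ds, "RescaleIntercept", None)
        if slope is None or intercept is None:
            raise ValueError(f"{f}: missing rescale slope/intercept")
        hu = ds.pixel_array.astype(np.float64) * float(slope) + float(intercept)
        slices.append(hu)
        ipp = getattr(ds, "ImagePositionPatient", None)
        positions.append(None if ipp is None else float(ipp[2]))

    ps = datasets[0][1].PixelSpacing  # (row, col)
    row_sp, col_sp = float(ps[0]), float(ps[1])

    if len(positions) > 1 and all(p is not None for p in positions):
        steps = np.diff(positions)
        if np.ptp(steps) > 1e-3:
            raise ValueError(f"{path}: inconsistent slice spacing across series")
        slice_sp = float(abs(steps[0]))
    else:
        st = getattr(datasets[0][1], "SliceThickness", None)
        if st is None:
            raise ValueError(f"{datasets[0][0]}: cannot determine slice spacing")
        slice_sp = float(st)
    if slice_sp <= 0:
        raise ValueError(f"{path}: non-positive slice spacing")

    voxels = np.clip(np.stack(slices, axis=0), HU_MIN, HU_MAX)
    ipp0 = getattr(datasets[0][1], "ImagePositionPatient", (0.0, 0.0, 0.0))
    origin = (float(ipp0[2]), float(ipp0[1]), float(ipp0[0]))
    return CTVolume(voxels=voxels, spacing_mm=(slice_sp, row_sp, col_sp), origin_mm=origin)


# ---------------------------------------------------------------------------
# Public I/O
# ---------------------------------------------------------------------------

def read_volume(path: str | Path, format: str | None = None) -> CTVolume:
    """Read a CT volume in HU from a NIfTI file or a DICOM series directory.

    ``format`` may be ``"nifti"``, ``"dicom_dir"`` or ``None`` (inferred:
    directories are DICOM series, files are NIfTI). HU values are clamped to
    ``[-1024, 3100]``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    if format is None:
        format = "dicom_dir" if path.is_dir() else "nifti"
    if format == "nifti":
        return _read_nifti(path)
    if format == "dicom_dir":
        return _read_dicom_dir(path)
    raise ValueError(f"unknown format {format!r}")


def write_volume(volume: CTVolume, path: str | Path, format: str = "nifti") -> None:
    """Write a volume as NIfTI-1 (.nii / .nii.gz). Round-trip exact for
    integer HU grids."""
    if format != "nifti":
        raise ValueError("only NIfTI output is supported")
    _write_nifti(volume, Path(path))


# ---------------------------------------------------------------------------
# Coordinates
# ---------------------------------------------------------------------------

def index_to_world(volume: CTVolume | Mask, index: Sequence[int]) -> tuple[float, float, float]:
    """World coordinates (mm) of a voxel center."""
    idx = tuple(int(i) for i in index)
    shape = volume.shape
    if any(i < 0 or i >= n for i, n in zip(idx, shape)):
        raise IndexError(f"index {idx} out of range for shape {shape}")
    return tuple(
        o + i * s for o, i, s in zip(volume.origin_mm, idx, volume.spacing_mm)
    )  # type: ignore[return-value]


def world_to_index(volume: CTVolume | Mask, world: Sequence[float]) -> tuple[int, int, int]:
    """Nearest voxel index for a world point (mm)."""
    idx = tuple(
        int(round((w - o) / s))
        for w, o, s in zip(world, volume.origin_mm, volume.spacing_mm)
    )
    shape = volume.shape
    if any(i < 0 or i >= n for i, n in zip(idx, shape)):
        raise IndexError(f"world point {tuple(world)} maps outside the grid")
    return idx  # type: ignore[return-value]
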