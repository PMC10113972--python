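"""CT volume and mask containers plus NIfTI / DICOM-series I/O.

Conventions used throughout the package:

* voxel arrays are indexed ``(z, y, x)``, 0-based;
* ``spacing`` is ``(dz, dy, dx)`` in millimetres, all strictly positive;
* voxel values are Hounsfield units (HU) after any rescale has been applied.

NIfTI files are written with a diagonal affine ``diag(dx, dy, dz, 1)`` and the
data transposed to ``(x, y, z)`` on disk, which round-trips exactly through
:func:`load_ct` / :func:`save_ct`.  Orientation codes beyond voxel spacing are
deliberately ignored (no resampling is performed).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

from .errors import CalibrationError, FormatError, GeometryError

__all__ = [
    "CTVolume",
    "MaskVolume",
    "load_ct",
    "save_ct",
    "load_mask",
    "save_mask",
    "HU_MIN_PLAUSIBLE",
    "HU_MAX_PLAUSIBLE",
]

# Values outside this range indicate a DICOM whose rescale slope/intercept was
# never applied (stored values instead of HU) — a silent unit error we want to
# catch at load time rather than downstream.
HU_MIN_PLAUSIBLE = -1100.0
HU_MAX_PLAUSIBLE = 4000.0


def _validate_spacing(spacing) -> tuple[float, float, float]:
    spacing = tuple(float(s) for s in spacing)
    if len(spacing) != 3:
        raise GeometryError(f"spacing must have 3 components, got {len(spacing)}")
    if not all(np.isfinite(s) and s > 0 for s in spacing):
        raise GeometryError(f"spacing components must be finite and > 0, got {spacing}")
    return spacing


@dataclass(frozen=True)
class CTVolume:
    """A 3D grid of HU values with physical voxel spacing.

    Parameters
    ----------
    voxels : ndarray, shape (nz, ny, nx)
        HU values, float32.
    spacing : tuple of float
        ``(dz, dy, dx)`` in mm.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self):
        vox = np.asarray(self.voxels, dtype=np.float32)
        if vox.ndim != 3:
            raise GeometryError(f"CT voxels must be 3D, got ndim={vox.ndim}")
        if not np.all(np.isfinite(vox)):
            raise CalibrationError("CT contains non-finite values")
        lo, hi = float(vox.min()), float(vox.max())
        if lo < HU_MIN_PLAUSIBLE or hi > HU_MAX_PLAUSIBLE:
            raise CalibrationError(
                f"voxel range [{lo:.1f}, {hi:.1f}] outside plausible HU range "
                f"[{HU_MIN_PLAUSIBLE:.0f}, {HU_MAX_PLAUSIBLE:.0f}]; "
                "was the DICOM rescale applied?"
            )
        object.__setattr__(self, "voxels", vox)
        object.__setattr__(self, "spacing", _validate_spacing(self.spacing))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def voxel_volume_ml(self) -> float:
        dz, dy, dx = self.spacing
        return dz * dy * dx / 1000.0


@dataclass(frozen=True)
class MaskVolume:
    """A boolean mask on the same grid convention as :class:`CTVolume`."""

    voxels: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self):
        vox = np.asarray(self.voxels)
        if vox.ndim != 3:
            raise GeometryError(f"mask voxels must be 3D, got ndim={vox.ndim}")
        object.__setattr__(self, "voxels", vox.astype(bool))
        object.__setattr__(self, "spacing", _validate_spacing(self.spacing))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def voxel_volume_ml(self) -> float:
        dz, dy, dx = self.spacing
        return dz * dy * dx / 1000.0

    def check_grid(self, other) -> None:
        """Raise :class:`GeometryError` unless shape and spacing match ``other``."""
        if self.shape != other.shape:
            raise GeometryError(f"shape mismatch: {self.shape} vs {other.shape}")
        if not np.allclose(self.spacing, other.spacing, rtol=1e-5):
            raise GeometryError(f"spacing mismatch: {self.spacing} vs {other.spacing}")


def _nifti_load(path):
    try:
        img = nib.load(str(path))
    except FileNotFoundError:
        raise
    except Exception as exc:  # nibabel raises several unrelated types
        raise FormatError(f"cannot read NIfTI file {path}: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise GeometryError(f"{path}: expected a 3D volume, got shape {data.shape}")
    zooms = img.header.get_zooms()[:3]  # (dx, dy, dz) for our writer
    spacing = (float(zooms[2]), float(zooms[1]), float(zooms[0]))
    return np.transpose(data, (2, 1, 0)), spacing


def load_ct(path, format: str = "nifti") -> CTVolume:
    """Load a CT volume from a NIfTI file or a DICOM series directory.

    Parameters
    ----------
    path : str or Path
        NIfTI file (``format='nifti'``) or directory of DICOM slices
        (``format='dicom_dir'``).
    format : {'nifti', 'dicom_dir'}

    Returns
    -------
    CTVolume
        HU-calibrated volume; DICOM stored values are rescaled with the
        slope/intercept from each slice header and slices are sorted along
        the normal axis.
    """
    if format == "nifti":
        if not os.path.exists(path):
            raise FileNotFoundError(path)
        data, spacing = _nifti_load(path)
        return CTVolume(np.asarray(data, dtype=np.float32), spacing)
    if format == "dicom_dir":
        from ._dicom import read_dicom_series

        voxels, spacing = read_dicom_series(path)
        return CTVolume(voxels, spacing)
    raise FormatError(f"unknown format {format!r}; expected 'nifti' or 'dicom_dir'")


def save_ct(vol: CTVolume, path) -> None:
    """Write a CT volume as NIfTI (float32)."""
    data = np.transpose(vol.voxels.astype(np.float32), (2, 1, 0))
    dz, dy, dx = vol.spacing
    affine = np.diag([dx, dy, dz, 1.0])
    nib.save(nib.Nifti1Image(data, affine), str(path))


def save_mask(mask: MaskVolume, path) -> None:
    """Write a mask as a 0/1 uint8 NIfTI."""
    data = np.transpose(mask.voxels.astype(np.uint8), (2, 1, 0))
    dz, dy, dx = mask.spacing
    affine = np.diag([dx, dy, dz, 1.0])
    nib.save(nib.Nifti1Image(data, affine), str(path))


def load_mask(path, reference: CTVolume | MaskVolume | None = None) -> MaskVolume:
    """Load a mask NIfTI, binarizing values > 0.5.

    When ``reference`` is given the mask grid must match it exactly.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    data, spacing = _nifti_load(path)
    mask = MaskVolume(np.asarray(data, dtype=np.float64) > 0.5, spacing)
    if reference is not None:
        mask.check_grid(reference)
    return mask
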