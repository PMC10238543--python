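"""CT volume / mask I/O, geometry validation, and isotropic resampling.

Volumes are plain HU arrays with physical voxel spacing.  Axial slices
occupy the first two array axes (index order ``[y, x, z]``); all physical
geometry refers to voxel centers.  NIfTI is the primary on-disk format;
DICOM series directories are read-only.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage


class FormatError(ValueError):
    """Input file could not be parsed as the expected image format."""


class MetadataError(ValueError):
    """Image header lacks required geometric metadata."""


class DegenerateMaskError(ValueError):
    """Tumor mask became empty (e.g. after resampling)."""


@dataclass
class CTVolume:
    """Scalar CT volume in Hounsfield units with physical spacing.

    Parameters
    ----------
    voxels
        3D array, HU.  Axes are (y, x, z); z indexes axial slices.
    spacing
        (x, y, z) voxel spacing in mm; all components > 0.
    origin
        (x, y, z) position of voxel (0, 0, 0) in mm.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(f"expected a 3D volume, got ndim={self.voxels.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise MetadataError(f"spacing components must be > 0, got {self.spacing}")
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def pixel_size_mm(self) -> float:
        """In-plane pixel size; meaningful once x and y spacing agree."""
        sx, sy, _ = self.spacing
        if not np.isclose(sx, sy):
            raise ValueError(f"anisotropic in-plane spacing {sx} x {sy}; resample first")
        return sx


@dataclass
class TumorMask:
    """Binary tumor mask on the same grid as its CTVolume."""

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        arr = np.asarray(self.voxels)
        if arr.ndim != 3:
            raise ValueError(f"expected a 3D mask, got ndim={arr.ndim}")
        vals = np.unique(arr)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError(f"mask must be binary, found values {vals[:10]}")
        self.voxels = arr.astype(bool)
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise MetadataError(f"spacing components must be > 0, got {self.spacing}")
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def pixel_count(self) -> int:
        return int(self.voxels.sum())


def _check_same_grid(vol: CTVolume, mask: TumorMask) -> None:
    if vol.shape != mask.shape:
        raise ValueError(f"volume shape {vol.shape} != mask shape {mask.shape}")
    if not np.allclose(vol.spacing, mask.spacing):
        raise ValueError(f"volume spacing {vol.spacing} != mask spacing {mask.spacing}")


def _affine_from_geometry(spacing, origin) -> np.ndarray:
    # Array axes (y, x, z) -> world (x, y, z): NIfTI stores data as [x, y, z],
    # so we transpose on write and keep a diagonal affine.
    aff = np.diag([spacing[0], spacing[1], spacing[2], 1.0])
    aff[:3, 3] = origin
    return aff


def load_volume(path: str | os.PathLike, kind: str = "nifti") -> CTVolume:
    """Read a CT volume from disk.

    Parameters
    ----------
    path
        NIfTI file (``.nii``/``.nii.gz``) or, with ``kind='dicom-dir'``,
        a directory holding one DICOM series.
    kind
        ``'nifti'`` (default) or ``'dicom-dir'``.

    Returns
    -------
    CTVolume
        HU values exactly as stored; spacing from the header.
    """
    if kind == "nifti":
        voxels, spacing, origin = _load_nifti(path)
    elif kind == "dicom-dir":
        voxels, spacing, origin = _load_dicom_dir(path)
    else:
        raise ValueError(f"unknown kind {kind!r}; expected 'nifti' or 'dicom-dir'")
    return CTVolume(voxels=voxels, spacing=spacing, origin=origin)


def load_mask(path: str | os.PathLike, kind: str = "nifti") -> TumorMask:
    """Read a binary tumor mask; any nonzero voxel is foreground."""
    if kind != "nifti":
        raise ValueError("masks are read from NIfTI only")
    voxels, spacing, origin = _load_nifti(path)
    return TumorMask(voxels=(voxels > 0).astype(np.uint8), spacing=spacing, origin=origin)


def _load_nifti(path):
    import nibabel as nib

    try:
        img = nib.load(os.fspath(path))
        data = np.asarray(img.dataobj)
    except Exception as exc:  # nibabel raises several unrelated types
        raise FormatError(f"could not read {path} as NIfTI: {exc}") from exc
    if data.ndim != 3:
        raise FormatError(f"{path}: expected 3D data, got shape {data.shape}")
    zooms = img.header.get_zooms()[:3]
    if any(not np.isfinite(z) or z <= 0 for z in zooms):
        raise MetadataError(f"{path}: invalid voxel spacing {zooms}")
    origin = tuple(float(v) for v in img.affine[:3, 3])
    # stored [x, y, z] -> in-memory [y, x, z]
    return np.swapaxes(data, 0, 1), (float(zooms[0]), float(zooms[1]), float(zooms[2])), origin


def _load_dicom_dir(path):
    import pydicom

    files = sorted(
        os.path.join(path, f) for f in os.listdir(path)
        if not f.startswith(".")
    )
    slices = []
    for f in files:
        try:
            ds = pydicom.dcmread(f)
        except Exception as exc:
            raise FormatError(f"could not read {f} as DICOM: {exc}") from exc
        if hasattr(ds, "PixelData"):
            slices.append(ds)
    if not slices:
        raise FormatError(f"no DICOM images found in {path}")
    try:
        slices.sort(key=lambda ds: float(ds.ImagePositionPatient[2]))
        z0 = float(slices[0].ImagePositionPatient[2])
        px = [float(v) for v in slices[0].PixelSpacing]
        if len(slices) > 1:
            dz = float(slices[1].ImagePositionPatient[2]) - z0
        else:
            dz = float(getattr(slices[0], "SliceThickness", 0) or 0)
        origin = (float(slices[0].ImagePositionPatient[0]),
                  float(slices[0].ImagePositionPatient[1]), z0)
    except (AttributeError, IndexError, TypeError) as exc:
        raise MetadataError(f"{path}: missing DICOM geometry metadata: {exc}") from exc
    if dz <= 0:
        raise MetadataError(f"{path}: nonpositive slice spacing {dz}")
    vol = np.stack(
        [ds.pixel_array * float(getattr(ds, "RescaleSlope", 1))
         + float(getattr(ds, "RescaleIntercept", 0)) for ds in slices],
        axis=-1,
    )
    # pixel_array rows are y, columns x -> already [y, x, z]
    return vol.astype(np.float64), (px[1], px[0], dz), origin


def save_volume(obj: CTVolume | TumorMask, path: str | os.PathLike) -> None:
    """Write a volume or mask as NIfTI, preserving spacing and origin."""
    import nibabel as nib

    data = np.swapaxes(np.asarray(obj.voxels), 0, 1)
    if data.dtype == bool:
        data = data.astype(np.uint8)
    img = nib.Nifti1Image(data, _affine_from_geometry(obj.spacing, obj.origin))
    img.header.set_zooms(obj.spacing)
    nib.save(img, os.fspath(path))


def resample_isotropic(
    vol: CTVolume, mask: TumorMask, target_mm: float = 1.0
) -> tuple[CTVolume, TumorMask]:
    """Resample an image/mask pair to an isotropic grid.

    The image is interpolated linearly, the mask with nearest-neighbor and
    re-binarized, so labels never blur into fractional values.  Physical
    extent is preserved to within one voxel.

    Parameters
    ----------
    target_mm
        Isotropic voxel edge length of the output grid (default 1 mm, the
        working resolution of the downstream texture analysis).

    Raises
    ------
    DegenerateMaskError
        If the mask is empty after resampling.
    """
    _check_same_grid(vol, mask)
    if target_mm <= 0:
        raise ValueError(f"target_mm must be > 0, got {target_mm}")
    sx, sy, sz = vol.spacing
    # array axes (y, x, z) scale by (sy, sx, sz) / target
    factors = (sy / target_mm, sx / target_mm, sz / target_mm)
    if np.allclose(factors, 1.0):
        return (replace(vol), TumorMask(mask.voxels.copy(), mask.spacing, mask.origin))
    new_vox = ndimage.zoom(np.asarray(vol.voxels, dtype=np.float64), factors, order=1,
                           mode="nearest", grid_mode=True)
    new_mask = ndimage.zoom(mask.voxels.astype(np.uint8), factors, order=0,
                            mode="nearest", grid_mode=True)
    new_spacing = (target_mm, target_mm, target_mm)
    out_mask = TumorMask(new_mask > 0, new_spacing, mask.origin)
    if out_mask.pixel_count() == 0:
        raise DegenerateMaskError("tumor mask is empty after resampling")
    return CTVolume(new_vox, new_spacing, vol.origin), out_mask


def validate_tumor_size(mask: TumorMask, min_pixels: int = 200) -> bool:
    """Inclusion check: the tumor must contain at least ``min_pixels`` voxels.

    Cases below the threshold are too small for stable texture statistics
    and are excluded from the analysis.
    """
    return mask.pixel_count() >= min_pixels
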