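"""Reading and writing density volumes and masks (MetaImage / NIfTI).

SimpleITK handles the on-disk formats.  SimpleITK's array view is indexed
(z, y, x), which matches this package's (axial, coronal, sagittal) axis
convention directly.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import SimpleITK as sitk

from .volume import CompartmentMask, DensityVolume

_FORMAT_EXTENSIONS = {
    "metaimage": (".mha", ".mhd"),
    "nifti": (".nii", ".nii.gz"),
}

#: Relative tolerance on voxel-spacing anisotropy before a warning is issued.
ANISOTROPY_TOLERANCE = 1e-3


def _infer_format(path: Path) -> str:
    name = path.name.lower()
    for fmt, exts in _FORMAT_EXTENSIONS.items():
        if any(name.endswith(ext) for ext in exts):
            return fmt
    raise ValueError(
        f"cannot infer volume format from {path.name!r}; expected one of "
        f"{sum(_FORMAT_EXTENSIONS.values(), ())}"
    )


def _check_format(path: Path, format: str | None) -> str:
    inferred = _infer_format(path)
    if format is not None and format != inferred:
        raise ValueError(
            f"requested format {format!r} does not match extension of {path.name!r}"
        )
    return inferred


def _read_image(path: str | Path, format: str | None) -> tuple[np.ndarray, float]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    _check_format(path, format)
    image = sitk.ReadImage(str(path))
    if image.GetDimension() != 3:
        raise ValueError(
            f"{path.name!r} is a {image.GetDimension()}-D image; a 3D volume is required"
        )
    spacing = image.GetSpacing()
    if (max(spacing) - min(spacing)) / max(spacing) > ANISOTROPY_TOLERANCE:
        warnings.warn(
            f"anisotropic voxels {spacing} in {path.name!r}; using mean spacing",
            stacklevel=3,
        )
    arr = sitk.GetArrayFromImage(image)  # (z, y, x) == (axial, coronal, sagittal)
    return np.asarray(arr), float(np.mean(spacing))


def _write_image(
    voxels: np.ndarray, voxel_size_mm: float, path: str | Path, format: str | None
) -> None:
    path = Path(path)
    _check_format(path, format)
    image = sitk.GetImageFromArray(np.ascontiguousarray(voxels))
    image.SetSpacing((voxel_size_mm,) * 3)
    sitk.WriteImage(image, str(path))


def read_volume(path: str | Path, format: str | None = None) -> DensityVolume:
    """Read a 3D density volume; ``format`` is 'metaimage', 'nifti' or inferred."""
    arr, spacing = _read_image(path, format)
    return DensityVolume(
        arr.astype(np.float64), voxel_size_mm=spacing, name=Path(path).stem
    )


def write_volume(
    vol: DensityVolume, path: str | Path, format: str | None = None
) -> None:
    """Write a density volume; round-trips bit-exactly at float64 precision."""
    _write_image(vol.voxels.astype(np.float64), vol.voxel_size_mm, path, format)


def read_mask(
    path: str | Path, format: str | None = None, label: str = "bone"
) -> CompartmentMask:
    """Read a binary mask; any nonzero stored value maps to 1."""
    arr, spacing = _read_image(path, format)
    return CompartmentMask((arr != 0).astype(np.uint8), label, spacing)


def write_mask(
    mask: CompartmentMask, path: str | Path, format: str | None = None
) -> None:
    _write_image(mask.voxels.astype(np.uint8), mask.voxel_size_mm, path, format)


def calibrate_native_to_density(
    raw: np.ndarray,
    slope: float,
    intercept: float,
    voxel_size_mm: float = 0.0607,
    name: str = "",
) -> DensityVolume:
    """Affine calibration of native scanner units to densities (mg HA/cm^3).

    The scanner's calibration constants vary by device and protocol, so they
    are always explicit arguments: density = raw * slope + intercept.
    """
    if slope == 0:
        raise ValueError("calibration slope must be nonzero")
    raw = np.asarray(raw, dtype=np.float64)
    return DensityVolume(raw * slope + intercept, voxel_size_mm, name)
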