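"""Core in-memory containers for HR-pQCT volumes and segmentations.

Axis convention throughout the package: axis 0 is the axial (slice) axis,
axis 1 is coronal, axis 2 is sagittal.  All grids are rank-3 NumPy arrays.
Densities are calibrated to mg HA/cm^3; the nominal HR-pQCT voxel size is
0.0607 mm isotropic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Nominal second-generation HR-pQCT isotropic voxel size, mm.
DEFAULT_VOXEL_SIZE_MM = 0.0607

MASK_LABELS = ("cortical", "trabecular", "bone", "background")


def _require_rank3(voxels: np.ndarray, what: str) -> np.ndarray:
    arr = np.asarray(voxels)
    if arr.ndim != 3:
        raise ValueError(f"{what} must be a rank-3 grid, got shape {arr.shape}")
    if min(arr.shape) < 1:
        raise ValueError(f"{what} must have all extents >= 1, got {arr.shape}")
    return arr


@dataclass
class DensityVolume:
    """A calibrated density volume (mg HA/cm^3) on an isotropic grid."""

    voxels: np.ndarray
    voxel_size_mm: float = DEFAULT_VOXEL_SIZE_MM
    name: str = ""

    def __post_init__(self) -> None:
        self.voxels = _require_rank3(self.voxels, "DensityVolume.voxels").astype(
            np.float64, copy=False
        )
        if not self.voxel_size_mm > 0:
            raise ValueError(f"voxel_size_mm must be > 0, got {self.voxel_size_mm}")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("DensityVolume densities must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[0]


@dataclass
class NormalizedVolume:
    """A density volume standardized to the unitless interval [-1, 1]."""

    voxels: np.ndarray
    voxel_size_mm: float = DEFAULT_VOXEL_SIZE_MM

    def __post_init__(self) -> None:
        self.voxels = _require_rank3(self.voxels, "NormalizedVolume.voxels").astype(
            np.float64, copy=False
        )
        lo, hi = float(self.voxels.min()), float(self.voxels.max())
        if lo < -1 - 1e-9 or hi > 1 + 1e-9:
            raise ValueError(
                f"NormalizedVolume values must lie in [-1, 1], got [{lo}, {hi}]"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[0]


@dataclass
class CompartmentMask:
    """A binary mask for one compartment on a volume grid."""

    voxels: np.ndarray
    label: str = "bone"
    voxel_size_mm: float = DEFAULT_VOXEL_SIZE_MM

    def __post_init__(self) -> None:
        arr = _require_rank3(self.voxels, "CompartmentMask.voxels")
        vals = np.unique(arr)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError("CompartmentMask values must be in {0, 1}")
        self.voxels = arr.astype(bool)
        if self.label not in MASK_LABELS:
            raise ValueError(f"label must be one of {MASK_LABELS}, got {self.label!r}")
        if not self.voxel_size_mm > 0:
            raise ValueError(f"voxel_size_mm must be > 0, got {self.voxel_size_mm}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape


@dataclass
class SegmentationPair:
    """Disjoint cortical and trabecular masks on a shared grid."""

    cortical: CompartmentMask
    trabecular: CompartmentMask

    def __post_init__(self) -> None:
        if self.cortical.shape != self.trabecular.shape:
            raise ValueError(
                "cortical and trabecular masks must share a shape, got "
                f"{self.cortical.shape} vs {self.trabecular.shape}"
            )
        if np.any(self.cortical.voxels & self.trabecular.voxels):
            raise ValueError("cortical and trabecular masks must be disjoint")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.cortical.shape

    @property
    def bone(self) -> np.ndarray:
        """Union of cortical and trabecular compartments."""
        return self.cortical.voxels | self.trabecular.voxels

    @property
    def background(self) -> np.ndarray:
        return ~self.bone

    @classmethod
    def from_arrays(
        cls,
        cortical: np.ndarray,
        trabecular: np.ndarray,
        voxel_size_mm: float = DEFAULT_VOXEL_SIZE_MM,
    ) -> "SegmentationPair":
        return cls(
            cortical=CompartmentMask(cortical, "cortical", voxel_size_mm),
            trabecular=CompartmentMask(trabecular, "trabecular", voxel_size_mm),
        )
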