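"""Pre-processing: in-plane padding, density standardization, slice stacking.

The standardization is a truncated linear map of calibrated densities from
[-400, 1400] mg HA/cm^3 onto the unitless interval [-1, 1]:

    rho' = min(max(rho, -400), 1400)
    rho_bar = (2 * rho' - 1000) / 1800

so that -400 -> -1, 500 -> 0, 1400 -> +1 and the classical 275 mg HA/cm^3
bone threshold lands at -0.25.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .volume import CompartmentMask, DensityVolume, NormalizedVolume

#: Truncation floor/ceiling of the density standardization, mg HA/cm^3.
DENSITY_FLOOR = -400.0
DENSITY_CEIL = 1400.0
#: In-plane extents are padded up to a common multiple of this.
PAD_MULTIPLE = 8
#: Number of adjacent axial slices stacked as network input channels.
N_INPUT_SLICES = 5


def padded_extent(coronal: int, sagittal: int, multiple: int = PAD_MULTIPLE) -> int:
    """Smallest multiple of ``multiple`` that covers both in-plane extents."""
    m = max(coronal, sagittal)
    return -(-m // multiple) * multiple


def _pad_widths(extent: int, target: int) -> tuple[int, int]:
    total = target - extent
    lo = total // 2
    return lo, total - lo  # extra voxel goes on the high side


def pad_in_plane(
    vol: DensityVolume | CompartmentMask, multiple: int = PAD_MULTIPLE
) -> DensityVolume | CompartmentMask:
    """Pad coronal and sagittal extents to one common multiple of eight.

    Densities are padded with the truncation floor (-400 mg HA/cm^3), which
    standardizes to -1 and reads as background; masks are padded with 0.  The
    original content is centered, the extra voxel on the high side when a pad
    width is odd.  The axial extent is unchanged.
    """
    _, cor, sag = vol.voxels.shape
    target = padded_extent(cor, sag, multiple)
    widths = ((0, 0), _pad_widths(cor, target), _pad_widths(sag, target))
    if isinstance(vol, CompartmentMask):
        padded = np.pad(vol.voxels, widths, constant_values=False)
        return CompartmentMask(padded.astype(np.uint8), vol.label, vol.voxel_size_mm)
    padded = np.pad(vol.voxels, widths, constant_values=DENSITY_FLOOR)
    return DensityVolume(padded, vol.voxel_size_mm, vol.name)


def crop_in_plane(voxels: np.ndarray, original_shape: tuple[int, int, int]) -> np.ndarray:
    """Inverse of :func:`pad_in_plane` for an array padded from ``original_shape``."""
    _, cor, sag = original_shape
    target = voxels.shape[1]
    lo_c, _ = _pad_widths(cor, target)
    lo_s, _ = _pad_widths(sag, voxels.shape[2])
    return voxels[:, lo_c : lo_c + cor, lo_s : lo_s + sag]


def standardize_array(rho: np.ndarray) -> np.ndarray:
    rho_prime = np.clip(rho, DENSITY_FLOOR, DENSITY_CEIL)
    return (2.0 * rho_prime - 1000.0) / 1800.0


def standardize(vol: DensityVolume) -> NormalizedVolume:
    """Truncate densities to [-400, 1400] and rescale to [-1, 1]."""
    return NormalizedVolume(standardize_array(vol.voxels), vol.voxel_size_mm)


def destandardize(nv: NormalizedVolume) -> DensityVolume:
    """Exact inverse of :func:`standardize` on the non-truncated range."""
    rho_bar = nv.voxels
    if rho_bar.min() < -1 - 1e-9 or rho_bar.max() > 1 + 1e-9:
        raise ValueError("destandardize expects values in [-1, 1]")
    return DensityVolume((1800.0 * rho_bar + 1000.0) / 2.0, nv.voxel_size_mm)


def reflect_index(i: int, n: int) -> int:
    """Mirror index ``i`` into [0, n) without repeating the boundary sample.

    NumPy 'reflect' convention: -1 -> 1, -2 -> 2, n -> n-2, n+1 -> n-3.
    """
    if n == 1:
        return 0
    period = 2 * (n - 1)
    i = i % period
    return i if i < n else period - i


def stack_indices(center_index: int, n_slices: int, width: int = N_INPUT_SLICES) -> list[int]:
    half = width // 2
    return [reflect_index(center_index + d, n_slices) for d in range(-half, half + 1)]


@dataclass
class SliceStack:
    """Five adjacent axial slices stacked on the channel dimension."""

    slices: np.ndarray  # (5, H, W)
    center_index: int

    def __post_init__(self) -> None:
        self.slices = np.asarray(self.slices, dtype=np.float64)
        if self.slices.ndim != 3 or self.slices.shape[0] != N_INPUT_SLICES:
            raise ValueError(
                f"SliceStack requires exactly {N_INPUT_SLICES} slices, got shape "
                f"{self.slices.shape}"
            )
        h, w = self.slices.shape[1:]
        if h % PAD_MULTIPLE or w % PAD_MULTIPLE:
            raise ValueError(
                f"SliceStack in-plane dims must be multiples of {PAD_MULTIPLE}, "
                f"got {h}x{w}; pad the volume first"
            )


def make_slice_stack(nv: NormalizedVolume, center_index: int) -> SliceStack:
    """Extract the 5-slice stack centered on ``center_index``.

    Out-of-range neighbors near the proximal/distal ends are filled by
    mirror reflection about the boundary (the edge slice is not repeated).
    """
    n = nv.n_slices
    if not 0 <= center_index < n:
        raise IndexError(f"center_index {center_index} out of range [0, {n})")
    if n < 3:
        raise ValueError("slice stacking requires at least 3 axial slices")
    idx = stack_indices(center_index, n)
    return SliceStack(nv.voxels[idx], center_index)
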