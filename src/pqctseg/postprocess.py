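"""Morphological post-processing of raw U-Net segmentations.

Three filters enforce the topology expected of a distal radius/tibia
segmentation — one connected region per compartment, no background gaps
between compartments, and a continuous cortical shell of configurable
minimum thickness around the trabecular compartment:

* the iterative binary segmentation filter, an alternating sequential
  open-close with Euclidean-ball structuring elements of radius r = 1..max
  (open max 5, close max 15 for U-Net masks; 3/15 for the density-derived
  bone mask), keeping only the largest foreground component inside each
  open and the largest background component (i.e. filling detached
  cavities) inside each close;
* the minimum cortical shell filter: the trabecular mask dilated by 8
  voxels (~0.5 mm at 60.7 um) minus the trabecular mask itself;
* the morphological bone mask filter: threshold the standardized image at
  -0.25 (275 mg HA/cm^3), median-filter with a 3x3x1 (sagittal, coronal,
  axial) kernel, then apply the iterative filter — a rough whole-bone mask
  that guards against catastrophic misses by the network.

Ball erosions and dilations are computed through exact Euclidean distance
transforms, which is equivalent to ball-footprint morphology; the volume
boundary is treated as edge-replicated, so structures running off the
axial ends of the scan are not eroded there.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volume import CompartmentMask, NormalizedVolume, SegmentationPair

#: 26-connectivity for foreground components, 6-connectivity for background
#: (the standard complementary pair).
_FG_STRUCTURE = np.ones((3, 3, 3), dtype=bool)
_BG_STRUCTURE = ndimage.generate_binary_structure(3, 1)


@dataclass
class PostprocessParams:
    open_max_radius_unet: int = 5
    close_max_radius_unet: int = 15
    open_max_radius_bone: int = 3
    close_max_radius_bone: int = 15
    shell_thickness: int = 8
    bone_threshold_normalized: float = -0.25
    median_kernel: tuple[int, int, int] = (3, 3, 1)  # (sagittal, coronal, axial)

    def __post_init__(self) -> None:
        for name in (
            "open_max_radius_unet",
            "close_max_radius_unet",
            "open_max_radius_bone",
            "close_max_radius_bone",
            "shell_thickness",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not -1 <= self.bone_threshold_normalized <= 1:
            raise ValueError("bone_threshold_normalized must be in [-1, 1]")


# ---------------------------------------------------------------------------
# Euclidean-ball morphology via exact distance transforms
# ---------------------------------------------------------------------------

def dilate_ball(mask: np.ndarray, radius: int) -> np.ndarray:
    """Binary dilation by a Euclidean ball of the given voxel radius."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return mask.copy()
    if mask.all():
        return mask.copy()
    return ndimage.distance_transform_edt(~mask) <= radius


def erode_ball(mask: np.ndarray, radius: int) -> np.ndarray:
    """Binary erosion by a Euclidean ball (volume border treated as foreground)."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return mask.copy()
    if mask.all():
        return mask.copy()
    return ndimage.distance_transform_edt(mask) > radius


def largest_component(mask: np.ndarray, structure: np.ndarray = _FG_STRUCTURE) -> np.ndarray:
    """Largest connected component of a binary mask (empty in, empty out)."""
    labels, n = ndimage.label(mask, structure=structure)
    if n == 0:
        return np.zeros_like(mask, dtype=bool)
    counts = np.bincount(labels.ravel())[1:]
    return labels == (int(np.argmax(counts)) + 1)


def fill_detached_background(mask: np.ndarray) -> np.ndarray:
    """Keep only the largest background component; fill all the others."""
    background = ~np.asarray(mask, dtype=bool)
    keep = largest_component(background, structure=_BG_STRUCTURE)
    return ~keep


# ---------------------------------------------------------------------------
# the three filters
# ---------------------------------------------------------------------------

def iterative_binary_segmentation_filter(
    mask: CompartmentMask | np.ndarray, open_max: int, close_max: int
) -> CompartmentMask | np.ndarray:
    """Alternating sequential filter with connectivity steps, radii 1..max.

    For each radius r: if r <= open_max, an open (erode, keep largest
    foreground component, dilate); if r <= close_max, a close (dilate, fill
    all but the largest background component, erode).  Removes union and
    subtractive noise and excludes any secondary bone from the mask.
    """
    as_mask = isinstance(mask, CompartmentMask)
    m = mask.voxels.copy() if as_mask else np.asarray(mask, dtype=bool).copy()
    if not m.any():
        return mask if as_mask else m
    for radius in range(1, max(open_max, close_max) + 1):
        if radius <= open_max:
            m = erode_ball(m, radius)
            if not m.any():
                warnings.warn(
                    f"mask emptied by the radius-{radius} erosion; returning empty",
                    stacklevel=2,
                )
                m = np.zeros_like(m)
                break
            m = largest_component(m)
            m = dilate_ball(m, radius)
        if radius <= close_max:
            m = dilate_ball(m, radius)
            m = fill_detached_background(m)
            m = erode_ball(m, radius)
    if as_mask:
        return CompartmentMask(m.astype(np.uint8), mask.label, mask.voxel_size_mm)
    return m


def minimum_cortical_shell_filter(
    trab: CompartmentMask | np.ndarray, shell_thickness: int = 8
) -> CompartmentMask | np.ndarray:
    """Shell of ``shell_thickness`` voxels around the trabecular compartment.

    The trabecular mask is dilated by the shell thickness (8 voxels is about
    0.5 mm) and the original mask subtracted, leaving a cortical shell that
    is disjoint from the trabecular mask by construction.
    """
    as_mask = isinstance(trab, CompartmentMask)
    t = trab.voxels if as_mask else np.asarray(trab, dtype=bool)
    shell = dilate_ball(t, shell_thickness) & ~t
    if as_mask:
        return CompartmentMask(shell.astype(np.uint8), "cortical", trab.voxel_size_mm)
    return shell


def morphological_bone_mask_filter(
    nv: NormalizedVolume, params: PostprocessParams | None = None
) -> CompartmentMask:
    """Density-derived whole-bone mask (first step of dual thresholding).

    Threshold the standardized image at -0.25, median-filter with the
    3x3x1 (sagittal, coronal, axial) kernel, then run the iterative binary
    segmentation filter with open/close radii 3/15.
    """
    params = params or PostprocessParams()
    binarized = nv.voxels >= params.bone_threshold_normalized
    # median_kernel is (sagittal, coronal, axial); array axes are
    # (axial, coronal, sagittal)
    size = tuple(reversed(params.median_kernel))
    filtered = ndimage.median_filter(binarized.astype(np.uint8), size=size) > 0
    bone = iterative_binary_segmentation_filter(
        filtered, params.open_max_radius_bone, params.close_max_radius_bone
    )
    if not bone.any():
        warnings.warn(
            "morphological bone mask is empty - possible catastrophic miss",
            stacklevel=2,
        )
    return CompartmentMask(bone.astype(np.uint8), "bone", nv.voxel_size_mm)


def postprocess_segmentation(
    nv: NormalizedVolume,
    raw: SegmentationPair,
    params: PostprocessParams | None = None,
) -> SegmentationPair:
    """Full post-processing of a raw U-Net segmentation.

    1. filter the raw trabecular mask (iterative filter, radii 5/15);
    2. build the minimum cortical shell around it (8 voxels);
    3. filter the raw whole-bone mask (cortical | trabecular, radii 5/15);
    4. build the density-derived morphological bone mask;
    5. union 1-4 into the final bone mask;
    6. final cortical = bone minus filtered trabecular; final trabecular =
       filtered trabecular.

    Guarantees disjoint masks, a >= 8-voxel cortical separation of the
    trabecular compartment from the background, and (on anatomies like the
    distal radius/tibia) a single connected component per compartment.
    """
    params = params or PostprocessParams()
    if nv.shape != raw.shape:
        raise ValueError(f"volume shape {nv.shape} != segmentation shape {raw.shape}")
    trab_f = iterative_binary_segmentation_filter(
        raw.trabecular.voxels, params.open_max_radius_unet, params.close_max_radius_unet
    )
    shell = minimum_cortical_shell_filter(trab_f, params.shell_thickness)
    bone_u = iterative_binary_segmentation_filter(
        raw.bone, params.open_max_radius_unet, params.close_max_radius_unet
    )
    bone_m = morphological_bone_mask_filter(nv, params).voxels
    bone_f = bone_u | bone_m | trab_f | shell
    if not bone_f.any():
        raise ValueError("empty bone mask after post-processing: possible failed segmentation")
    cortical_final = bone_f & ~trab_f
    return SegmentationPair.from_arrays(
        cortical_final.astype(np.uint8),
        trab_f.astype(np.uint8),
        voxel_size_mm=raw.cortical.voxel_size_mm,
    )
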