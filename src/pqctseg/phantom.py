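"""Synthetic HR-pQCT-like phantoms with exact ground truth.

A phantom emulates a distal radius/tibia cross-section: a high-density
cortical annulus (~900 mg HA/cm^3) around a lower-density textured
trabecular interior (mean ~200 mg HA/cm^3), in a near-zero-density
background, with optional cortical pores, an optional secondary bone
(ulna/fibula stand-in) near the image edge, additive Gaussian noise, and a
slow axial drift of the bone center.  Because the geometry is analytic
(per-slice circles), the ground-truth compartment masks and the exact
Euclidean signed-distance embeddings of the endosteal and periosteal
surfaces are known in closed form.

The generator also produces repeat-scan pairs (same anatomy, rigid in-plane
repositioning, fresh noise) and implements the participant-level stratified
split (per-study quartiles of minimum total BMD, 70/15/15 by default).

What the phantom does not emulate: real plate-and-rod trabecular
microarchitecture, beam hardening, or scanner noise physics.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .preprocess import DENSITY_CEIL, DENSITY_FLOOR
from .volume import DEFAULT_VOXEL_SIZE_MM, DensityVolume, SegmentationPair

#: Internal texture model: strut density and volume fraction of the
#: trabecular interior; the marrow density is solved so the interior mean
#: equals the requested trabecular mean density.
STRUT_DENSITY = 450.0
STRUT_FRACTION = 0.3


@dataclass
class PhantomSpec:
    n_slices: int = 16
    in_plane: int = 160
    voxel_size_mm: float = DEFAULT_VOXEL_SIZE_MM
    outer_radius_mm: float = 3.5
    cortical_thickness_mm: float = 0.8
    cortical_density: float = 900.0
    trabecular_mean_density: float = 200.0
    trabecular_texture_scale_mm: float = 0.5
    pore_count: int = 0
    pore_radius_mm: float = 0.12
    noise_sd: float = 50.0
    secondary_bone: bool = False
    secondary_radius_mm: float = 0.6
    drift_per_slice_mm: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.cortical_thickness_mm < self.outer_radius_mm:
            raise ValueError("need 0 < cortical_thickness_mm < outer_radius_mm")
        if self.n_slices < 3:
            raise ValueError("n_slices must be >= 3")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class RigidTransform:
    """In-plane rigid repositioning: rotation about the grid center, then shift."""

    dy_mm: float = 0.0
    dx_mm: float = 0.0
    rotation_deg: float = 0.0


@dataclass
class PhantomSample:
    volume: DensityVolume
    truth: SegmentationPair
    endo_sdf: np.ndarray  # voxel units, negative inside the endosteal surface
    peri_sdf: np.ndarray  # voxel units, negative inside the periosteal surface
    spec: PhantomSpec


def _slice_centers(spec: PhantomSpec, transform: RigidTransform) -> np.ndarray:
    """Per-slice bone center (row, col) in voxel coordinates."""
    mid = (spec.in_plane - 1) / 2.0
    drift_vox = spec.drift_per_slice_mm / spec.voxel_size_mm
    k = np.arange(spec.n_slices) - (spec.n_slices - 1) / 2.0
    direction = np.array([1.0, 1.0]) / np.sqrt(2.0)
    centers = mid + k[:, None] * drift_vox * direction[None, :]
    theta = np.deg2rad(transform.rotation_deg)
    rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
    centers = (centers - mid) @ rot.T + mid
    shift = np.array([transform.dy_mm, transform.dx_mm]) / spec.voxel_size_mm
    return centers + shift[None, :]


def _check_geometry(spec: PhantomSpec, centers: np.ndarray) -> None:
    r_vox = spec.outer_radius_mm / spec.voxel_size_mm
    lo = centers.min() - r_vox
    hi = centers.max() + r_vox
    if lo < 0 or hi > spec.in_plane - 1:
        raise ValueError(
            f"phantom geometry exceeds the {spec.in_plane}^2 grid "
            f"(bone spans voxels [{lo:.1f}, {hi:.1f}])"
        )


def _texture_field(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Band-limited strut/marrow texture covering the whole grid (noiseless)."""
    raw = rng.standard_normal((spec.n_slices, spec.in_plane, spec.in_plane))
    sigma_vox = spec.trabecular_texture_scale_mm / spec.voxel_size_mm / 2.0
    smooth = ndimage.gaussian_filter(raw, sigma=(0, sigma_vox, sigma_vox))
    cut = np.quantile(smooth, 1.0 - STRUT_FRACTION)
    struts = smooth >= cut
    marrow_density = (
        spec.trabecular_mean_density - STRUT_FRACTION * STRUT_DENSITY
    ) / (1.0 - STRUT_FRACTION)
    return np.where(struts, STRUT_DENSITY, marrow_density)


def _render(
    spec: PhantomSpec,
    transform: RigidTransform,
    texture: np.ndarray,
    pore_params: np.ndarray,
    noise_rng: np.random.Generator,
) -> PhantomSample:
    centers = _slice_centers(spec, transform)
    _check_geometry(spec, centers)
    vs = spec.voxel_size_mm
    r_outer = spec.outer_radius_mm / vs
    r_inner = r_outer - spec.cortical_thickness_mm / vs
    rows = np.arange(spec.in_plane, dtype=float)
    yy, xx = np.meshgrid(rows, rows, indexing="ij")

    peri_sdf = np.empty((spec.n_slices, spec.in_plane, spec.in_plane))
    endo_sdf = np.empty_like(peri_sdf)
    for k in range(spec.n_slices):
        dist = np.hypot(yy - centers[k, 0], xx - centers[k, 1])
        peri_sdf[k] = dist - r_outer
        endo_sdf[k] = dist - r_inner
    trabecular = endo_sdf < 0
    cortical = (endo_sdf >= 0) & (peri_sdf < 0)

    # move the texture field with the anatomy (inverse in-plane transform)
    if transform.dy_mm or transform.dx_mm or transform.rotation_deg:
        mid = (spec.in_plane - 1) / 2.0
        theta = np.deg2rad(transform.rotation_deg)
        rot = np.array(
            [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
        )
        shift = np.array([transform.dy_mm, transform.dx_mm]) / vs
        inv = rot.T  # inverse rotation
        matrix = np.zeros((3, 3))
        matrix[0, 0] = 1.0
        matrix[1:, 1:] = inv
        offset = np.zeros(3)
        # x_src = inv @ (x_dst - mid - shift) + mid
        offset[1:] = mid - inv @ (mid + shift)
        texture = ndimage.affine_transform(
            texture, matrix, offset=offset, order=1, mode="nearest"
        )

    density = np.zeros_like(peri_sdf)
    density[cortical] = spec.cortical_density
    density[trabecular] = texture[trabecular]

    # cortical pores: low-density spheres at mid-cortex (still labelled cortical)
    for angle, z_frac in pore_params:
        k0 = z_frac * (spec.n_slices - 1)
        r_mid = (r_outer + r_inner) / 2.0
        kc = int(round(k0))
        cy = centers[kc, 0] + r_mid * np.sin(angle)
        cx = centers[kc, 1] + r_mid * np.cos(angle)
        r_pore = spec.pore_radius_mm / vs
        zz = np.arange(spec.n_slices, dtype=float)[:, None, None]
        pore = (
            (zz - k0) ** 2 + (yy[None] - cy) ** 2 + (xx[None] - cx) ** 2
        ) <= r_pore**2
        density[pore & cortical] = spec.trabecular_mean_density

    if spec.secondary_bone:
        margin = 2.0
        r2 = spec.secondary_radius_mm / vs
        cy2 = r2 + margin
        cx2 = r2 + margin
        dist2 = np.hypot(yy - cy2, xx - cx2)
        ring2 = (dist2 < r2) & (dist2 >= r2 - spec.cortical_thickness_mm / vs)
        interior2 = dist2 < r2 - spec.cortical_thickness_mm / vs
        sec = np.zeros_like(density, dtype=bool)
        density[:, ring2] = spec.cortical_density
        density[:, interior2] = spec.trabecular_mean_density
        sec[:, ring2 | interior2] = True
        if np.any(sec & (cortical | trabecular)):
            raise ValueError("secondary bone overlaps the primary bone")

    if spec.noise_sd > 0:
        density = density + noise_rng.normal(0.0, spec.noise_sd, density.shape)
    density = np.clip(density, DENSITY_FLOOR, DENSITY_CEIL)

    volume = DensityVolume(density, vs, name=f"phantom_seed{spec.seed}")
    truth = SegmentationPair.from_arrays(
        cortical.astype(np.uint8), trabecular.astype(np.uint8), vs
    )
    return PhantomSample(volume, truth, endo_sdf, peri_sdf, spec)


def _pore_params(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    if spec.pore_count == 0:
        return np.empty((0, 2))
    angles = rng.uniform(0, 2 * np.pi, spec.pore_count)
    z = rng.uniform(0.15, 0.85, spec.pore_count)
    return np.column_stack([angles, z])


def generate_phantom(spec: PhantomSpec) -> PhantomSample:
    """Generate one phantom; the seed fixes all randomness bit-exactly."""
    rng = np.random.default_rng(spec.seed)
    texture = _texture_field(spec, rng)
    pores = _pore_params(spec, rng)
    noise_rng = np.random.default_rng(rng.integers(2**31))
    return _render(spec, RigidTransform(), texture, pores, noise_rng)


def generate_repeat_pair(
    spec: PhantomSpec,
    repositioning_mm: tuple[float, float] = (0.2, -0.15),
    rotation_deg: float = 2.0,
    fresh_noise: bool = True,
) -> tuple[PhantomSample, PhantomSample, RigidTransform]:
    """Same anatomy twice: identity scan and a rigidly repositioned rescan.

    The second sample shares the texture (anatomy) but is displaced by the
    returned transform and, unless ``fresh_noise`` is disabled, receives an
    independent noise realization.  The true transform is returned for
    common-volume evaluation.
    """
    rng = np.random.default_rng(spec.seed)
    texture = _texture_field(spec, rng)
    pores = _pore_params(spec, rng)
    noise_seed = int(rng.integers(2**31))
    transform = RigidTransform(
        dy_mm=repositioning_mm[0], dx_mm=repositioning_mm[1], rotation_deg=rotation_deg
    )
    first = _render(
        spec, RigidTransform(), texture, pores, np.random.default_rng(noise_seed)
    )
    second_noise = (
        np.random.default_rng(noise_seed + 1) if fresh_noise
        else np.random.default_rng(noise_seed)
    )
    second = _render(spec, transform, texture, pores, second_noise)
    return first, second, transform


def desk_scale_spec(**overrides) -> PhantomSpec:
    """A reduced phantom for desk-scale (single-CPU) experiments.

    A 12-slice, 96^2 grid with a 1.4 mm outer radius and 0.6 mm cortex keeps
    the bone clear of the radius-15 closing's border effects (erosion treats
    the grid border as foreground, so a closing needs >= 15 voxels of
    background margin around the bone) while every filter radius and
    threshold stays at its full-scale value.
    """
    spec = dict(
        n_slices=12,
        in_plane=96,
        outer_radius_mm=1.4,
        cortical_thickness_mm=0.6,
    )
    spec.update(overrides)
    return PhantomSpec(**spec)


def generate_cohort(
    n: int,
    seed: int = 0,
    base_spec: PhantomSpec | None = None,
    radius_range_mm: tuple[float, float] = (1.2, 1.6),
    thickness_range_mm: tuple[float, float] = (0.55, 0.7),
) -> list[PhantomSample]:
    """Generate ``n`` phantoms with per-sample geometry variation.

    Outer radius and cortical thickness are drawn uniformly from the given
    ranges so a model trained on the cohort must localize surfaces rather
    than memorize one geometry.
    """
    base = base_spec or desk_scale_spec()
    rng = np.random.default_rng(seed)
    samples = []
    for _ in range(n):
        spec = replace(
            base,
            outer_radius_mm=float(rng.uniform(*radius_range_mm)),
            cortical_thickness_mm=float(rng.uniform(*thickness_range_mm)),
            seed=int(rng.integers(2**31)),
        )
        samples.append(generate_phantom(spec))
    return samples


# ---------------------------------------------------------------------------
# stratified participant split
# ---------------------------------------------------------------------------

def stratified_split(
    participants: pd.DataFrame,
    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15),
    seed: int = 0,
    id_column: str = "participant",
    study_column: str = "study",
    bmd_column: str = "tt_bmd",
) -> pd.Series:
    """Assign participants to training/validation/test subsets.

    Rows are images (one or more per participant) with a study label and a
    total BMD value; stratification uses the minimum Tt.BMD across each
    participant's images.  Within each study, participants are binned into
    Tt.BMD quartiles, and within each bin assigned randomly at the given
    fractions (largest-remainder rounding with carried remainders, so the
    overall split is within one participant of the exact fractions).  All
    images of a participant land in the same subset.
    """
    if participants.empty:
        raise ValueError("empty participant table")
    if not np.isclose(sum(fractions), 1.0):
        raise ValueError("fractions must sum to 1")
    subsets = ("training", "validation", "test")
    per_participant = (
        participants.groupby([study_column, id_column])[bmd_column].min().reset_index()
    )
    rng = np.random.default_rng(seed)
    assignment: dict[object, str] = {}
    for _, group in per_participant.groupby(study_column):
        n_bins = min(4, group[id_column].nunique())
        bins = pd.qcut(group[bmd_column], q=n_bins, labels=False, duplicates="drop")
        carry = np.zeros(3)
        for _, bin_group in group.groupby(bins):
            ids = bin_group[id_column].to_numpy()
            rng.shuffle(ids)
            desired = np.array(fractions) * len(ids) + carry
            counts = np.floor(desired).astype(int)
            for i in np.argsort(-(desired - counts))[: len(ids) - counts.sum()]:
                counts[i] += 1
            carry = desired - counts
            start = 0
            for subset, count in zip(subsets, counts):
                for pid in ids[start : start + count]:
                    assignment[pid] = subset
                start += count
    return pd.Series(assignment, name="subset")
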