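"""Morphological post-processing against brute-force oracles.

The oracle path computes ball dilations/erosions by direct counting
(FFT convolution with an explicit ball footprint, outside-the-grid treated
as foreground for erosion) and connected components with scikit-image —
fully independent of the distance-transform implementation under test.
"""

import numpy as np
import pytest
from scipy import ndimage
from scipy.signal import fftconvolve
from skimage.measure import label as sk_label
from skimage.morphology import ball

from pqctseg.postprocess import (
    PostprocessParams,
    dilate_ball,
    erode_ball,
    fill_detached_background,
    iterative_binary_segmentation_filter,
    largest_component,
    minimum_cortical_shell_filter,
    morphological_bone_mask_filter,
    postprocess_segmentation,
)
from pqctseg.preprocess import standardize
from pqctseg.volume import NormalizedVolume, SegmentationPair


# ---------------------------------------------------------------------------
# brute-force oracle morphology
# ---------------------------------------------------------------------------

def oracle_dilate(mask, r):
    counts = fftconvolve(mask.astype(float), ball(r).astype(float), mode="same")
    return counts > 0.5


def oracle_erode(mask, r):
    padded = np.pad(mask, r, constant_values=True)
    counts = fftconvolve(padded.astype(float), ball(r).astype(float), mode="same")
    counts = counts[r:-r, r:-r, r:-r]
    return counts > ball(r).sum() - 0.5


def oracle_largest_fg(mask):
    labels = sk_label(mask, connectivity=3)
    if labels.max() == 0:
        return np.zeros_like(mask, dtype=bool)
    counts = np.bincount(labels.ravel())[1:]
    return labels == (np.argmax(counts) + 1)


def oracle_fill_background(mask):
    labels = sk_label(~mask, connectivity=1)
    if labels.max() == 0:
        return mask.astype(bool)
    counts = np.bincount(labels.ravel())[1:]
    return ~(labels == (np.argmax(counts) + 1))


def oracle_iterative_filter(mask, open_max, close_max):
    m = mask.copy()
    for r in range(1, max(open_max, close_max) + 1):
        if r <= open_max:
            m = oracle_erode(m, r)
            if not m.any():
                return np.zeros_like(mask, dtype=bool)
            m = oracle_largest_fg(m)
            m = oracle_dilate(m, r)
        if r <= close_max:
            m = oracle_dilate(m, r)
            m = oracle_fill_background(m)
            m = oracle_erode(m, r)
    return m


def speck_and_cavity_fixture(n=64):
    """Solid ball (radius 30) with an internal cavity plus a distant speck."""
    c = (n - 1) / 2.0
    zz, yy, xx = np.meshgrid(*(np.arange(n) - c,) * 3, indexing="ij")
    dist = np.sqrt(zz**2 + yy**2 + xx**2)
    mask = dist <= 30
    cavity = np.sqrt((zz - 10) ** 2 + yy**2 + xx**2) <= 5
    mask &= ~cavity
    mask[1, 1, 1] = True  # distant 1-voxel speck
    return mask, cavity


# ---------------------------------------------------------------------------
# elementary ball morphology
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("radius", [1, 2, 4])
def test_ball_dilate_matches_footprint_oracle(rng, radius):
    mask = ndimage.binary_dilation(rng.random((24, 24, 24)) > 0.97)
    np.testing.assert_array_equal(
        dilate_ball(mask, radius), oracle_dilate(mask, radius)
    )


@pytest.mark.parametrize("radius", [1, 2, 4])
def test_ball_erode_matches_footprint_oracle(rng, radius):
    mask = ndimage.binary_dilation(rng.random((24, 24, 24)) > 0.9, iterations=3)
    np.testing.assert_array_equal(erode_ball(mask, radius), oracle_erode(mask, radius))


def test_erosion_preserves_structures_at_volume_border():
    # a tube running through the whole axial extent must not erode at the ends
    mask = np.zeros((8, 32, 32), dtype=bool)
    mask[:, 8:24, 8:24] = True
    eroded = erode_ball(mask, 2)
    assert eroded[0].any() and eroded[-1].any()
    assert eroded.sum(axis=(1, 2)).min() == eroded.sum(axis=(1, 2)).max()


# ---------------------------------------------------------------------------
# iterative binary segmentation filter
# ---------------------------------------------------------------------------

class TestIterativeFilter:
    def test_empty_mask_passes_through_silently(self):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("error")
            out = iterative_binary_segmentation_filter(
                np.zeros((16, 16, 16), bool), 5, 15
            )
        assert not out.any()

    def test_speck_removed_cavity_filled_matches_oracle(self):
        mask, cavity = speck_and_cavity_fixture()
        ours = iterative_binary_segmentation_filter(mask, 5, 15)
        theirs = oracle_iterative_filter(mask, 5, 15)
        np.testing.assert_array_equal(ours, theirs)
        assert not ours[1, 1, 1]  # speck gone
        assert ours[cavity].all()  # cavity filled
        # the big ball is approximately preserved
        solid = np.zeros_like(mask)
        solid |= mask | cavity
        solid[1, 1, 1] = False
        agreement = (ours & solid).sum() / solid.sum()
        assert agreement > 0.98

    def test_single_foreground_component_retained(self, rng):
        mask = np.zeros((32, 32, 32), bool)
        mask[8:20, 8:20, 8:20] = True  # main block
        mask[26:29, 26:29, 26:29] = True  # secondary blob
        out = iterative_binary_segmentation_filter(mask, 3, 5)
        assert not out[26:29, 26:29, 26:29].any()
        assert sk_label(out, connectivity=3).max() == 1

    def test_total_erosion_warns_and_returns_empty(self):
        mask = np.zeros((16, 16, 16), bool)
        mask[8, 8, 8] = True
        with pytest.warns(UserWarning, match="emptied"):
            out = iterative_binary_segmentation_filter(mask, 5, 15)
        assert not out.any()


# ---------------------------------------------------------------------------
# minimum cortical shell filter
# ---------------------------------------------------------------------------

class TestShellFilter:
    def test_shell_disjoint_from_trabecular(self, rng):
        trab = ndimage.binary_dilation(rng.random((16, 24, 24)) > 0.99, iterations=4)
        shell = minimum_cortical_shell_filter(trab, 8)
        assert not (shell & trab).any()

    def test_slab_shell_thickness_by_distance_transform(self):
        trab = np.zeros((8, 48, 48), bool)
        trab[:, 16:32, :] = True  # thick slab spanning the grid
        shell = minimum_cortical_shell_filter(trab, 8)
        dist = ndimage.distance_transform_edt(~trab)
        assert shell[dist > 8].sum() == 0
        np.testing.assert_array_equal(shell, (dist <= 8) & ~trab)
        # along the slab normal the shell is exactly 8 voxels wide
        column = shell[4, :, 24]
        assert column[8:16].all() and column[32:40].all()
        assert column.sum() == 16

    def test_empty_trabecular_gives_empty_shell(self):
        shell = minimum_cortical_shell_filter(np.zeros((8, 16, 16), bool), 8)
        assert not shell.any()

    def test_eight_voxels_is_about_half_a_millimetre(self):
        assert 8 * 0.0607 == pytest.approx(0.5, abs=0.015)


# ---------------------------------------------------------------------------
# morphological bone mask filter and the full procedure
# ---------------------------------------------------------------------------

class TestBoneMaskFilter:
    def test_uniform_background_volume_warns_empty(self):
        nv = NormalizedVolume(np.full((8, 24, 24), -1.0))
        with pytest.warns(UserWarning):
            bone = morphological_bone_mask_filter(nv)
        assert not bone.voxels.any()

    def test_phantom_annulus_fills_to_single_component(self, small_phantom):
        nv = standardize(small_phantom.volume)
        bone = morphological_bone_mask_filter(nv)
        assert sk_label(bone.voxels, connectivity=3).max() == 1
        truth_bone = small_phantom.truth.bone
        inter = (bone.voxels & truth_bone).sum()
        dsc = 2 * inter / (bone.voxels.sum() + truth_bone.sum())
        assert dsc > 0.97  # interior cavity filled, annulus covered

    def test_secondary_bone_excluded(self):
        from pqctseg.phantom import desk_scale_spec, generate_phantom

        sample = generate_phantom(desk_scale_spec(secondary_bone=True, seed=21))
        nv = standardize(sample.volume)
        bone = morphological_bone_mask_filter(nv)
        assert sk_label(bone.voxels, connectivity=3).max() == 1
        # nothing outside a 1-voxel band of the primary bone
        primary_band = ndimage.binary_dilation(sample.truth.bone, np.ones((3, 3, 3)))
        assert not (bone.voxels & ~primary_band).any()


@pytest.fixture(scope="module")
def corrupted(small_phantom):
    """Raw masks with an injected speck and hole, and their post-processing."""
    truth = small_phantom.truth
    cort = truth.cortical.voxels.copy()
    trab = truth.trabecular.voxels.copy()
    cort[2, 4, 4] = True  # speck in the background
    trab[6, 44:47, 48:51] = False  # hole in the trabecular mask
    raw = SegmentationPair.from_arrays(cort.astype(np.uint8), trab.astype(np.uint8))
    nv = standardize(small_phantom.volume)
    return nv, raw, postprocess_segmentation(nv, raw)


class TestPostprocessSegmentation:
    def test_final_masks_disjoint(self, corrupted):
        _, _, final = corrupted
        assert not (final.cortical.voxels & final.trabecular.voxels).any()

    def test_final_masks_near_ground_truth(self, corrupted, small_phantom):
        _, _, final = corrupted
        for name in ("cortical", "trabecular"):
            pred = getattr(final, name).voxels
            true = getattr(small_phantom.truth, name).voxels
            band = ndimage.binary_dilation(true, np.ones((3, 3, 3)), iterations=2)
            assert not (pred & ~band).any(), f"{name} extends past 2-voxel band"
            core = ndimage.binary_erosion(true, np.ones((3, 3, 3)), iterations=2)
            assert (core & ~pred).sum() == 0, f"{name} misses interior voxels"

    def test_single_component_per_compartment(self, corrupted):
        _, _, final = corrupted
        assert sk_label(final.cortical.voxels, connectivity=3).max() == 1
        assert sk_label(final.trabecular.voxels, connectivity=3).max() == 1

    def test_trabecular_separated_from_background_by_shell(self, corrupted):
        _, _, final = corrupted
        background = ~(final.cortical.voxels | final.trabecular.voxels)
        dist = ndimage.distance_transform_edt(~final.trabecular.voxels)
        assert dist[background].min() > 8

    def test_no_background_gap_between_compartments(self, corrupted):
        _, _, final = corrupted
        # every trabecular boundary voxel's outward 6-neighbors are bone
        trab = final.trabecular.voxels
        bone = final.cortical.voxels | trab
        grown = ndimage.binary_dilation(
            trab, ndimage.generate_binary_structure(3, 1)
        )
        assert (grown & ~bone).sum() == 0

    def test_idempotent_within_one_percent(self, corrupted):
        nv, _, final = corrupted
        again = postprocess_segmentation(nv, final)
        for name in ("cortical", "trabecular"):
            a = getattr(final, name).voxels
            b = getattr(again, name).voxels
            assert (a ^ b).sum() / max(a.sum(), 1) < 0.01

    def test_shape_mismatch_rejected(self, small_phantom):
        nv = standardize(small_phantom.volume)
        zeros = np.zeros((4, 8, 8), dtype=np.uint8)
        with pytest.raises(ValueError, match="shape"):
            postprocess_segmentation(nv, SegmentationPair.from_arrays(zeros, zeros))

    def test_empty_everything_is_failed_segmentation(self):
        nv = NormalizedVolume(np.full((8, 24, 24), -1.0))
        zeros = np.zeros(nv.shape, dtype=np.uint8)
        raw = SegmentationPair.from_arrays(zeros, zeros)
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError, match="failed segmentation"):
                postprocess_segmentation(nv, raw)


def test_largest_component_and_fill_background_match_oracle(rng):
    mask = rng.random((20, 20, 20)) > 0.7
    np.testing.assert_array_equal(largest_component(mask), oracle_largest_fg(mask))
    np.testing.assert_array_equal(
        fill_detached_background(mask), oracle_fill_background(mask)
    )
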