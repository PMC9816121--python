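"""Repair corrupted segmentations with the morphological post-processing.

Specks, holes, and a secondary bone are injected into ground-truth masks;
the three-filter procedure removes them and restores the required topology:
one connected component per compartment and a continuous cortical shell of
at least 8 voxels (~0.5 mm) around the trabecular compartment.
"""

import numpy as np
from scipy import ndimage
from skimage.measure import label

from pqctseg import SegmentationPair, overlap_metrics, postprocess_segmentation
from pqctseg.phantom import desk_scale_spec, generate_phantom
from pqctseg.preprocess import standardize

sample = generate_phantom(desk_scale_spec(secondary_bone=True, seed=21))
nv = standardize(sample.volume)

rng = np.random.default_rng(0)
cort = sample.truth.cortical.voxels.copy()
trab = sample.truth.trabecular.voxels.copy()
cort |= rng.random(cort.shape) > 0.9995            # union noise specks
trab &= rng.random(trab.shape) > 0.001             # subtractive noise
cort |= (sample.volume.voxels > 600) & ~sample.truth.bone  # secondary bone picked up

raw = SegmentationPair.from_arrays(
    (cort & ~trab).astype(np.uint8), trab.astype(np.uint8)
)
print(f"raw cortical components:   {label(raw.cortical.voxels, connectivity=3).max()}")

final = postprocess_segmentation(nv, raw)
print(f"final cortical components: {label(final.cortical.voxels, connectivity=3).max()}")
print(f"final trabecular components: {label(final.trabecular.voxels, connectivity=3).max()}")

for name in ("cortical", "trabecular"):
    dsc = overlap_metrics(
        getattr(final, name), getattr(sample.truth, name)
    ).dsc
    print(f"{name} DSC vs ground truth: {dsc:.4f}")

background = ~(final.cortical.voxels | final.trabecular.voxels)
dist = ndimage.distance_transform_edt(~final.trabecular.voxels)
print(f"minimum cortical separation of trabecular from background: "
      f"{dist[background].min():.2f} voxels (>= 8 required)")
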