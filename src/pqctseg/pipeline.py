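"""End-to-end inference: axial sweep, mask conversion, post-processing."""

from __future__ import annotations

import time
from dataclasses import dataclass

import numpy as np

from .postprocess import PostprocessParams, postprocess_segmentation
from .preprocess import crop_in_plane, make_slice_stack, pad_in_plane, standardize
from .unet import EmbeddingUNet
from .volume import DensityVolume, NormalizedVolume, SegmentationPair


@dataclass
class VolumeEmbeddings:
    """Per-slice embedding fields assembled into rank-3 grids."""

    endo: np.ndarray
    peri: np.ndarray

    def __post_init__(self) -> None:
        self.endo = np.asarray(self.endo, dtype=np.float64)
        self.peri = np.asarray(self.peri, dtype=np.float64)
        if self.endo.shape != self.peri.shape:
            raise ValueError("endo and peri grids must share a shape")


def predict_volume(
    model: EmbeddingUNet, nv: NormalizedVolume, batch_size: int = 4
) -> VolumeEmbeddings:
    """Sweep the 2D model over every axial slice (independent predictions).

    Each slice's 5-slice stack is forwarded in evaluation mode; the
    center-slice output fields are stacked into two rank-3 embedding grids.
    """
    stride = 2**model.config.depth
    h, w = nv.shape[1:]
    if h % stride or w % stride:
        raise ValueError(
            f"in-plane dims {h}x{w} must be divisible by 2^depth = {stride}; "
            "pad the volume first"
        )
    endo = np.empty(nv.shape)
    peri = np.empty(nv.shape)
    for start in range(0, nv.n_slices, batch_size):
        indices = range(start, min(start + batch_size, nv.n_slices))
        stacks = np.stack([make_slice_stack(nv, i).slices for i in indices])
        out = model.forward_batch(stacks, train=False)
        data = out.data if hasattr(out, "data") else out
        endo[list(indices)] = data[:, 0]
        peri[list(indices)] = data[:, 1]
    return VolumeEmbeddings(endo, peri)


def embeddings_to_masks(
    emb: VolumeEmbeddings, voxel_size_mm: float = 0.0607
) -> SegmentationPair:
    """Threshold embeddings at zero (strict inequalities).

    Trabecular is the region inside the endosteal surface (phi_endo < 0);
    cortical is the region between the surfaces (phi_endo > 0 and
    phi_peri < 0).  Voxels with a field exactly zero belong to neither, so
    the masks are disjoint by construction.
    """
    trabecular = emb.endo < 0
    cortical = (emb.endo > 0) & (emb.peri < 0)
    return SegmentationPair.from_arrays(
        cortical.astype(np.uint8), trabecular.astype(np.uint8), voxel_size_mm
    )


def segment(
    vol: DensityVolume,
    model: EmbeddingUNet,
    params: PostprocessParams | None = None,
    postprocess: bool = True,
    log_fn=None,
) -> SegmentationPair:
    """Full deterministic pipeline from a calibrated volume to final masks.

    pad -> standardize -> predict_volume -> embeddings_to_masks ->
    postprocess_segmentation -> crop back to the original extents.
    """
    timings: dict[str, float] = {}

    def _tick(stage, t0):
        timings[stage] = time.perf_counter() - t0
        return time.perf_counter()

    t = time.perf_counter()
    padded = pad_in_plane(vol)
    nv = standardize(padded)
    t = _tick("preprocess", t)
    emb = predict_volume(model, nv)
    t = _tick("predict", t)
    raw = embeddings_to_masks(emb, vol.voxel_size_mm)
    if postprocess:
        final = postprocess_segmentation(nv, raw, params)
    else:
        final = raw
    t = _tick("postprocess", t)
    out = SegmentationPair.from_arrays(
        crop_in_plane(final.cortical.voxels, vol.shape).astype(np.uint8),
        crop_in_plane(final.trabecular.voxels, vol.shape).astype(np.uint8),
        vol.voxel_size_mm,
    )
    if log_fn is not None:
        log_fn(timings)
    return out
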