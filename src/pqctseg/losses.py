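"""Embedding-based losses for the surface-predicting U-Net.

The network predicts two level-set embedding fields per slice.  Training
drives them with three ingredients:

* a cross-entropy classification loss, after converting the embeddings to
  per-voxel class probabilities through a smoothed Heaviside function
  H_eps(x) = 1/2 + (1/pi) * arctan(x / eps):

      p_trab = H(-phi_endo),  p_cort = H(phi_endo) * H(-phi_peri),
      p_back = H(phi_peri),   then normalized to sum to one per voxel;

* a curvature regularizer that penalizes zero-level-set curvature magnitudes
  beyond a physiological threshold kappa_thresh (0.005 um^-1, i.e. 0.3035
  voxel^-1 at the 60.7 um voxel), where curvature is the divergence of the
  normalized gradient field;

* a gradient-magnitude regularizer log^2|grad phi| away from the surface,
  which pushes the embeddings toward proper signed distance functions
  (|grad phi| = 1 off-surface).

The total is L_CE + lambda_kappa * (L_k,endo + L_k,peri)
           + lambda_grad * (L_g,endo + L_g,peri), both lambdas 1e-4.

All functions treat the last two array axes as the slice plane, so they work
on single 2D fields and on batched (N, H, W) stacks alike.  Every term is
differentiable through :mod:`pqctseg.autodiff` when given tracked tensors;
the surface band delta(phi) is a binary constant computed from field values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .unet import EmbeddingFieldPair
from .volume import DEFAULT_VOXEL_SIZE_MM

#: Probability clamp before the cross-entropy logarithm.
CE_LOG_CLAMP = 1e-12
#: Floor on |grad phi| before its logarithm, and the curvature stabilizer.
GRAD_LOG_CLAMP = 1e-8
CURVATURE_STABILIZER = 1e-8


@dataclass
class LossWeights:
    """Loss hyper-parameters.

    epsilon: Heaviside sharpness, voxel units.  kappa_thresh_um: curvature
    threshold in um^-1 (converted to voxel^-1 through the voxel size).
    lambda_kappa / lambda_grad: regularization coefficients.
    """

    epsilon: float = 1.0
    kappa_thresh_um: float = 0.005
    lambda_kappa: float = 1e-4
    lambda_grad: float = 1e-4
    voxel_size_mm: float = DEFAULT_VOXEL_SIZE_MM

    def __post_init__(self) -> None:
        if not self.epsilon > 0:
            raise ValueError("epsilon must be > 0")
        if not self.kappa_thresh_um > 0:
            raise ValueError("kappa_thresh_um must be > 0")
        if self.lambda_kappa < 0 or self.lambda_grad < 0:
            raise ValueError("lambda coefficients must be >= 0")

    @property
    def kappa_thresh_voxel(self) -> float:
        """Curvature threshold in voxel^-1 (0.005 um^-1 -> 0.3035 at 60.7 um)."""
        return self.kappa_thresh_um * self.voxel_size_mm * 1000.0


@dataclass
class ProbabilisticSegmentation:
    p_trab: np.ndarray
    p_cort: np.ndarray
    p_back: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        for name in ("p_trab", "p_cort", "p_back"):
            arr = np.asarray(getattr(self, name), dtype=np.float64)
            if arr.min() < -1e-9 or arr.max() > 1 + 1e-9:
                raise ValueError(f"{name} must lie in [0, 1]")
            setattr(self, name, arr)
        if self.normalized:
            total = self.p_trab + self.p_cort + self.p_back
            if np.any(np.abs(total - 1.0) > 1e-6):
                raise ValueError("normalized probabilities must sum to 1 per voxel")


@dataclass
class SurfaceBand:
    """Binary indicator of the zero-crossing band of an embedding field."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask).astype(bool)


@dataclass
class LossBreakdown:
    """The five loss terms and their lambda-weighted total."""

    l_ce: object
    l_kappa_endo: object
    l_kappa_peri: object
    l_grad_endo: object
    l_grad_peri: object
    l_total: object

    def as_floats(self) -> "LossBreakdown":
        def f(x):
            return float(x.data) if ad.is_tensor(x) else float(x)

        return LossBreakdown(*(f(getattr(self, n)) for n in _BREAKDOWN_FIELDS))


_BREAKDOWN_FIELDS = (
    "l_ce",
    "l_kappa_endo",
    "l_kappa_peri",
    "l_grad_endo",
    "l_grad_peri",
    "l_total",
)


# ---------------------------------------------------------------------------
# probabilities and cross-entropy
# ---------------------------------------------------------------------------

def heaviside(x, epsilon: float = 1.0):
    """Smoothed Heaviside H_eps(x) = 1/2 + arctan(x / eps) / pi, in (0, 1)."""
    if not epsilon > 0:
        raise ValueError("epsilon must be > 0")
    return 0.5 + ad.atan(x * (1.0 / epsilon)) * (1.0 / np.pi)


def _class_probabilities(endo, peri, epsilon: float):
    p_trab = heaviside(-endo, epsilon)
    p_cort = heaviside(endo, epsilon) * heaviside(-peri, epsilon)
    p_back = heaviside(peri, epsilon)
    return p_trab, p_cort, p_back


def probabilistic_segmentation(
    fields: EmbeddingFieldPair, w: LossWeights | None = None
) -> ProbabilisticSegmentation:
    """Convert embeddings to (unnormalized) per-voxel class probabilities."""
    w = w or LossWeights()
    p_trab, p_cort, p_back = _class_probabilities(fields.endo, fields.peri, w.epsilon)
    return ProbabilisticSegmentation(p_trab, p_cort, p_back, normalized=False)


def normalize_probs(p: ProbabilisticSegmentation) -> ProbabilisticSegmentation:
    """Normalize the three class probabilities to sum to one per voxel."""
    total = p.p_trab + p.p_cort + p.p_back
    if np.any(total <= 0):
        raise ValueError("cannot normalize a zero-sum probability voxel")
    return ProbabilisticSegmentation(
        p.p_trab / total, p.p_cort / total, p.p_back / total, normalized=True
    )


def _one_hot_refs(cortical: np.ndarray, trabecular: np.ndarray):
    cortical = np.asarray(cortical).astype(bool)
    trabecular = np.asarray(trabecular).astype(bool)
    if cortical.shape != trabecular.shape:
        raise ValueError("reference masks must share a shape")
    if np.any(cortical & trabecular):
        raise ValueError("reference masks must be disjoint")
    background = ~(cortical | trabecular)
    return trabecular.astype(float), cortical.astype(float), background.astype(float)


def _cross_entropy_terms(p_trab, p_cort, p_back, cortical, trabecular):
    s_trab, s_cort, s_back = _one_hot_refs(cortical, trabecular)
    nll = -(
        s_trab * ad.log(ad.clip_min(p_trab, CE_LOG_CLAMP))
        + s_cort * ad.log(ad.clip_min(p_cort, CE_LOG_CLAMP))
        + s_back * ad.log(ad.clip_min(p_back, CE_LOG_CLAMP))
    )
    return ad.mean(nll)


def cross_entropy(
    p: ProbabilisticSegmentation, cortical: np.ndarray, trabecular: np.ndarray
):
    """Mean per-voxel negative log-likelihood against one-hot reference masks."""
    if not p.normalized:
        raise ValueError("cross_entropy expects normalized probabilities")
    if np.asarray(cortical).shape != np.asarray(p.p_trab).shape:
        raise ValueError("reference and probability shapes differ")
    return float(_cross_entropy_terms(p.p_trab, p.p_cort, p.p_back, cortical, trabecular))


# ---------------------------------------------------------------------------
# discrete differential operators (last two axes = slice plane)
# ---------------------------------------------------------------------------

def _axis_slice(ndim: int, axis: int, sl: slice) -> tuple:
    key = [slice(None)] * ndim
    key[axis] = sl
    return tuple(key)


def _diff_along(phi, axis: int):
    """np.gradient-style derivative: central interior, one-sided at borders."""
    ndim = phi.ndim if ad.is_tensor(phi) else np.asarray(phi).ndim
    n = phi.shape[axis]
    if n < 3:
        raise ValueError("fields must have extent >= 3 along spatial axes")
    first = phi[_axis_slice(ndim, axis, slice(1, 2))] - phi[
        _axis_slice(ndim, axis, slice(0, 1))
    ]
    interior = (
        phi[_axis_slice(ndim, axis, slice(2, None))]
        - phi[_axis_slice(ndim, axis, slice(0, -2))]
    ) * 0.5
    last = phi[_axis_slice(ndim, axis, slice(-1, None))] - phi[
        _axis_slice(ndim, axis, slice(-2, -1))
    ]
    return ad.concat([first, interior, last], axis=axis)


def spatial_gradient(phi):
    """In-plane gradient (d/drow, d/dcol) with unit voxel spacing."""
    shape = phi.shape
    if shape[-1] < 3 or shape[-2] < 3:
        raise ValueError(f"field too small for gradients: {shape}")
    ndim = phi.ndim if ad.is_tensor(phi) else np.asarray(phi).ndim
    return _diff_along(phi, ndim - 2), _diff_along(phi, ndim - 1)


def gradient_magnitude(phi, stabilizer: float = 0.0):
    """|grad phi|; a small ``stabilizer`` smooths the magnitude at zero."""
    gr, gc = spatial_gradient(phi)
    return (gr * gr + gc * gc + stabilizer**2) ** 0.5


def zero_crossing_mask(phi, connectivity: int = 4) -> SurfaceBand:
    """Voxels where phi is zero or changes sign against a neighbor.

    4-connectivity by default; 8-connectivity additionally compares the two
    in-plane diagonals and widens the band by at most one voxel.
    """
    arr = phi.data if ad.is_tensor(phi) else np.asarray(phi, dtype=np.float64)
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    sign = np.sign(arr)
    band = arr == 0.0
    offsets = [(0, 1), (1, 0)]
    if connectivity == 8:
        offsets += [(1, 1), (1, -1)]
    ndim = arr.ndim
    for dr, dc in offsets:
        a_key = [slice(None)] * ndim
        b_key = [slice(None)] * ndim
        a_key[-2] = slice(None, -dr) if dr else slice(None)
        b_key[-2] = slice(dr, None) if dr else slice(None)
        if dc > 0:
            a_key[-1], b_key[-1] = slice(None, -dc), slice(dc, None)
        elif dc < 0:
            a_key[-1], b_key[-1] = slice(-dc, None), slice(None, dc)
        differs = sign[tuple(a_key)] != sign[tuple(b_key)]
        band[tuple(a_key)] |= differs
        band[tuple(b_key)] |= differs
    return SurfaceBand(band)


def curvature(phi, stabilizer: float = CURVATURE_STABILIZER):
    """Zero-level-set curvature: divergence of the normalized gradient field.

    kappa = div(grad phi / (|grad phi| + eta)), in voxel^-1 units.
    """
    shape = phi.shape
    if shape[-1] < 5 or shape[-2] < 5:
        raise ValueError(f"field too small for curvature: {shape}")
    gr, gc = spatial_gradient(phi)
    gm = (gr * gr + gc * gc + stabilizer**2) ** 0.5
    nr = gr / (gm + stabilizer)
    nc = gc / (gm + stabilizer)
    ndim = phi.ndim if ad.is_tensor(phi) else np.asarray(phi).ndim
    return _diff_along(nr, ndim - 2) + _diff_along(nc, ndim - 1)


# ---------------------------------------------------------------------------
# regularizers and the combined loss
# ---------------------------------------------------------------------------

def curvature_loss(phi, w: LossWeights | None = None):
    """Mean of delta(phi) * ReLU((kappa / kappa_thresh)^2 - 1) over all voxels."""
    w = w or LossWeights()
    band = zero_crossing_mask(phi).mask.astype(float)
    kappa = curvature(phi)
    ratio = kappa * (1.0 / w.kappa_thresh_voxel)
    return ad.mean(band * ad.relu(ratio * ratio - 1.0))


def gradient_magnitude_loss(phi, w: LossWeights | None = None):
    """Mean of (1 - delta(phi)) * log^2|grad phi| over all voxels.

    The magnitude is floored at 1e-8 (via a smooth stabilizer) before the
    logarithm; a proper signed distance function scores zero.
    """
    w = w or LossWeights()
    off_band = 1.0 - zero_crossing_mask(phi).mask.astype(float)
    gm = gradient_magnitude(phi, stabilizer=GRAD_LOG_CLAMP)
    log_gm = ad.log(gm)
    return ad.mean(off_band * (log_gm * log_gm))


def total_loss_fields(endo, peri, cortical, trabecular, w: LossWeights | None = None):
    """Combined loss on raw (possibly tracked) embedding fields.

    Returns a :class:`LossBreakdown` whose entries are tensors when the
    fields are tensors, so the total can be backpropagated.
    """
    w = w or LossWeights()
    p_trab, p_cort, p_back = _class_probabilities(endo, peri, w.epsilon)
    total = p_trab + p_cort + p_back
    l_ce = _cross_entropy_terms(
        p_trab / total, p_cort / total, p_back / total, cortical, trabecular
    )
    l_k_endo = curvature_loss(endo, w)
    l_k_peri = curvature_loss(peri, w)
    l_g_endo = gradient_magnitude_loss(endo, w)
    l_g_peri = gradient_magnitude_loss(peri, w)
    l_total = (
        l_ce
        + w.lambda_kappa * (l_k_endo + l_k_peri)
        + w.lambda_grad * (l_g_endo + l_g_peri)
    )
    return LossBreakdown(l_ce, l_k_endo, l_k_peri, l_g_endo, l_g_peri, l_total)


def total_loss(
    fields: EmbeddingFieldPair,
    cortical: np.ndarray,
    trabecular: np.ndarray,
    w: LossWeights | None = None,
) -> LossBreakdown:
    """Combined loss for one predicted slice against its reference masks."""
    if np.asarray(cortical).shape != fields.endo.shape:
        raise ValueError("reference and field shapes differ")
    return total_loss_fields(fields.endo, fields.peri, cortical, trabecular, w).as_floats()
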