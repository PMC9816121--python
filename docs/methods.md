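# Methods

This note records the model, the numerical choices, and the design
decisions behind `pqctseg`, together with what the synthetic phantoms do
and do not establish about behavior on real scans.

## Problem setting

An HR-pQCT scan of the distal radius or tibia is a stack of ~168 axial
slices at 60.7 µm isotropic voxels, calibrated to hydroxyapatite-equivalent
density (mg HA/cm³). Morphometric analysis requires a semantic segmentation
into three regions — background, cortical bone, trabecular bone — separated
by two nested surfaces: the periosteal surface (background/cortical
interface) and the endosteal surface (cortical/trabecular interface). The
pipeline here is surface-centric: the network predicts level-set embeddings
of the two surfaces rather than class labels, which makes surface geometry
(curvature, distance) directly accessible to the loss.

## Pre-processing

Densities are clamped to [−400, 1400] mg HA/cm³ and mapped linearly to
[−1, 1] (so 275 mg HA/cm³ → −0.25, the threshold used by the density-based
bone mask). The clamp range covers air/soft tissue at the bottom and dense
cortical bone at the top; values outside carry no information the
segmentation needs. In-plane extents are padded to one common multiple of 8
— a single square extent rather than per-axis multiples, since a square
grid simplifies the network and the difference is only padding voxels. The
pad value is the −400 floor, which standardizes to −1 and reads as
background. Calibration slopes/intercepts from native scanner units vary by
device and are therefore always explicit inputs, never constants.

Each slice's network input is the stack of five adjacent slices. At the
volume ends the missing neighbors are filled by mirror reflection without
repeating the edge slice (NumPy/ITK 'reflect'); the alternative
edge-repeating convention would change only the two outermost stacks.

## Network

A 2D U-Net (configurable depth and width; default depth 4, 32 base
channels doubling per level) with:

* double 3×3 convolutions per level, 'same' padding so output size equals
  input size;
* group normalization (8 groups) and dropout (p = 0.1) in each block —
  group counts and dropout rate are not critical and are config-exposed;
* 2×2 max-pool downsampling and 2×2-stride-2 transposed-convolution
  upsampling with skip concatenation;
* ReLU activations and a final 1×1 convolution to two output fields,
  ordered (endosteal, periosteal).

Because no deep-learning framework is part of the dependency set, the
network, its layers, and AdamW are implemented over NumPy with a compact
tape-based reverse-mode autodiff engine (`pqctseg.autodiff`). Every
primitive's gradient (convolution, transposed convolution, max-pool, group
norm, reductions, slicing/concatenation, elementwise ops) is checked
against central finite differences in `tests/test_autodiff.py`. Evaluation
mode is deterministic; training determinism holds on a single device given
the config seed.

## Losses

With H_ε(x) = ½ + atan(x/ε)/π (ε = 1 voxel by default; a ~1-voxel
transition width matches the surface-localization task and is
config-exposed), the fields become class probabilities

    p_trab = H(−φ_endo),  p_cort = H(φ_endo)·H(−φ_peri),  p_back = H(φ_peri),

normalized to sum to one per voxel, and scored by mean negative
log-likelihood against the one-hot reference (probabilities floored at
1e−12 before the log).

Two regularizers act on each field:

* **Curvature.** κ = ∇·(∇φ/(|∇φ| + η)), central differences with one-sided
  borders, stabilizer η = 1e−8. On the zero-crossing band δ(φ) (4-connected
  sign changes or exact zeros; 8-connectivity is available and widens the
  band ≤ 1 voxel), the loss is mean δ(φ)·ReLU((κ/κ_thresh)² − 1), i.e. only
  curvature magnitudes beyond κ_thresh = 0.005 µm⁻¹ are penalized. The
  threshold is stored in physical units and converted by the voxel size
  (0.3035 voxel⁻¹ at 60.7 µm).
* **Gradient magnitude.** mean (1 − δ(φ))·log²|∇φ|, zero exactly when the
  field is a signed distance function off-surface. |∇φ| is computed as
  √(∂r² + ∂c² + 1e−16), a smooth implementation of the 1e−8 clamp that
  keeps the gradient finite where the field is locally flat.

All terms reduce by the mean over all slice voxels, which keeps the λ's
independent of image size. The total is L_CE + 10⁻⁴·(curvature terms) +
10⁻⁴·(gradient terms). The discrete curvature of a circle of radius R
matches 1/R to within a few percent for R ≥ 10 voxels (tested); at exactly
κ = κ_thresh the analytic loss is zero and the discrete residual is below
5e−3.

## Training protocol

Per epoch, images are shuffled; within each image, slices are shuffled and
consumed in batches of 4 (a 168-slice scan gives 42 batches; trailing
partial batches are kept — a full-size scan never produces one). AdamW uses
its canonical defaults (β₂ = 0.999, eps = 1e−8, weight decay 0.01); the
learning rate and β₁ follow the one-cycle policy with linear ramps:
lr 10⁻⁴ → 10⁻³ over a 10-epoch half-cycle, back to 10⁻⁴ over the second,
then annealing to lr_min/25 over 5 convergence epochs (the /25 final target
follows the policy's usual final-annealing convention; momentum moves
inversely 0.95 ↔ 0.85 and stays at 0.95 during convergence). A full
validation pass in evaluation mode closes every epoch. Non-finite losses
abort with a diagnostic. Multi-device training is out of scope.

## Post-processing

Raw masks from thresholding the fields at zero (exact zeros belong to no
compartment — a measure-zero case) are repaired by three filters:

1. **Iterative binary segmentation filter** — an alternating sequential
   open–close with Euclidean-ball structuring elements of radius
   r = 1, 2, …, max (open max 5, close max 15), interleaved per radius.
   Inside each open, only the largest 26-connected foreground component is
   kept; inside each close, only the largest 6-connected background
   component survives (detached cavities are filled). This removes specks,
   fills holes, and excludes the secondary bone (ulna/fibula).
2. **Minimum cortical shell filter** — dilate the filtered trabecular mask
   by 8 voxels (≈ 0.5 mm) and subtract the mask, yielding a shell that
   forces a minimum cortical thickness around the trabecular compartment.
3. **Morphological bone mask filter** — threshold the standardized image at
   −0.25, median-filter with a 3×3×1 (sagittal, coronal, axial) kernel, and
   run the iterative filter with radii 3/15. This density-derived whole-bone
   mask is unioned in to protect against a catastrophic network miss.

The full procedure: filter the trabecular mask (1), build its shell (2),
filter the raw whole-bone union (1), build the density bone mask (3), union
all four into the final bone mask, and split it as cortical = bone minus
trabecular. The wiring satisfies every stated guarantee (disjoint masks,
single components, no background gaps between compartments, ≥ 8-voxel
separation of trabecular from background) and is isolated in one function
so alternate wirings can be swapped in. The whole-bone input to the
iterative filter is the cortical ∪ trabecular union rather than the
cortical mask alone — the union is the quantity with the topology the
filter is meant to enforce.

Ball erosions/dilations are computed via exact Euclidean distance
transforms, which is equivalent to ball-footprint morphology but linear in
the voxel count; the tests verify voxel-exact agreement with a brute-force
counting-convolution implementation. The volume border is treated as
edge-replicated (erosion does not eat structures that run off the axial
ends of the scan, matching scikit-image's border convention). A
consequence: a closing with radius r needs ≥ r voxels of in-plane
background margin around the bone, or the dilation clips at the border and
the closing inflates the mask. Full-scale scans and the default phantom
satisfy this; the desk-scale phantom grid is sized accordingly (96² for
bones up to ~1.6 mm radius with the radius-15 close).

## Metrics and precision

Overlap: DSC and JSC (both defined as 1 for two empty masks). Surface
distances: boundaries are 6-connectivity erosion differences; ASSD and
Hausdorff are the mean and max of the pooled bidirectional nearest-surface
distances, in mm. Agreement: Bland–Altman bias ± 1.96·SD (n−1) and OLS
(statsmodels) with ±1.96·SE confidence intervals. Precision: per-pair
SD = |x₁ − x₂|/√2, RMS SD and RMS %CV (pair-mean denominator, the standard
densitometry convention), LSC = 2.77 · RMS SD (two measurements at both
timepoints, 95% confidence; the multiplier is config-exposed). Protocol
comparison: D'Agostino–Pearson normality on the per-participant SDs, then a
two-sided paired Wilcoxon signed-rank test (Pratt zero handling). The
"low cortical thickness" / "high cortical porosity" sub-groups are bottom-
and top-quartile selections over an externally supplied parameter table —
morphometric parameters themselves (Ct.Po, Tb.N, …) are out of scope, as is
the rigid registration of repeat scans (a transform is accepted as input).

## Synthetic phantoms

Each phantom is a per-slice circular cross-section with slow axial center
drift: a cortical annulus at 900 mg HA/cm³ around an interior whose
band-limited strut/marrow texture (0.5 mm correlation scale, 30% strut
fraction at 450 mg HA/cm³) averages 200 mg HA/cm³, optional low-density
cortical pores, an optional secondary bone near the image corner, and
additive Gaussian noise (SD 50 mg HA/cm³) clipped to the calibration range.
Geometry is analytic, so the ground-truth masks and exact signed-distance
embeddings are known in closed form — the SDFs satisfy |∇φ| ≈ 1 off-surface
and band curvature ≈ 1/R, which makes them oracles for the regularizer
losses. Defaults (3.5 mm outer radius, 0.8 mm cortex, 160² × 16 grid)
mirror distal-radius scale; `desk_scale_spec()` (1.4 mm radius, 0.6 mm
cortex, 96² × 12) is used for minute-scale tests. Cortical thickness in any
phantom meant to be recovered exactly should be ≥ 8 voxels (0.49 mm), since
the shell filter deliberately enforces that minimum. Repeat-scan pairs
share anatomy (the texture field is rigidly resampled), are displaced by a
known in-plane rigid transform, and receive fresh noise.

What the phantom does **not** emulate: plate-and-rod trabecular
microarchitecture, cortical porosity gradients, beam hardening, motion
artifacts, or non-circular cross-sections. Passing the end-to-end test
therefore shows that the implementation — losses, optimizer, schedule,
sweep, post-processing — can recover known surfaces from noisy images at
realistic densities and noise levels; it does not certify clinical accuracy
on real anatomy, which requires training on expert-segmented scans.

## Desk-scale study conditions

The end-to-end check trains a depth-2, 8-channel network on 8 phantoms
(geometry varied per sample: radius 1.2–1.6 mm, cortex 0.55–0.7 mm) for the
full 25-epoch protocol and segments 2 held-out phantoms — a few minutes on
one CPU. Post-processed masks reach DSC ≥ 0.95 per compartment with the
required topology. The same run is reproduced by `scripts/acceptance.py`.

## Known limitations

* Single-device determinism only; no mixed precision or distribution.
* NumPy execution is orders of magnitude slower than GPU frameworks;
  full-scale (1822-image) training is out of reach here by design.
* The iterative filter's per-radius interleaving of open and close is one
  reading of "alternating with gradually increasing elements"; the
  alternative (two full sequential passes) is not implemented.
* Exact channel widths of the original architecture are schematic-derived;
  capacity is config-driven and no result here depends on matching it.
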