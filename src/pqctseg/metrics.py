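"""Segmentation quality metrics, agreement analysis, and precision statistics.

Overlap is quantified by the Dice and Jaccard coefficients, surface accuracy
by the average and maximum symmetric surface distances (ASSD, Hausdorff)
between 6-connectivity boundary voxels.  Method agreement across a cohort
uses Bland-Altman limits (bias +/- 1.96 SD of the errors) and ordinary
least squares regression (statsmodels), with 1.96 SE confidence intervals.

Repeat-scan precision follows the standard densitometry convention: for a
same-day scan pair (x1, x2), SD = |x1 - x2| / sqrt(2); the cohort precision
error is the root mean square of the SDs (RMS SD) or of the percentage CVs
(RMS %CV, pair mean as denominator), and the least significant change is
LSC = 2.77 * RMS SD (95% confidence for a two-measurement comparison).
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import ndimage, stats
from scipy.spatial import cKDTree

from .volume import CompartmentMask, DensityVolume, SegmentationPair

#: LSC multiplier for two repeat measurements at 95% confidence (Gluer).
LSC_MULTIPLIER = 2.77


# ---------------------------------------------------------------------------
# overlap and surface metrics
# ---------------------------------------------------------------------------

@dataclass
class OverlapMetrics:
    dsc: float
    jsc: float


@dataclass
class SurfaceMetrics:
    assd_mm: float
    hausdorff_mm: float


def _mask_array(m) -> np.ndarray:
    return m.voxels if isinstance(m, CompartmentMask) else np.asarray(m, dtype=bool)


def overlap_metrics(a, b) -> OverlapMetrics:
    """Dice and Jaccard coefficients; both 1 when both masks are empty."""
    av, bv = _mask_array(a), _mask_array(b)
    if av.shape != bv.shape:
        raise ValueError(f"mask shapes differ: {av.shape} vs {bv.shape}")
    inter = np.count_nonzero(av & bv)
    na, nb = np.count_nonzero(av), np.count_nonzero(bv)
    union = na + nb - inter
    if na + nb == 0:
        return OverlapMetrics(1.0, 1.0)
    return OverlapMetrics(dsc=2 * inter / (na + nb), jsc=inter / union)


def boundary_voxels(mask: np.ndarray) -> np.ndarray:
    """Mask voxels with at least one 6-neighbor outside (erosion difference)."""
    mask = np.asarray(mask, dtype=bool)
    eroded = ndimage.binary_erosion(
        mask, structure=ndimage.generate_binary_structure(3, 1), border_value=1
    )
    return mask & ~eroded


def surface_distances(a, b, voxel_size_mm: float | None = None) -> SurfaceMetrics:
    """ASSD and Hausdorff distance between mask boundaries, in mm."""
    av, bv = _mask_array(a), _mask_array(b)
    if av.shape != bv.shape:
        raise ValueError(f"mask shapes differ: {av.shape} vs {bv.shape}")
    if not (av.any() and bv.any()):
        raise ValueError("surface distances require two nonempty masks")
    if voxel_size_mm is None:
        voxel_size_mm = a.voxel_size_mm if isinstance(a, CompartmentMask) else 1.0
    pa = np.argwhere(boundary_voxels(av)).astype(float)
    pb = np.argwhere(boundary_voxels(bv)).astype(float)
    d_ab, _ = cKDTree(pb).query(pa)
    d_ba, _ = cKDTree(pa).query(pb)
    all_d = np.concatenate([d_ab, d_ba]) * voxel_size_mm
    return SurfaceMetrics(assd_mm=float(all_d.mean()), hausdorff_mm=float(all_d.max()))


# ---------------------------------------------------------------------------
# agreement analysis
# ---------------------------------------------------------------------------

@dataclass
class AgreementResult:
    bias: float
    loa_low: float
    loa_high: float
    slope: float
    slope_ci: tuple[float, float]
    intercept: float
    intercept_ci: tuple[float, float]
    r_squared: float


def bland_altman(pred, ref) -> tuple[float, tuple[float, float]]:
    """Mean error and 95% limits of agreement (bias +/- 1.96 SD, n-1 SD)."""
    pred = np.asarray(pred, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if pred.shape != ref.shape:
        raise ValueError("series lengths differ")
    if pred.size < 2:
        raise ValueError("need at least 2 paired values")
    errors = pred - ref
    bias = float(errors.mean())
    sd = float(errors.std(ddof=1))
    return bias, (bias - 1.96 * sd, bias + 1.96 * sd)


def linear_agreement(pred, ref) -> AgreementResult:
    """OLS of pred on ref with 1.96 SE confidence intervals and R^2."""
    pred = np.asarray(pred, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if pred.size != ref.size:
        raise ValueError("series lengths differ")
    if pred.size < 3:
        raise ValueError("need at least 3 paired values")
    if np.var(ref) == 0:
        raise ValueError("reference series has zero variance")
    model = sm.OLS(pred, sm.add_constant(ref)).fit()
    intercept, slope = model.params
    se_int, se_slope = model.bse
    bias, loa = bland_altman(pred, ref)
    return AgreementResult(
        bias=bias,
        loa_low=loa[0],
        loa_high=loa[1],
        slope=float(slope),
        slope_ci=(float(slope - 1.96 * se_slope), float(slope + 1.96 * se_slope)),
        intercept=float(intercept),
        intercept_ci=(float(intercept - 1.96 * se_int), float(intercept + 1.96 * se_int)),
        r_squared=float(model.rsquared),
    )


# ---------------------------------------------------------------------------
# precision statistics
# ---------------------------------------------------------------------------

@dataclass
class PrecisionResult:
    rms_sd: float
    rms_pct_cv: float
    lsc: float


def pair_sds(pairs) -> np.ndarray:
    """Per-pair standard deviations |x1 - x2| / sqrt(2)."""
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 1:
        raise ValueError("pairs must be an (n, 2) array with n >= 1")
    return np.abs(arr[:, 0] - arr[:, 1]) / np.sqrt(2.0)


def precision_stats(pairs, lsc_multiplier: float = LSC_MULTIPLIER) -> PrecisionResult:
    """RMS SD, RMS %CV (pair-mean denominator) and LSC over repeat pairs."""
    arr = np.asarray(pairs, dtype=float)
    sds = pair_sds(arr)
    means = arr.mean(axis=1)
    if np.any(means <= 0):
        raise ValueError("pair means must be > 0 for %CV")
    rms_sd = float(np.sqrt(np.mean(sds**2)))
    pct_cv = 100.0 * sds / means
    return PrecisionResult(
        rms_sd=rms_sd,
        rms_pct_cv=float(np.sqrt(np.mean(pct_cv**2))),
        lsc=lsc_multiplier * rms_sd,
    )


@dataclass
class PrecisionComparison:
    normality_p_a: float
    normality_p_b: float
    wilcoxon_statistic: float
    p_value: float
    significant: bool
    median_sd_difference: float


def compare_precision(pred_pairs, ref_pairs, alpha: float = 0.05) -> PrecisionComparison:
    """Compare two protocols' per-participant repeat-scan SDs.

    D'Agostino-Pearson normality check on each protocol's SDs, then a paired
    two-sided Wilcoxon signed-rank test (zero differences kept, Pratt
    method) at the given significance level.
    """
    sds_a = pair_sds(pred_pairs)
    sds_b = pair_sds(ref_pairs)
    if sds_a.size != sds_b.size:
        raise ValueError("protocols must have the same number of pairs")
    if sds_a.size < 5:
        warnings.warn(
            "fewer than 5 pairs: large-sample tests are unreliable", stacklevel=2
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # normaltest warns for tiny n
        norm_a = stats.normaltest(sds_a).pvalue if sds_a.size >= 8 else np.nan
        norm_b = stats.normaltest(sds_b).pvalue if sds_b.size >= 8 else np.nan
    diffs = sds_a - sds_b
    if np.all(diffs == 0):
        statistic, p_value = 0.0, 1.0
    else:
        res = stats.wilcoxon(sds_a, sds_b, zero_method="pratt", alternative="two-sided")
        statistic, p_value = float(res.statistic), float(res.pvalue)
    return PrecisionComparison(
        normality_p_a=float(norm_a),
        normality_p_b=float(norm_b),
        wilcoxon_statistic=statistic,
        p_value=p_value,
        significant=bool(p_value < alpha),
        median_sd_difference=float(np.median(diffs)),
    )


# ---------------------------------------------------------------------------
# compartment summaries and sub-grouping
# ---------------------------------------------------------------------------

def compartment_summaries(vol: DensityVolume, seg: SegmentationPair) -> pd.DataFrame:
    """Voxel counts, mean densities and mean cross-sectional areas per compartment."""
    if vol.shape != seg.shape:
        raise ValueError(f"volume shape {vol.shape} != segmentation shape {seg.shape}")
    rows = []
    area_per_voxel = vol.voxel_size_mm**2
    for name, mask in (
        ("cortical", seg.cortical.voxels),
        ("trabecular", seg.trabecular.voxels),
    ):
        count = int(mask.sum())
        mean_density = float(vol.voxels[mask].mean()) if count else np.nan
        mean_area = float(mask.sum(axis=(1, 2)).mean() * area_per_voxel)
        rows.append(
            {
                "compartment": name,
                "voxel_count": count,
                "mean_density_mgHA_cm3": mean_density,
                "mean_area_mm2": mean_area,
            }
        )
    return pd.DataFrame(rows)


def quartile_subgroup(
    table: pd.DataFrame, column: str, which: str = "bottom"
) -> pd.DataFrame:
    """Rows in the bottom or top quartile of ``column``.

    Used for the adverse-case sub-analyses: 'low cortical thickness' is the
    bottom Ct.Th quartile and 'high cortical porosity' the top Ct.Po
    quartile of an externally computed morphometric parameter table.
    """
    if which not in ("bottom", "top"):
        raise ValueError("which must be 'bottom' or 'top'")
    values = table[column]
    if which == "bottom":
        return table[values <= values.quantile(0.25)]
    return table[values >= values.quantile(0.75)]
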