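"""Evaluation suite: masked error statistics, lesion SUV analysis with
bone / in-plane classification, and an exact Wilcoxon signed-rank test.

Error statistics use the population (1/n) standard deviation so the
decomposition RMSE^2 = mean_error^2 + std_error^2 is an exact identity.

Lesions are classified as *bone* when any lesion voxel lies within
10 mm (Euclidean, in physical units) of the bone mask, and as
*in-plane* with an implant when the lesion's axial-slice range
intersects the implant's slice range.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd
from scipy import ndimage

from .humu import Mask
from .phantom import LesionROI

__all__ = ["ErrorStats", "masked_error_stats", "classify_lesion", "suvmax",
           "lesion_mean_suv", "wilcoxon_signed_rank", "lesion_report"]


@dataclass(frozen=True)
class ErrorStats:
    rmse: float
    mae: float
    mean_error: float
    std_error: float
    n_voxels: int


def _mask_array(mask) -> np.ndarray:
    return np.asarray(mask.data if isinstance(mask, Mask) else mask, dtype=bool)


def masked_error_stats(est, ref, mask) -> ErrorStats:
    """Population error statistics of est - ref over the mask."""
    est = np.asarray(est, dtype=np.float64)
    ref = np.asarray(ref, dtype=np.float64)
    m = _mask_array(mask)
    if est.shape != ref.shape or est.shape != m.shape:
        raise ValueError("est, ref and mask grids differ")
    if not m.any():
        raise ValueError("empty evaluation mask")
    err = est[m] - ref[m]
    mean = float(err.mean())
    std = float(err.std())            # population (1/n)
    return ErrorStats(rmse=float(np.sqrt((err ** 2).mean())),
                      mae=float(np.abs(err).mean()),
                      mean_error=mean, std_error=std,
                      n_voxels=int(err.size))


def classify_lesion(lesion: LesionROI, bone_mask, implant_mask,
                    voxel_size_mm, bone_distance_mm: float = 10.0
                    ) -> tuple[str, str]:
    """(bone|soft, in-plane|out-plane) classification of a lesion.

    Bone iff the lesion touches bone or any lesion voxel lies within
    ``bone_distance_mm`` of a bone voxel (distance transform in mm);
    in-plane iff the lesion's axial-slice range overlaps the implant's.
    """
    if lesion.n_voxels == 0:
        raise ValueError("empty lesion")
    bone = _mask_array(bone_mask)
    implant = _mask_array(implant_mask)
    if bone.any():
        dist = ndimage.distance_transform_edt(~bone, sampling=voxel_size_mm)
        klass = "bone" if dist[lesion.indices].min() <= bone_distance_mm else "soft"
    else:
        klass = "soft"
    if implant.any():
        imp_slices = np.unique(np.nonzero(implant)[0])
        les_slices = np.unique(lesion.indices[0])
        plane = ("in-plane" if np.intersect1d(imp_slices, les_slices).size
                 else "out-plane")
    else:
        plane = "out-plane"
    return klass, plane


def suvmax(pet, lesion: LesionROI, suv_scale: float = 1.0) -> float:
    """Maximum SUV-scaled activity over the lesion voxels."""
    if lesion.n_voxels == 0:
        raise ValueError("empty lesion")
    return float(np.asarray(pet)[lesion.indices].max() * suv_scale)


def lesion_mean_suv(pet, lesion: LesionROI, suv_scale: float = 1.0) -> float:
    if lesion.n_voxels == 0:
        raise ValueError("empty lesion")
    return float(np.asarray(pet)[lesion.indices].mean() * suv_scale)


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank test

def _exact_wplus_distribution(ranks2: np.ndarray) -> np.ndarray:
    """Distribution of 2*W+ over all 2^n sign assignments, by dynamic
    programming; ``ranks2`` are doubled midranks (integers)."""
    total = int(ranks2.sum())
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in ranks2:
        nxt = dist.copy()
        nxt[r:] += dist[:total + 1 - r]
        dist = nxt
    return dist / dist.sum()


def wilcoxon_signed_rank(a, b) -> float:
    """Two-sided Wilcoxon signed-rank p-value for paired samples.

    Zero differences are dropped before ranking; ties receive midranks.
    Exact for n <= 25 (the full sign-assignment distribution, computed by
    dynamic programming, equivalent to enumerating all 2^n assignments);
    a tie-corrected normal approximation above.  All-zero differences
    give p = 1.0 by convention.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1 or a.size < 1:
        raise ValueError("need equal-length 1-D paired samples")
    d = a - b
    d = d[d != 0]
    n = d.size
    if n == 0:
        return 1.0
    # midranks of |d|
    order = np.argsort(np.abs(d), kind="stable")
    absd = np.abs(d)[order]
    ranks = np.empty(n)
    i = 0
    while i < n:
        j = i
        while j + 1 < n and absd[j + 1] == absd[i]:
            j += 1
        ranks[order[i:j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    wplus = float(ranks[d > 0].sum())
    if n <= 25:
        ranks2 = np.rint(2.0 * ranks).astype(np.int64)
        dist = _exact_wplus_distribution(ranks2)
        w2 = int(round(2.0 * wplus))
        lo = dist[:w2 + 1].sum()
        hi = dist[w2:].sum()
        return float(min(1.0, 2.0 * min(lo, hi)))
    mean = n * (n + 1) / 4.0
    # tie correction on the variance
    _, counts = np.unique(ranks, return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - (counts ** 3 - counts).sum() / 48.0
    from scipy.stats import norm
    z = (wplus - mean) / np.sqrt(var)
    return float(min(1.0, 2.0 * norm.sf(abs(z))))


# ---------------------------------------------------------------------------
# lesion reports

def lesion_report(reference_pet, method_pets: dict[str, np.ndarray],
                  lesions: list[LesionROI], bone_mask, implant_mask,
                  voxel_size_mm, suv_scale: float = 1.0) -> pd.DataFrame:
    """One row per (lesion, method): SUVmax, mean SUV, class, implant
    relation, and the SUVmax bias relative to the reference
    reconstruction."""
    rows = []
    for li, roi in enumerate(lesions):
        klass, plane = classify_lesion(roi, bone_mask, implant_mask,
                                       voxel_size_mm)
        ref_max = suvmax(reference_pet, roi, suv_scale)
        for method, pet in method_pets.items():
            smax = suvmax(pet, roi, suv_scale)
            rows.append({
                "lesion": li, "method": method, "class": klass,
                "plane": plane, "suvmax": smax,
                "mean_suv": lesion_mean_suv(pet, roi, suv_scale),
                "ref_suvmax": ref_max,
                "suvmax_bias": (smax - ref_max) / ref_max if ref_max else np.nan,
            })
    return pd.DataFrame(rows)


def paired_suvmax_pvalues(report: pd.DataFrame) -> pd.DataFrame:
    """Wilcoxon signed-rank p-values of per-lesion SUVmax between each
    pair of methods, per (class, plane) stratum."""
    rows = []
    methods = sorted(report["method"].unique())
    for (klass, plane), grp in report.groupby(["class", "plane"]):
        wide = grp.pivot(index="lesion", columns="method", values="suvmax")
        for m1, m2 in product(methods, methods):
            if m1 >= m2:
                continue
            p = wilcoxon_signed_rank(wide[m1].to_numpy(), wide[m2].to_numpy())
            rows.append({"class": klass, "plane": plane,
                         "method_a": m1, "method_b": m2, "p_value": p})
    return pd.DataFrame(rows)
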