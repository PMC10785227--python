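"""CT-to-attenuation conversion and body/evaluation masks.

Hounsfield units are mapped to 511-keV linear attenuation coefficients
(cm^-1) with the standard piecewise-linear (bilinear) model used for
CT-based attenuation correction: one slope for soft-tissue-like HU
below a breakpoint, a shallower slope for bone-like HU above it,
anchored so that mu(-1000 HU) = 0.

The shipped default coefficients correspond to a 120-kVp acquisition:
slope 9.6e-5 cm^-1/HU below the +47 HU breakpoint (so water at 0 HU
maps to 0.096 cm^-1) and 5.1e-5 cm^-1/HU above it.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy import ndimage

__all__ = ["BilinearModel", "MaskKind", "Mask", "hu_to_mu", "body_mask",
           "eval_masks", "remove_arms"]

WATER_MU_511 = 0.096  # cm^-1


@dataclass(frozen=True)
class BilinearModel:
    """Continuous, non-decreasing piecewise-linear HU -> mu map.

    mu(h) = slope_below * (h + 1000)                      for h <= breakpoint
          = mu(breakpoint) + slope_above * (h - breakpoint) otherwise,
    clamped to 0 below -1000 HU.
    """

    breakpoint_hu: float = 47.0
    slope_below: float = 9.6e-5   # cm^-1 per HU
    slope_above: float = 5.1e-5   # cm^-1 per HU

    def __post_init__(self):
        if self.slope_below < 0 or self.slope_above < 0:
            raise ValueError("slopes must be non-negative")

    @property
    def mu_at_breakpoint(self) -> float:
        return self.slope_below * (self.breakpoint_hu + 1000.0)

    def __call__(self, hu):
        hu = np.asarray(hu, dtype=np.float64)
        below = self.slope_below * (hu + 1000.0)
        above = self.mu_at_breakpoint + self.slope_above * (hu - self.breakpoint_hu)
        mu = np.where(hu <= self.breakpoint_hu, below, above)
        return np.maximum(mu, 0.0)


def hu_to_mu(ct, model: BilinearModel | None = None) -> np.ndarray:
    """Convert a HU volume to a 511-keV attenuation map (cm^-1)."""
    ct = np.asarray(ct, dtype=np.float64)
    if not np.all(np.isfinite(ct)):
        raise ValueError("CT volume contains non-finite HU values")
    model = model or BilinearModel()
    return model(ct)


class MaskKind(str, Enum):
    BODY = "body"
    HU_EVAL = "hu_eval"
    MU_EVAL = "mu_eval"


@dataclass
class Mask:
    data: np.ndarray  # boolean
    kind: MaskKind

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=bool)

    def __array__(self, dtype=None, copy=None):
        return np.asarray(self.data, dtype=dtype)

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())


def _erosion_structure(shape):
    # 1-voxel-radius ball in index space (6-connectivity in 3D); for
    # single-slice stacks erode in-plane only so the slice survives.
    if len(shape) == 3 and shape[0] == 1:
        st = np.zeros((1, 3, 3), dtype=bool)
        st[0] = ndimage.generate_binary_structure(2, 1)
        return st
    return ndimage.generate_binary_structure(len(shape), 1)


def body_mask(pct, threshold_hu: float = -400.0) -> Mask:
    """Body mask from a (pseudo-)CT: threshold > -400 HU, erode by a
    1-voxel-radius ball, then fill holes per axial slice.

    Raises ``ValueError`` when no body remains (e.g. an all-air volume or
    only isolated speckles that erosion removes).
    """
    pct = np.asarray(pct, dtype=np.float64)
    raw = pct > threshold_hu
    eroded = ndimage.binary_erosion(raw, structure=_erosion_structure(pct.shape))
    if not eroded.any():
        raise ValueError("no body found: mask is empty after thresholding/erosion")
    if eroded.ndim == 3:
        filled = np.stack([ndimage.binary_fill_holes(sl) for sl in eroded])
    else:
        filled = ndimage.binary_fill_holes(eroded)
    return Mask(filled, MaskKind.BODY)


def remove_arms(mask: Mask) -> Mask:
    """Arm-removal hook.

    The phantoms have no arms, so this is an intentional no-op kept so the
    mask-refinement pipeline has the same stages as a clinical workflow.
    """
    return mask


def eval_masks(ct_ref, mu_ref,
               hu_threshold: float = -950.0,
               mu_threshold: float = 0.01) -> tuple[Mask, Mask]:
    """Evaluation masks: HU comparisons over {ct_ref > -950 HU} (excludes
    air), attenuation-map comparisons over {mu_ref > 0.01 cm^-1}.  Both
    thresholds are strict inequalities."""
    ct_ref = np.asarray(ct_ref)
    mu_ref = np.asarray(mu_ref)
    if ct_ref.shape != mu_ref.shape:
        raise ValueError("ct_ref and mu_ref grids differ")
    return (Mask(ct_ref > hu_threshold, MaskKind.HU_EVAL),
            Mask(mu_ref > mu_threshold, MaskKind.MU_EVAL))
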