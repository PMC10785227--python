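"""Predictive variance -> spatially varying prior strength.

The predictive variance map (HU^2) from Monte Carlo dropout is mapped
through a fixed sigmoidal transform to a weight in (0, 1)::

    w(r) = 1 / (1 + exp(0.1 * (sigma^2(r)/1000 - 25)))

whose transition band covers in-body variances of 0 to ~1e5 HU^2
(standard deviations up to ~300 HU) and saturates at the variances seen
in signal-void/artifact regions.  The weight map is then linearly
rescaled over in-body voxels to the prior-strength range
[beta_min, beta_max] = [1e3, 5e6] and zeroed outside the body, giving
the per-voxel regularization strength beta_MR used by the
attenuation update: low beta where the pseudo-CT is uncertain (the
emission data dominates there), high beta where it is trusted.

The default "minmax" scaling maps the in-body minimum and maximum
weight exactly onto the endpoints, so the printed range is attained;
the alternative "fixed" mapping sends w in (0,1) affinely onto the
range without referencing the data (and never attains beta_max, since
w <= 1/(1+e^-2.5) ~ 0.9241 for any non-negative variance).
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.special import expit

from .humu import Mask

__all__ = ["BETA_MIN", "BETA_MAX", "variance_to_weight", "weight_to_beta"]

BETA_MIN = 1e3
BETA_MAX = 5e6


def variance_to_weight(var) -> np.ndarray:
    """Sigmoidal weight w in (0, 1), strictly decreasing in the variance.

    Evaluated with overflow-safe arithmetic; w(25000 HU^2) = 0.5 exactly.
    """
    var = np.asarray(var, dtype=np.float64)
    if not np.all(np.isfinite(var)):
        raise ValueError("variance map contains non-finite values")
    if np.any(var < 0):
        raise ValueError("variance map contains negative values")
    return expit(-(0.1 * (var / 1000.0 - 25.0)))


def weight_to_beta(w, body, beta_min: float = BETA_MIN,
                   beta_max: float = BETA_MAX,
                   scaling: str = "minmax") -> np.ndarray:
    """Rescale a weight map to prior strengths; zero outside the body.

    With ``scaling="minmax"`` the in-body minimum and maximum of ``w`` map
    exactly to ``beta_min`` and ``beta_max``.  A constant in-body weight
    map carries no contrast to rescale, and every in-body voxel is
    assigned ``beta_max`` with a warning.
    """
    w = np.asarray(w, dtype=np.float64)
    body_arr = np.asarray(body.data if isinstance(body, Mask) else body, dtype=bool)
    if w.shape != body_arr.shape:
        raise ValueError("weight map and body mask grids differ")
    if not body_arr.any():
        raise ValueError("empty body mask")
    if np.any((w <= 0) | (w >= 1)):
        raise ValueError("weights must lie strictly in (0, 1)")
    if beta_min >= beta_max:
        raise ValueError("beta_min must be below beta_max")

    beta = np.zeros_like(w)
    win = w[body_arr]
    if scaling == "minmax":
        lo, hi = win.min(), win.max()
        if hi == lo:
            warnings.warn("constant in-body weight map: assigning beta_max "
                          "to every in-body voxel", stacklevel=2)
            beta[body_arr] = beta_max
        else:
            beta[body_arr] = beta_min + (win - lo) / (hi - lo) * (beta_max - beta_min)
    elif scaling == "fixed":
        beta[body_arr] = beta_min + win * (beta_max - beta_min)
    else:
        raise ValueError(f"unknown scaling {scaling!r} (use 'minmax' or 'fixed')")
    return beta
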