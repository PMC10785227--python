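"""Emission reconstruction engines.

Four reconstruction modes share one machinery:

* ``osem_reconstruct`` — TOF-OSEM with a fixed attenuation map (the
  comparator reconstructions: CT-based or pseudo-CT-based mu-maps).
* ``mlaa_run(mode="naive")`` — joint activity/attenuation estimation
  with no pseudo-CT prior (beta_MR = 0 everywhere).
* ``mlaa_run(mode="regularized_uniform")`` — a spatially constant
  beta_MR pulling mu toward the pseudo-CT-derived prior mu_MR.
* ``mlaa_run(mode="upct")`` — the uncertainty-weighted variant: the
  per-voxel BetaMap from the predictive-variance pipeline modulates the
  prior strength, so mu is pinned to mu_MR where the pseudo-CT is
  trusted and estimated from the emission data where it is not.

Each outer iteration performs one ordered-subsets EM pass over the
activity followed by several ordered-subsets transmission-style (OSTR)
passes over the attenuation.  The attenuation update maximizes the
Poisson emission log-likelihood in mu (activity fixed) penalized by

    R(mu) = sum_i beta_i/2 (mu_i - mu_MR_i)^2  +  beta_smooth * R_smooth(mu)

via separable paraboloidal surrogates: per-line curvatures are inflated
to cover a trust region of half-width ``step_clamp`` in mu, steps are
clamped to that region, and the quadratic priors enter through their
own separable surrogates.  With a single subset every update then
increases the penalized objective monotonically; ordered subsets trade
that guarantee for speed exactly as in emission OSEM.

R_smooth is a first-order quadratic penalty over the in-plane
4-neighbourhood, restricted to voxel pairs inside the body mask.
Out-of-body voxels take part in neither updates nor priors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .humu import WATER_MU_511, Mask
from .petsim import (ScannerGeometry, Sinogram, SubsetPartition,
                     attenuation_factors, back_project, forward_project)

__all__ = ["ReconConfig", "ReconResult", "osem_activity_update",
           "ostr_attenuation_update", "penalized_objective", "mlaa_run",
           "osem_reconstruct"]

_TINY = 1e-30


@dataclass(frozen=True)
class ReconConfig:
    """Joint-reconstruction schedule and bounds.

    The reference schedule is 5 outer iterations of (1 OSEM pass + 5
    OSTR passes) with 28 subsets; 2-D desk runs default to 8 subsets.
    ``mu_max`` (cm^-1) bounds the attenuation update from above, safely
    over any implant value at 511 keV; ``step_clamp`` is the OSTR trust
    region half-width per subset update (cm^-1).
    """

    outer_iterations: int = 5
    n_subsets: int = 8
    osem_passes_per_outer: int = 1
    ostr_passes_per_outer: int = 5
    beta_smooth: float = 2e4
    mu_max: float = 0.5
    mu_init_naive: float = WATER_MU_511
    background: float = 0.0
    step_clamp: float = 0.02
    osem_iterations: int = 2   # for fixed-mu osem_reconstruct

    def __post_init__(self):
        if min(self.outer_iterations, self.n_subsets,
               self.osem_passes_per_outer, self.ostr_passes_per_outer) < 1:
            raise ValueError("iteration counts must be positive")
        if self.mu_max <= 0 or self.step_clamp <= 0:
            raise ValueError("bounds must be positive")


@dataclass
class ReconResult:
    activity: np.ndarray
    mu: np.ndarray
    objective_trace: np.ndarray
    config: ReconConfig
    mode: str = ""


def _mask_array(mask) -> np.ndarray:
    return np.asarray(mask.data if isinstance(mask, Mask) else mask, dtype=bool)


# ---------------------------------------------------------------------------
# activity update (TOF-OSEM)

def osem_activity_update(lam, data, mu, geom: ScannerGeometry,
                         partition: SubsetPartition | None = None,
                         background: float = 0.0) -> np.ndarray:
    """One full ordered-subsets EM pass over the activity (mu fixed).

    Per subset s: lam <- lam * P_s^T[a y / (a P_s lam + b)] / P_s^T[a].
    Multiplicative, hence non-negativity preserving; voxels with zero
    subset sensitivity are frozen.
    """
    lam = np.asarray(lam, dtype=np.float64).copy()
    y = data.data if isinstance(data, Sinogram) else np.asarray(data)
    partition = partition or geom.partition()
    for angles in partition:
        att = attenuation_factors(mu, geom, angles=angles)
        proj = forward_project(lam, geom, tof=True, angles=angles)
        ybar = att[..., None] * proj + background
        ysub = y[list(angles)]
        ratio = np.divide(ysub, ybar, out=np.zeros_like(ybar),
                          where=ybar > 0)
        num = back_project(att[..., None] * ratio, geom, tof=True,
                           angles=angles)
        sens = back_project(att, geom, tof=False, angles=angles)
        np.multiply(lam, np.divide(num, sens, out=np.ones_like(sens),
                                   where=sens > 0), out=lam)
    return lam


# ---------------------------------------------------------------------------
# attenuation update (OSTR-style separable paraboloidal surrogates)

def _smooth_neighbor_terms(mu: np.ndarray, body: np.ndarray):
    """Gradient of the pairwise quadratic smoothness penalty
    (1/2) sum_pairs (mu_j - mu_k)^2 over in-body 4-neighbour pairs, and
    the in-body neighbour count per voxel."""
    grad = np.zeros_like(mu)
    deg = np.zeros_like(mu)
    for axis in (0, 1):
        for shift in (1, -1):
            nb_mu = np.roll(mu, shift, axis=axis)
            nb_body = np.roll(body, shift, axis=axis)
            # roll wraps around; mask out the wrapped border
            sl = [slice(None)] * 2
            sl[axis] = slice(0, 1) if shift == 1 else slice(-1, None)
            nb_body = nb_body.copy()
            nb_body[tuple(sl)] = False
            pair = body & nb_body
            grad[pair] += mu[pair] - nb_mu[pair]
            deg += pair
    return grad, deg


def _line_lengths(geom: ScannerGeometry, angles):
    A0 = geom.system_matrix(False, angles)
    return np.asarray(A0 @ np.ones(geom.n_pixels)).reshape(len(angles),
                                                           geom.n_radial)


def ostr_attenuation_update(mu, data, lam, betamap, mu_prior,
                            beta_smooth: float, geom: ScannerGeometry,
                            body, partition: SubsetPartition | None = None,
                            mu_max: float = 0.5, step_clamp: float = 0.02,
                            background: float = 0.0) -> np.ndarray:
    """One full ordered-subsets pass over the attenuation (activity fixed).

    Maximizes the penalized Poisson emission log-likelihood in mu with a
    trust-region separable-paraboloidal-surrogate step per subset; mu is
    clamped to [0, mu_max] and frozen outside the body mask.
    """
    mu = np.asarray(mu, dtype=np.float64).copy()
    lam = np.asarray(lam, dtype=np.float64)
    betamap = np.asarray(betamap, dtype=np.float64)
    if np.any(betamap < 0):
        raise ValueError("beta map must be non-negative")
    mu_prior = np.asarray(mu_prior, dtype=np.float64)
    body = _mask_array(body)
    y = data.data if isinstance(data, Sinogram) else np.asarray(data)
    partition = partition or geom.partition()
    m_sub = float(len(partition))

    for angles in partition:
        A0 = geom.system_matrix(False, angles)
        ell = np.asarray(A0 @ mu.ravel())
        abar = np.exp(-ell)
        proj = forward_project(lam, geom, tof=True, angles=angles)
        q = proj.reshape(-1, geom.n_tof)
        ysub = y[list(angles)].reshape(-1, geom.n_tof)
        aq = abar[:, None] * q
        ybar = aq + background
        ratio = np.divide(ysub, ybar, out=np.zeros_like(ybar), where=ybar > 0)
        # d/d(ell) of sum_t [y log ybar - ybar]
        grad_line = ((1.0 - ratio) * aq).sum(axis=1)
        # trust-region curvature: |d2/d(ell)2| = sum_t aq*(1 - y*b/ybar^2)
        # <= sum_t aq; inflate by exp(L * step) to cover the trust region
        L = np.asarray(A0 @ np.ones(geom.n_pixels))
        curv_line = aq.sum(axis=1) * np.exp(np.minimum(L * step_clamp, 50.0))
        grad_mu = np.asarray(A0.T @ grad_line).reshape(geom.img_shape)
        denom_mu = np.asarray(A0.T @ (curv_line * L)).reshape(geom.img_shape)

        sm_grad, deg = _smooth_neighbor_terms(mu, body)
        grad_r = betamap * (mu - mu_prior) + beta_smooth * sm_grad
        curv_r = betamap + 2.0 * beta_smooth * deg

        num = m_sub * grad_mu - grad_r
        den = m_sub * denom_mu + curv_r
        step = np.divide(num, den, out=np.zeros_like(num), where=den > _TINY)
        np.clip(step, -step_clamp, step_clamp, out=step)
        mu_new = np.clip(mu + step, 0.0, mu_max)
        mu[body] = mu_new[body]
        if not np.all(np.isfinite(mu)):
            raise FloatingPointError("non-finite attenuation update")
    return mu


# ---------------------------------------------------------------------------
# objective

def penalized_objective(lam, mu, data, geom: ScannerGeometry,
                        betamap, mu_prior, beta_smooth: float, body,
                        background: float = 0.0) -> float:
    """Poisson log-likelihood sum[y log ybar - ybar] (constants dropped)
    minus the quadratic priors."""
    y = data.data if isinstance(data, Sinogram) else np.asarray(data)
    att = attenuation_factors(mu, geom)
    ybar = att[..., None] * forward_project(lam, geom, tof=True) + background
    logterm = np.where(y > 0, y * np.log(np.maximum(ybar, _TINY)), 0.0)
    ll = float((logterm - ybar).sum())
    body = _mask_array(body)
    betamap = np.asarray(betamap, dtype=np.float64)
    mu = np.asarray(mu, dtype=np.float64)
    prior = 0.5 * float((betamap * (mu - np.asarray(mu_prior)) ** 2)[body].sum())
    sm = 0.0
    for axis in (0, 1):
        d = np.diff(mu, axis=axis)
        pb = _mask_array(body)
        pair = pb.take(range(1, mu.shape[axis]), axis=axis) & \
            pb.take(range(0, mu.shape[axis] - 1), axis=axis)
        sm += float((d[pair] ** 2).sum())
    return ll - prior - beta_smooth * 0.5 * sm


# ---------------------------------------------------------------------------
# drivers

def _uniform_in_body(body: np.ndarray, value: float = 1.0) -> np.ndarray:
    lam = np.zeros(body.shape)
    lam[body] = value
    return lam


def _check_slice_inputs(data, geom):
    y = data.data if isinstance(data, Sinogram) else np.asarray(data)
    if y.ndim == 3:
        return y[None], True
    if y.ndim == 4:
        return y, False
    raise ValueError("expected a TOF sinogram (angle, radial, tof) or a "
                     "stack of them")


def _as_stack(arr, n_slices, geom):
    arr = np.asarray(arr)
    if arr.ndim == 2:
        return np.broadcast_to(arr, (n_slices,) + arr.shape)
    if arr.ndim == 3 and arr.shape[0] == n_slices:
        return arr
    raise ValueError("per-slice input has wrong shape")


def mlaa_run(data, mode: str, cfg: ReconConfig | None = None,
             geom: ScannerGeometry | None = None, body=None,
             betamap=None, mu_prior=None, beta_uniform: float | None = None
             ) -> ReconResult:
    """Joint activity/attenuation estimation.

    ``mode`` is one of ``"naive"`` (beta_MR = 0, water-equivalent mu
    init), ``"regularized_uniform"`` (constant ``beta_uniform`` toward
    ``mu_prior``), or ``"upct"`` (per-voxel ``betamap`` toward
    ``mu_prior``).  ``body`` bounds all updates and priors.  Thin stacks
    are reconstructed slice by slice; the objective trace (one entry per
    outer iteration) sums over slices.
    """
    cfg = cfg or ReconConfig()
    if geom is None:
        geom = data.geom if isinstance(data, Sinogram) else None
    if geom is None:
        raise ValueError("geometry required")
    ystack, squeeze = _check_slice_inputs(data, geom)
    n_slices = ystack.shape[0]
    if body is None:
        raise ValueError("body mask required")
    body_stack = _as_stack(_mask_array(body), n_slices, geom)

    if mode == "naive":
        betamap_stack = np.zeros((n_slices,) + geom.img_shape)
        prior_stack = np.zeros((n_slices,) + geom.img_shape)
        mu0 = np.where(body_stack, cfg.mu_init_naive, 0.0)
    elif mode == "regularized_uniform":
        if beta_uniform is None or mu_prior is None:
            raise ValueError("regularized_uniform mode needs beta_uniform "
                             "and mu_prior")
        prior_stack = np.array(_as_stack(mu_prior, n_slices, geom), dtype=float)
        betamap_stack = np.where(body_stack, float(beta_uniform), 0.0)
        mu0 = prior_stack.copy()
    elif mode == "upct":
        if betamap is None or mu_prior is None:
            raise ValueError("upct mode needs betamap and mu_prior")
        betamap_stack = np.array(_as_stack(betamap, n_slices, geom), dtype=float)
        prior_stack = np.array(_as_stack(mu_prior, n_slices, geom), dtype=float)
        mu0 = prior_stack.copy()
    else:
        raise ValueError(f"unknown mode {mode!r}")

    partition = geom.partition(cfg.n_subsets)
    lam_out = np.empty((n_slices,) + geom.img_shape)
    mu_out = np.empty((n_slices,) + geom.img_shape)
    trace = np.zeros(cfg.outer_iterations)
    for s in range(n_slices):
        lam = _uniform_in_body(body_stack[s])
        mu = np.where(body_stack[s], mu0[s], 0.0)
        ysl = ystack[s]
        for it in range(cfg.outer_iterations):
            for _ in range(cfg.osem_passes_per_outer):
                lam = osem_activity_update(lam, ysl, mu, geom, partition,
                                           cfg.background)
            for _ in range(cfg.ostr_passes_per_outer):
                mu = ostr_attenuation_update(
                    mu, ysl, lam, betamap_stack[s], prior_stack[s],
                    cfg.beta_smooth, geom, body_stack[s], partition,
                    cfg.mu_max, cfg.step_clamp, cfg.background)
            trace[it] += penalized_objective(
                lam, mu, ysl, geom, betamap_stack[s], prior_stack[s],
                cfg.beta_smooth, body_stack[s], cfg.background)
        lam_out[s] = lam
        mu_out[s] = mu
    if not np.all(np.isfinite(trace)):
        raise FloatingPointError("non-finite objective trace")
    if squeeze:
        lam_out, mu_out = lam_out[0], mu_out[0]
    return ReconResult(activity=lam_out, mu=mu_out, objective_trace=trace,
                       config=cfg, mode=mode)


def osem_reconstruct(data, mu, cfg: ReconConfig | None = None,
                     geom: ScannerGeometry | None = None, body=None,
                     n_iterations: int | None = None) -> np.ndarray:
    """TOF-OSEM with a fixed attenuation map (deterministic comparator).

    Runs ``cfg.osem_iterations`` full passes (reference default: 2
    iterations with the configured subsets).
    """
    cfg = cfg or ReconConfig()
    if geom is None:
        geom = data.geom if isinstance(data, Sinogram) else None
    if geom is None:
        raise ValueError("geometry required")
    ystack, squeeze = _check_slice_inputs(data, geom)
    n_slices = ystack.shape[0]
    mu_stack = _as_stack(mu, n_slices, geom)
    if body is None:
        body_stack = np.ones((n_slices,) + geom.img_shape, dtype=bool)
    else:
        body_stack = _as_stack(_mask_array(body), n_slices, geom)
    partition = geom.partition(cfg.n_subsets)
    n_it = n_iterations if n_iterations is not None else cfg.osem_iterations
    out = np.empty((n_slices,) + geom.img_shape)
    for s in range(n_slices):
        lam = _uniform_in_body(body_stack[s])
        for _ in range(n_it):
            lam = osem_activity_update(lam, ystack[s], mu_stack[s], geom,
                                       partition, cfg.background)
        out[s] = lam
    return out[0] if squeeze else out
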