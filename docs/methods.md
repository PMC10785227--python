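# Methods

This note documents the models, numerical choices and limitations of
`uqmlaa`: an end-to-end desk-scale implementation of uncertainty-guided
pseudo-CT priors for joint PET activity/attenuation estimation
(UpCT-MLAA) on synthetic pelvis phantoms.

## Problem setting

Attenuation correction for PET/MRI needs a 511-keV attenuation map
(μ-map, cm⁻¹) that MRI cannot measure directly.  A network can
synthesize a pseudo-CT from Dixon-type MR channels and convert it to a
μ-map, but it fails silently wherever the MR data are unlike the
training distribution — most dramatically in the signal void around a
metal implant, which a CT would show as a high-HU object.  Joint
estimation of activity and attenuation from the TOF emission data
(MLAA) can recover such structures but is noisy where the emission data
carry little information.  The method combines both: Monte Carlo
dropout turns the pseudo-CT network into an approximate Bayesian
predictor whose per-voxel predictive variance modulates, through a
fixed sigmoid and a rescaling, the strength βMR of a quadratic prior
that pulls the MLAA attenuation estimate toward the pseudo-CT-derived
μ-map.  Where the network is confident, μ is pinned to the prior; where
it is not (implants, gas, bone), the emission data dominate.

## Synthetic phantoms (`phantom`)

Real paired MR/CT/PET pelvis data cannot ship with the package, so a
seeded generator produces cases with the statistical structure the
method needs:

* Geometry: thin axial stacks, default one 96×96 slice at 2.5 mm.
  An elliptical body with a subcutaneous fat rind, soft-tissue
  interior, two iliac-like and one sacrum-like bone, and two bowel-gas
  pockets; per-case geometry jitter of ±6 % emulates anatomical
  variability.
* CT: per-class truncated-Gaussian HU (air exactly −1000; fat
  −100 ± 15; soft 40 ± 12; bone 950 ± 120 truncated to 700–1200).
  The HU jitter is i.i.d. and therefore partly unlearnable — a stand-in
  for CT noise that gives the training loss a floor.
* MR: three channels (in-phase, fat-fraction, water-fraction analogs)
  computed from tissue class, lightly smoothed, plus additive Gaussian
  noise (σ = 0.02).  Bone is assigned almost no MR signal
  (in-phase 0.08), overlapping air within the noise: distinguishing
  cortical bone from gas requires spatial context, exactly the
  ambiguity whose resolution the predictive uncertainty should expose.
  The bowel-gas pockets put "no signal inside the body" into the
  training distribution with *two* conflicting HU interpretations
  (−1000 vs ~950), which is what makes the implant void produce
  disagreeing Monte Carlo samples rather than a confident guess.
* Activity: per-class uptake (soft 1.0, bone 0.5, fat 0.2, air/implant
  0) with spherical lesions as multiplicative hot spots (default ×4).
* Metal artifact: the implant core is stamped at the configured HU
  (≥ 3000) and the MR channels are blanked (all values < 0.05) inside a
  halo larger than the core; the CT additionally receives seeded radial
  streak perturbations confined to the halo.  This is a pattern
  generator, not a CT physics simulation — only the MR/CT discrepancy
  matters to the method.  Ground-truth activity is unchanged.

What the phantoms do *not* contain: arms and FOV truncation, bias
fields, Dixon fat/water swaps, registration error between MR and CT
(pairs are perfectly registered by construction), or realistic CT
beam-hardening.  Passing tests therefore demonstrate the mechanics and
the qualitative behaviour of the method, not clinical-grade accuracy.

## Pseudo-CT network and uncertainty (`bcnn`)

A depth-3 U-net-style encoder–decoder (two 3×3 conv + leaky-ReLU +
dropout blocks per level, average-pool down, nearest-neighbour up with
skip concatenation, linear 1×1 head) maps the three MR channels to HU.  The
network, backpropagation and the Adam optimizer are implemented
directly on numpy arrays (im2col convolutions); at the default 64×64
2-D patches and 8–16 base channels this trains in minutes on one CPU
core.  Design choices:

* Dropout (default rate 0.2, a free parameter of the method) follows
  every convolution except the output head, and stays active at
  inference.  Inverted scaling keeps the deterministic pass identical
  at rate 0.
* Inputs are centred by a fixed offset of 0.5, and activations are
  leaky ReLUs (negative slope 0.1).  Both choices keep units
  responsive in signal voids: without them an all-zero input region
  silences the feature maps, and the Monte Carlo dropout variance —
  which is carried by the activations — collapses to zero exactly
  where the uncertainty signal is needed.  Real normalized Dixon data
  never present the network with a numerically dead input, so this is
  a fidelity fix, not a tuning knob.
* The output head predicts HU/1000 and is rescaled, keeping weights
  O(1).
* Training loss: `mean|y−ŷ| + λ_GDL Σ_axes mean((∇a y − ∇a ŷ)²)
  + λ_LDL mean((Δy − Δŷ)²)` with λ_GDL = λ_LDL = 0.01.  Finite
  differences: forward differences with a trailing zero for ∇; a
  2·ndim-point Laplacian with edge-replicate (Neumann) boundaries.
  Both stencils annihilate constants, so a constant offset c costs
  exactly |c| — replicate padding (rather than zero padding) for the
  Laplacian is required for this property to hold at the borders.
* Optimizer: Adam with β₁ = 0.9, β₂ = 0.999, ε = 1e-8, L2 weight decay
  1e-5, minibatch 4.  The reference recipe for the full-scale method
  uses a learning rate of 1e-5 over 100 000 iterations; a desk-scale
  run of ~1000–2000 iterations learns nothing at that rate, so the
  package default is 1e-3.  Both are plain config values.
* Monte Carlo dropout inference: N stochastic passes (reference value
  243; tests use 32), assembled per pass from overlapping patches
  (stride = half patch, uniform-average blending).  The pseudo-CT is
  the per-voxel sample mean and the uncertainty the biased (1/N)
  sample variance, computed in float64 directly from the sample stack.
* Training refuses cases containing implant voxels unless explicitly
  overridden: implants must remain out-of-distribution.

## Priors (`priorweight`, `humu`)

The variance map (HU²) becomes a weight
`w = 1/(1 + exp(0.1(σ²/1000 − 25)))` — 0.5 at σ² = 25 000 HU², ≈ 0.92
at σ² = 0, ≈ 5.5e-4 at σ² = 1e5 — evaluated with an overflow-safe
sigmoid.  The weight map is then rescaled to βMR ∈ [1e3, 5e6] and
zeroed outside the body.  "Linearly scaled to have a range" is read as
per-volume min–max rescaling over in-body voxels, so the printed range
is attained exactly; the alternative fixed affine map (which never
attains the upper endpoint, since w ≤ 0.9242) is available via
`scaling="fixed"`.  A constant in-body weight map degenerates to βmax
everywhere with a warning.

HU→μ uses the standard bilinear 120-kVp model anchored at
μ(−1000) = 0: slope 9.6e-5 cm⁻¹/HU below +47 HU (water → 0.096 cm⁻¹),
5.1e-5 above, clamped at zero below −1000 HU.  The body mask
thresholds the pseudo-CT at > −400 HU, erodes by a 1-voxel-radius ball
in index space (in-plane for single-slice stacks), and fills holes per
axial slice; an arm-removal hook is a deliberate no-op (phantoms have
no arms).  Evaluation masks use strict thresholds > −950 HU and
> 0.01 cm⁻¹.

## PET system model (`petsim`)

A 2-D parallel-beam scanner over 180°, applied slice-by-slice.  The
projector is pixel-driven with linear interpolation between radial
bins and materialized as a sparse matrix, so back projection is the
exact transpose — the adjoint identity holds to machine precision,
which the monotonicity guarantees of the reconstruction updates
require.  Path lengths are in cm.  TOF distributes each pixel's
contribution over TOF bins with a Gaussian kernel (default FWHM 60 mm,
9 bins) centred at the pixel's position along the line of response and
normalized to unit sum per pixel, so TOF marginalizes exactly to the
non-TOF projection.  Emission data are Poisson draws from
`a · P λ (+ background)` scaled to a target total count; subsets
partition angles interleaved in bit-reversal order.  An optional
isotropic Gaussian PSF (self-adjoint, zero-padded) is off by default.
No scatter, randoms, or normalization effects are modelled.

## Joint reconstruction (`mlaa`)

Each outer iteration runs one ordered-subsets EM activity pass, then
five ordered-subsets transmission-style (OSTR) attenuation passes
(reference schedule: 5 outer iterations, 28 subsets; 2-D unit tests
use 8).  The activity update is the standard multiplicative OSEM step
with attenuation factors from the current μ; voxels with zero subset
sensitivity are frozen.

The attenuation update maximizes the Poisson emission log-likelihood
in μ (activity fixed) penalized by
`R(μ) = Σ_i βMR,i/2 (μ_i − μMR,i)² + βsmooth R_smooth(μ)` with
separable paraboloidal surrogates:

* Per line, the log-likelihood as a function of the attenuation line
  integral is concave; its curvature is bounded on a trust region of
  half-width `step_clamp` (default 0.02 cm⁻¹) in μ by the current
  Newton curvature inflated by `exp(L · step_clamp)` (L the chord
  length).  Steps are clamped to the trust region, giving a monotone
  minorize–maximize update in the single-subset case; with multiple
  subsets the guarantee is traded for speed exactly as in OSEM.
  The in-package tests verify a non-decreasing penalized objective
  over 20 single-subset outer iterations to 1e-8 relative.
* De Pierro's convexity trick makes the surrogate separable across
  voxels; the quadratic priors enter through their own separable
  surrogates (curvature βMR,i + 2 βsmooth · degree).
* R_smooth is a first-order quadratic penalty on the in-plane
  4-neighbourhood, restricted to voxel pairs inside the body;
  βsmooth = 2e4 by default and also applies in naive mode.
* μ is clamped to [0, 0.5 cm⁻¹] (above any implant value at 511 keV);
  out-of-body voxels take part in neither updates nor priors.
* Initialization: λ uniform inside the body; μ = μMR in prior modes,
  water-equivalent 0.096 cm⁻¹ in naive mode.  With b = 0 background
  the TOF bins collapse in the attenuation update (only the per-line
  count and projection sums enter); with b > 0 the per-bin terms are
  used with the conservative curvature.

Modes: `naive` (βMR ≡ 0), `regularized_uniform` (constant βMR), and
`upct` (per-voxel BetaMap).  A constant BetaMap reduces `upct` exactly
to `regularized_uniform`, and βMR ≡ 0 with a water prior reduces it
exactly to `naive` (both covered by tests).  Fixed-μ TOF-OSEM
(`osem_reconstruct`, reference default 2 iterations) provides the
comparator reconstructions.

## Evaluation (`metrics`)

Masked error statistics use the population (1/n) standard deviation so
`RMSE² = μ² + σ²` is an exact identity.  Lesions are *bone* when any
lesion voxel lies within 10 mm (Euclidean distance transform in
physical units) of the bone mask, and *in-plane* when their axial
slice range overlaps the implant's (the operational reading of
in-plane/out-plane).  SUV on phantoms is a configured scale constant —
no injected dose or body weight exists — so reported biases are
ratios.  The Wilcoxon signed-rank test drops zero differences, uses
midranks for ties, and computes the exact two-sided p-value for
n ≤ 25 by dynamic programming over the 2W⁺ distribution (equivalent to
enumerating all 2ⁿ sign assignments; verified against brute-force
enumeration and against scipy on tie-free data), with a tie-corrected
normal approximation above; all-zero differences give p = 1 by
convention.

## Study problem sizes (`experiments`)

The two headline studies are fixed at sizes that run in minutes on one
CPU core:

* Out-of-distribution uncertainty: 10 implant-free training phantoms
  (8 train / 2 validation), depth-3 net with 8 base channels, 1000
  iterations, 32 MC samples, then a fresh implant phantom.  Measured
  outcome: median MC variance inside the artifact halo vs in normal
  soft tissue.  The package's tests require a ratio ≥ 5 in the
  majority of three seeds; observed ratios are typically well above
  that, with halo variances of order 1e4–1e5 HU² against a few
  hundred in soft tissue — the same order split the sigmoid transform
  was designed around.
* Implant recovery: a 96×96 implant phantom with an in-plane lesion
  adjacent to the implant, an 84-angle/9-TOF-bin scanner with the
  reference 28-subset schedule, and 1e7 counts for the slice (a
  clinical pelvis acquisition spread over its axial extent is of this
  order; the βsmooth = 2e4 prior is balanced against likelihood terms
  of roughly this magnitude).  The pseudo-CT failure mode is imposed
  exactly: the prior carries air throughout the artifact halo, with
  βMR = βmin there and βmax outside.  Comparator OSEM reconstructions
  run five activity passes to match the joint schedule, so SUVmax
  differences reflect attenuation handling rather than iteration
  count.  The strong-prior limit experiment sets βsmooth = 0 to
  isolate the MR-prior term; with smoothing active the stationary
  point at sharp prior edges sits ~0.5 % away from the prior, which
  is the expected prior-vs-smoothing equilibrium rather than an
  error.

## Known limitations

* 2-D per-slice reconstruction; no axial coupling in the projector or
  the smoothness prior.
* The emission-likelihood attenuation update assumes no
  scatter/randoms; the background term, if used, employs a
  conservative surrogate curvature without a formal monotonicity
  proof.
* The dropout network is far smaller than a clinical pseudo-CT model;
  its absolute HU accuracy (MAE of order 100 HU on validation
  phantoms, dominated by the unlearnable per-voxel jitter and
  boundary voxels) is not representative of full-scale training, and
  only the *relative* uncertainty structure is exploited downstream.
* Cohort-level clinical error statistics are out of reach by design;
  the package demonstrates mechanisms, invariants and directional
  results on synthetic data.
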