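"""Seeded synthetic pelvis-like phantoms.

Generates paired pseudo-Dixon MR channels (in-phase, fat-fraction,
water-fraction analogs), a ground-truth CT in Hounsfield units, a
ground-truth activity map with focal lesions, and an optional metal
implant whose artifact reproduces the MR/CT discrepancy that motivates
uncertainty-guided attenuation correction: a signal void in the MR
channels versus a high-HU core with radial streaks in the CT.

Volumes are thin axial stacks, axes ordered (slice, row, column),
0-based voxel indices, voxel size carried in mm.  Everything is
deterministic for a fixed seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "AIR", "FAT", "SOFT", "BONE", "IMPLANT",
    "OrganEllipse", "LesionSpec", "ImplantSpec", "PhantomSpec",
    "LesionROI", "PhantomCase", "PhantomDataset",
    "default_pelvis_spec", "make_phantom", "apply_metal_artifact",
    "make_dataset", "check_case_invariants",
]

# tissue class labels
AIR, FAT, SOFT, BONE, IMPLANT = 0, 1, 2, 3, 4

#: mean HU and within-class jitter std / truncation range per class.
#: Air is exactly -1000 HU (no jitter); cortical bone is kept in 700-1200 HU.
HU_TABLE = {
    AIR: (-1000.0, 0.0, (-1000.0, -1000.0)),
    FAT: (-100.0, 15.0, (-150.0, -50.0)),
    SOFT: (40.0, 12.0, (0.0, 80.0)),
    BONE: (950.0, 120.0, (700.0, 1200.0)),
}

#: relative tracer uptake per class (soft tissue = 1).  Implants are cold.
UPTAKE_TABLE = {AIR: 0.0, FAT: 0.2, SOFT: 1.0, BONE: 0.5, IMPLANT: 0.0}

#: MR channel signal per class: (in-phase, fat fraction, water fraction).
#: Bone carries almost no Dixon signal, overlapping air within the noise:
#: telling cortical bone from gas requires context, which is exactly the
#: ambiguity that predictive uncertainty should expose in signal voids.
MR_TABLE = {
    AIR: (0.02, 0.0, 0.0),
    FAT: (0.95, 0.90, 0.08),
    SOFT: (0.85, 0.08, 0.85),
    BONE: (0.08, 0.02, 0.05),
    IMPLANT: (0.0, 0.0, 0.0),  # overwritten by the artifact void anyway
}


@dataclass(frozen=True)
class OrganEllipse:
    """Axis-aligned ellipsoid painted into the label map.

    ``center`` is in fractional grid coordinates per axis (slice, row, col)
    in [0, 1]; ``semiaxes_mm`` are physical half-axes in mm.  Later
    ellipses overwrite earlier ones.
    """

    center: tuple[float, float, float]
    semiaxes_mm: tuple[float, float, float]
    tissue: int


@dataclass(frozen=True)
class LesionSpec:
    center: tuple[float, float, float]  # fractional grid coordinates
    radius_mm: float
    contrast: float                     # uptake multiplier, > 1
    klass: str                          # intended class: "bone" | "soft"


@dataclass(frozen=True)
class ImplantSpec:
    center: tuple[float, float, float] = (0.5, 0.48, 0.27)  # at the left hip
    radius_mm: float = 10.0
    implant_hu: float = 3000.0          # > 1000
    halo_radius_mm: float = 25.0        # artifact (signal-void) radius > radius_mm
    n_streaks: int = 12
    streak_amplitude_hu: float = 300.0


@dataclass(frozen=True)
class PhantomSpec:
    grid_shape: tuple[int, int, int] = (1, 96, 96)
    voxel_size_mm: tuple[float, float, float] = (2.5, 2.5, 2.5)
    organ_ellipses: tuple[OrganEllipse, ...] = ()
    lesion_specs: tuple[LesionSpec, ...] = ()
    implant_spec: ImplantSpec | None = None
    noise: float = 0.02                 # MR additive noise std (channel units)
    seed: int = 0

    def validate(self) -> None:
        ns, nr, nc = self.grid_shape
        if nr < 32 or nc < 32:
            raise ValueError("in-plane grid must be at least 32 voxels per axis")
        for e in self.organ_ellipses:
            # through-plane axes may span the whole thin stack; only the
            # in-plane extent must stay inside the grid
            for ax in (1, 2):
                c, n, a, v = (e.center[ax], self.grid_shape[ax],
                              e.semiaxes_mm[ax], self.voxel_size_mm[ax])
                if c * n * v - a < -1e-9 or c * n * v + a > n * v + 1e-9:
                    raise ValueError(f"ellipse {e} extends outside the grid")
        for l in self.lesion_specs:
            if l.contrast <= 1:
                raise ValueError("lesion contrast multiplier must be > 1")
            if l.klass not in ("bone", "soft"):
                raise ValueError("lesion class must be 'bone' or 'soft'")
        if self.implant_spec is not None:
            imp = self.implant_spec
            if imp.implant_hu <= 1000:
                raise ValueError("implant HU must exceed 1000")
            if imp.halo_radius_mm <= imp.radius_mm:
                raise ValueError("artifact halo must exceed the implant radius")


@dataclass(frozen=True)
class LesionROI:
    """Connected set of lesion voxels with its intended class."""

    indices: tuple[np.ndarray, np.ndarray, np.ndarray]  # (slice, row, col)
    klass: str
    multiplier: float

    def mask(self, shape: tuple[int, int, int]) -> np.ndarray:
        m = np.zeros(shape, dtype=bool)
        m[self.indices] = True
        return m

    @property
    def n_voxels(self) -> int:
        return int(self.indices[0].size)


@dataclass
class PhantomCase:
    """One synthetic subject: aligned MR, CT, activity and annotations."""

    mr: np.ndarray          # (3, S, R, C), channels in [0, 1]
    ct: np.ndarray          # (S, R, C) Hounsfield units
    activity: np.ndarray    # (S, R, C) arbitrary activity units
    labels: np.ndarray      # (S, R, C) int class map
    lesions: list[LesionROI]
    implant_mask: np.ndarray
    body_truth: np.ndarray
    voxel_size_mm: tuple[float, float, float] = (2.5, 2.5, 2.5)
    seed: int = 0

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.ct.shape


@dataclass
class PhantomDataset:
    cases: list[PhantomCase]
    train_indices: list[int]
    val_indices: list[int]

    @property
    def train(self) -> list[PhantomCase]:
        return [self.cases[i] for i in self.train_indices]

    @property
    def val(self) -> list[PhantomCase]:
        return [self.cases[i] for i in self.val_indices]


# ---------------------------------------------------------------------------
# geometry helpers

def _coords_mm(shape, voxel_size):
    """Physical voxel-center coordinates per axis, origin at grid corner."""
    return [(np.arange(n) + 0.5) * v for n, v in zip(shape, voxel_size)]


def _ellipse_mask(shape, voxel_size, center_frac, semiaxes_mm):
    zs, ys, xs = _coords_mm(shape, voxel_size)
    cz, cy, cx = [c * n * v for c, n, v in zip(center_frac, shape, voxel_size)]
    az, ay, ax = [max(a, 1e-6) for a in semiaxes_mm]
    z = ((zs - cz) / az)[:, None, None]
    y = ((ys - cy) / ay)[None, :, None]
    x = ((xs - cx) / ax)[None, None, :]
    return z * z + y * y + x * x <= 1.0


def _sphere_mask(shape, voxel_size, center_frac, radius_mm):
    return _ellipse_mask(shape, voxel_size, center_frac,
                         (radius_mm, radius_mm, radius_mm))


def default_pelvis_spec(seed: int = 0,
                        grid_shape: tuple[int, int, int] = (1, 96, 96),
                        voxel_size_mm: tuple[float, float, float] = (2.5, 2.5, 2.5),
                        lesion_specs: tuple[LesionSpec, ...] = (),
                        implant_spec: ImplantSpec | None = None,
                        jitter_rng: np.random.Generator | None = None,
                        noise: float = 0.02) -> PhantomSpec:
    """Template pelvis-like slice: fat rind, soft-tissue interior, two
    iliac-like bones and a sacrum-like bone.  ``jitter_rng`` perturbs organ
    geometry a few percent to vary anatomy between subjects."""
    _, nr, nc = grid_shape
    vz, vy, vx = voxel_size_mm
    fov_y, fov_x = nr * vy, nc * vx

    def j(x, frac=0.06):
        if jitter_rng is None:
            return x
        return x * float(1.0 + frac * (2.0 * jitter_rng.random() - 1.0))

    body_a = j(0.42 * fov_y), j(0.46 * fov_x)        # semi-axes mm (row, col)
    inner_a = 0.86 * body_a[0], 0.88 * body_a[1]
    nz = grid_shape[0]
    zc = 0.5
    az = max(nz * vz, 1.0)  # ellipses span the whole thin stack
    ells = [
        OrganEllipse((zc, 0.5, 0.5), (az, body_a[0], body_a[1]), FAT),
        OrganEllipse((zc, 0.5, 0.5), (az, inner_a[0], inner_a[1]), SOFT),
        # iliac-like bones left/right
        OrganEllipse((zc, j(0.48, 0.03), j(0.27, 0.04)),
                     (az, j(0.16 * fov_y), j(0.07 * fov_x)), BONE),
        OrganEllipse((zc, j(0.48, 0.03), j(0.73, 0.04)),
                     (az, j(0.16 * fov_y), j(0.07 * fov_x)), BONE),
        # sacrum-like posterior bone
        OrganEllipse((zc, j(0.70, 0.03), 0.5),
                     (az, j(0.08 * fov_y), j(0.10 * fov_x)), BONE),
        # bowel-gas pockets: air inside the body, so "no MR signal inside
        # the body" is ambiguous between gas and bone in training
        OrganEllipse((zc, j(0.30, 0.06), j(0.42, 0.05)),
                     (az, j(0.055 * fov_y), j(0.05 * fov_x)), AIR),
        OrganEllipse((zc, j(0.32, 0.06), j(0.58, 0.05)),
                     (az, j(0.045 * fov_y), j(0.04 * fov_x)), AIR),
    ]
    return PhantomSpec(grid_shape=grid_shape, voxel_size_mm=voxel_size_mm,
                       organ_ellipses=tuple(ells), lesion_specs=lesion_specs,
                       implant_spec=implant_spec, noise=noise, seed=seed)


# ---------------------------------------------------------------------------
# generation

def _paint_labels(spec: PhantomSpec) -> np.ndarray:
    labels = np.full(spec.grid_shape, AIR, dtype=np.int16)
    for e in spec.organ_ellipses:
        labels[_ellipse_mask(spec.grid_shape, spec.voxel_size_mm,
                             e.center, e.semiaxes_mm)] = e.tissue
    return labels


def _truncated_normal(rng, mean, std, lo, hi, size):
    if std == 0:
        return np.full(size, mean)
    x = rng.normal(mean, std, size=size)
    return np.clip(x, lo, hi)


def make_phantom(spec: PhantomSpec) -> PhantomCase:
    """Generate one phantom case from a spec.

    Deterministic for a fixed ``spec.seed``.  Per-class HU values are drawn
    from truncated Gaussians (:data:`HU_TABLE`), activity follows the
    per-class uptake table with lesion multipliers applied, and the MR
    channels are computed from class composition with additive noise.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    labels = _paint_labels(spec)
    shape = spec.grid_shape

    ct = np.empty(shape, dtype=np.float64)
    for klass, (mean, std, (lo, hi)) in HU_TABLE.items():
        sel = labels == klass
        ct[sel] = _truncated_normal(rng, mean, std, lo, hi, int(sel.sum()))

    activity = np.zeros(shape, dtype=np.float64)
    for klass, uptake in UPTAKE_TABLE.items():
        activity[labels == klass] = uptake

    # lesions: spherical uptake multipliers on top of the local class uptake
    lesions: list[LesionROI] = []
    for ls in spec.lesion_specs:
        m = _sphere_mask(shape, spec.voxel_size_mm, ls.center, ls.radius_mm)
        m &= labels != AIR
        if not m.any():
            raise ValueError(f"lesion {ls} contains no in-body voxels")
        activity[m] *= ls.contrast
        lesions.append(LesionROI(indices=tuple(np.nonzero(m)),
                                 klass=ls.klass, multiplier=ls.contrast))

    # MR channels from class signal, lightly smoothed, plus additive noise
    from scipy.ndimage import gaussian_filter
    mr = np.zeros((3,) + shape, dtype=np.float64)
    for klass, sig in MR_TABLE.items():
        sel = labels == klass
        for c in range(3):
            mr[c][sel] = sig[c]
    for c in range(3):
        mr[c] = gaussian_filter(mr[c], sigma=(0.0, 0.6, 0.6))
    mr += rng.normal(0.0, spec.noise, size=mr.shape)
    np.clip(mr, 0.0, 1.0, out=mr)

    # the body outline includes interior gas pockets: fill per slice
    from scipy.ndimage import binary_fill_holes
    body = np.stack([binary_fill_holes(sl) for sl in labels != AIR])

    case = PhantomCase(mr=mr, ct=ct, activity=activity, labels=labels,
                       lesions=lesions,
                       implant_mask=np.zeros(shape, dtype=bool),
                       body_truth=body,
                       voxel_size_mm=spec.voxel_size_mm, seed=spec.seed)
    if spec.implant_spec is not None:
        case = apply_metal_artifact(case, spec)
    return case


def apply_metal_artifact(case: PhantomCase, spec: PhantomSpec) -> PhantomCase:
    """Stamp a metal implant and its MR/CT artifact into a case.

    The implant core gets the configured high HU; the CT receives seeded
    radial streak perturbations confined to the halo radius; the MR
    channels are blanked (signal void) within the halo; the ground-truth
    activity is unchanged.  The streaks are a deterministic perturbation
    pattern, not a CT physics simulation — only the MR/CT discrepancy
    matters downstream.
    """
    if spec.implant_spec is None:
        raise ValueError("spec has no implant_spec")
    imp = spec.implant_spec
    shape = case.grid_shape
    vox = case.voxel_size_mm

    core = _sphere_mask(shape, vox, imp.center, imp.radius_mm)
    halo = _sphere_mask(shape, vox, imp.center, imp.halo_radius_mm)
    for roi in case.lesions:
        if core[roi.indices].any():
            raise ValueError("implant overlaps a lesion ROI; adjust the spec")
    outside = halo & ~case.body_truth
    if outside.any():
        warnings.warn("implant artifact halo extends beyond the body; clipped",
                      stacklevel=2)
        halo &= case.body_truth
    halo |= core

    ct = case.ct.copy()
    labels = case.labels.copy()
    mr = case.mr.copy()

    # deterministic radial streaks, seeded from the case seed
    rng = np.random.default_rng(np.random.SeedSequence([int(case.seed), 0xA27]))
    zs, ys, xs = _coords_mm(shape, vox)
    cz, cy, cx = [c * n * v for c, n, v in zip(imp.center, shape, vox)]
    dy = (ys - cy)[None, :, None]
    dx = (xs - cx)[None, None, :]
    r = np.sqrt(dy * dy + dx * dx) + 0.0 * zs[:, None, None]
    theta = np.arctan2(dy, dx) + 0.0 * zs[:, None, None]
    phases = rng.uniform(0, 2 * np.pi)
    signs = rng.choice([-1.0, 1.0], size=imp.n_streaks)
    streak = np.zeros(shape)
    spoke = np.cos(imp.n_streaks * theta + phases)
    streak = imp.streak_amplitude_hu * np.sign(spoke) * (np.abs(spoke) ** 8)
    streak *= signs[0]  # overall seeded polarity
    fall = np.clip(1.0 - r / imp.halo_radius_mm, 0.0, 1.0)
    in_streak = halo & ~core
    ct[in_streak] += (streak * fall)[in_streak]
    ct[core] = imp.implant_hu
    labels[core] = IMPLANT

    # MR signal void inside the halo: residual noise only, all values < 0.05
    void_noise = np.clip(np.abs(rng.normal(0.0, 0.02, size=(3,) + shape)),
                         0.0, 0.045)
    for c in range(3):
        mr[c][halo] = void_noise[c][halo]

    implant_mask = case.implant_mask | core
    return replace(case, mr=mr, ct=ct, labels=labels,
                   implant_mask=implant_mask)


# ---------------------------------------------------------------------------
# datasets

def check_case_invariants(case: PhantomCase) -> None:
    """Raise AssertionError if a case violates its structural contracts."""
    shape = case.grid_shape
    assert case.mr.shape == (3,) + shape
    assert case.activity.shape == shape and case.labels.shape == shape
    assert case.implant_mask.shape == shape and case.body_truth.shape == shape
    assert np.all(case.ct[case.labels == AIR] <= -900.0)
    assert np.all(case.activity >= 0)
    assert case.mr.min() >= 0.0 and case.mr.max() <= 1.0
    if case.implant_mask.any():
        assert np.all(case.ct[case.implant_mask] >= 1000.0)
    for roi in case.lesions:
        assert roi.n_voxels > 0


def make_dataset(n_cases: int,
                 base_spec: PhantomSpec | None = None,
                 seed: int = 0,
                 split_fraction: float = 0.8,
                 geometry_jitter: float = 0.06,
                 with_implants: bool = False,
                 implant_spec: ImplantSpec | None = None,
                 lesion_specs: tuple[LesionSpec, ...] = ()) -> PhantomDataset:
    """Generate ``n_cases`` phantoms with jittered anatomy and a train/val split.

    Training datasets are implant-free by default, matching the policy of
    training the pseudo-CT network only on artifact-free subjects so that
    implants remain out-of-distribution at inference time.
    """
    if n_cases < 2:
        raise ValueError("need at least 2 cases")
    ss = np.random.SeedSequence([int(seed), 0xD5])
    case_seeds = [int(s) for s in ss.generate_state(n_cases) % (2 ** 31)]
    jitter_master = np.random.default_rng(ss.spawn(1)[0])

    grid_shape = base_spec.grid_shape if base_spec else (1, 96, 96)
    voxel = base_spec.voxel_size_mm if base_spec else (2.5, 2.5, 2.5)
    noise = base_spec.noise if base_spec else 0.02

    cases = []
    for cseed in case_seeds:
        spec = default_pelvis_spec(
            seed=cseed, grid_shape=grid_shape, voxel_size_mm=voxel,
            lesion_specs=lesion_specs,
            implant_spec=implant_spec if with_implants else None,
            jitter_rng=jitter_master if geometry_jitter > 0 else None,
            noise=noise)
        cases.append(make_phantom(spec))

    n_train = int(round(split_fraction * n_cases))
    return PhantomDataset(cases=cases,
                          train_indices=list(range(n_train)),
                          val_indices=list(range(n_train, n_cases)))
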