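"""Toy time-of-flight PET system model.

A 2-D parallel-beam scanner over 180 degrees, applied independently to
each axial slice of a thin stack.  The projector is pixel-driven with
linear interpolation between radial bins and is materialized as a
sparse matrix, so forward and back projection are exact adjoints of one
another by construction — the property the joint-reconstruction
monotonicity arguments rely on.

Time of flight is modelled by distributing each pixel's contribution
across TOF bins with a Gaussian kernel centred at the pixel's position
along the line of response; the kernel is normalised to unit sum per
pixel, so TOF bins marginalise exactly to the non-TOF projection.
Path lengths are accumulated in cm so attenuation maps in cm^-1 need
no unit conversion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.ndimage import gaussian_filter

__all__ = ["ScannerGeometry", "Sinogram", "SubsetPartition",
           "bit_reversal_permutation", "forward_project", "back_project",
           "attenuation_factors", "emission_expectation", "simulate_emission"]

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def bit_reversal_permutation(n: int) -> list[int]:
    """Bit-reversal-style ordering of ``range(n)``: all evens (recursively
    reordered) before all odds, which maximally spreads consecutive subsets
    in angle.  For n a power of two this is the classic bit-reversal
    permutation; odd factors fall back to natural order."""
    if n <= 2 or n % 2:
        return list(range(n))
    half = bit_reversal_permutation(n // 2)
    return [2 * i for i in half] + [2 * i + 1 for i in half]


@dataclass(frozen=True)
class SubsetPartition:
    """Disjoint, covering, equal-size angle-index subsets, interleaved."""

    subsets: tuple[tuple[int, ...], ...]

    @classmethod
    def make(cls, n_angles: int, n_subsets: int) -> "SubsetPartition":
        if n_angles % n_subsets:
            raise ValueError("n_subsets must divide n_angles")
        order = bit_reversal_permutation(n_subsets)
        return cls(tuple(tuple(range(s, n_angles, n_subsets)) for s in order))

    def __len__(self) -> int:
        return len(self.subsets)

    def __iter__(self):
        return iter(self.subsets)


@dataclass
class ScannerGeometry:
    """Configurable toy scanner tied to a reconstruction grid.

    ``img_shape`` is the in-plane (rows, cols) grid; ``voxel_size_mm`` is
    the isotropic in-plane voxel size.  ``n_tof`` must be odd (a centre
    bin); ``n_tof == 1`` disables TOF resolution but keeps the data
    layout.  Radial and TOF bin widths default to the voxel size and to
    FOV/n_tof respectively.
    """

    img_shape: tuple[int, int] = (96, 96)
    voxel_size_mm: float = 2.5
    n_angles: int = 64
    n_radial: int = 96
    radial_width_mm: float | None = None
    n_tof: int = 9
    tof_fwhm_mm: float = 60.0
    tof_bin_width_mm: float | None = None
    psf_fwhm_mm: float = 0.0
    n_subsets: int = 8
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        if self.n_tof < 1 or self.n_tof % 2 == 0:
            raise ValueError("n_tof must be odd and >= 1")
        if self.n_angles % self.n_subsets:
            raise ValueError("n_subsets must divide n_angles")
        if self.radial_width_mm is None:
            self.radial_width_mm = float(self.voxel_size_mm)
        if self.tof_bin_width_mm is None:
            self.tof_bin_width_mm = self.n_radial * self.radial_width_mm / self.n_tof

    # -- geometry helpers ---------------------------------------------------

    @property
    def n_pixels(self) -> int:
        return self.img_shape[0] * self.img_shape[1]

    @property
    def angles_rad(self) -> np.ndarray:
        return np.arange(self.n_angles) * np.pi / self.n_angles

    def partition(self, n_subsets: int | None = None) -> SubsetPartition:
        return SubsetPartition.make(self.n_angles, n_subsets or self.n_subsets)

    def tof_kernel(self, t_mm: np.ndarray) -> np.ndarray:
        """Unit-sum TOF bin weights for positions ``t_mm`` along the LOR;
        returns shape ``t_mm.shape + (n_tof,)``."""
        centers = (np.arange(self.n_tof) - (self.n_tof - 1) / 2) * self.tof_bin_width_mm
        if self.n_tof == 1:
            return np.ones(t_mm.shape + (1,))
        sigma = self.tof_fwhm_mm * _FWHM_TO_SIGMA
        w = np.exp(-0.5 * ((t_mm[..., None] - centers) / sigma) ** 2)
        w[w < 1e-12] = 0.0
        s = w.sum(axis=-1, keepdims=True)
        # pixels beyond every bin still need unit mass: park it in the
        # nearest bin so marginalisation stays exact
        dead = (s == 0)[..., 0]
        if dead.any():
            idx = np.abs(t_mm[dead][:, None] - centers).argmin(axis=1)
            w[dead, idx] = 1.0
            s = w.sum(axis=-1, keepdims=True)
        return w / s

    # -- system matrices ----------------------------------------------------

    def _pixel_coords_mm(self):
        nr, nc = self.img_shape
        y = -(np.arange(nr) - (nr - 1) / 2) * self.voxel_size_mm
        x = (np.arange(nc) - (nc - 1) / 2) * self.voxel_size_mm
        yy, xx = np.meshgrid(y, x, indexing="ij")
        return yy.ravel(), xx.ravel()

    def _angle_matrices(self, k: int):
        """(tof_matrix, nontof_matrix) for angle index k."""
        yy, xx = self._pixel_coords_mm()
        th = self.angles_rad[k]
        s = xx * np.cos(th) + yy * np.sin(th)
        t = -xx * np.sin(th) + yy * np.cos(th)
        # pixel footprint along the ray in cm, spread over radial bins
        weight_cm = (self.voxel_size_mm ** 2 / self.radial_width_mm) / 10.0
        sidx = s / self.radial_width_mm + (self.n_radial - 1) / 2
        i0 = np.floor(sidx).astype(np.int64)
        frac = sidx - i0
        cols = np.arange(self.n_pixels, dtype=np.int64)

        rows_list, cols_list, vals_list = [], [], []
        for ioff, wfrac in ((0, 1.0 - frac), (1, frac)):
            i = i0 + ioff
            ok = (i >= 0) & (i < self.n_radial) & (wfrac > 0)
            rows_list.append(i[ok])
            cols_list.append(cols[ok])
            vals_list.append(wfrac[ok] * weight_cm)
        rows = np.concatenate(rows_list)
        colsb = np.concatenate(cols_list)
        vals = np.concatenate(vals_list)
        nontof = sparse.coo_matrix((vals, (rows, colsb)),
                                   shape=(self.n_radial, self.n_pixels)).tocsr()

        kern = self.tof_kernel(t)  # (n_pix, n_tof)
        kv = kern[colsb]           # (nnz, n_tof)
        tof_rows = (rows[:, None] * self.n_tof
                    + np.arange(self.n_tof)[None, :]).ravel()
        tof_cols = np.repeat(colsb, self.n_tof)
        tof_vals = (vals[:, None] * kv).ravel()
        nz = tof_vals > 0
        tof = sparse.coo_matrix(
            (tof_vals[nz], (tof_rows[nz], tof_cols[nz])),
            shape=(self.n_radial * self.n_tof, self.n_pixels)).tocsr()
        return tof, nontof

    def _all_angle_matrices(self):
        if "angles" not in self._cache:
            self._cache["angles"] = [self._angle_matrices(k)
                                     for k in range(self.n_angles)]
        return self._cache["angles"]

    def system_matrix(self, tof: bool, angles: tuple[int, ...] | None = None):
        """Stacked sparse system matrix for the given angles (default all),
        row-ordered (angle, radial[, tof])."""
        key = (tof, angles)
        if key not in self._cache:
            mats = self._all_angle_matrices()
            idx = range(self.n_angles) if angles is None else angles
            sel = [mats[k][0 if tof else 1] for k in idx]
            self._cache[key] = sparse.vstack(sel, format="csr")
        return self._cache[key]


@dataclass
class Sinogram:
    """TOF-binned projection data: shape (n_angles, n_radial, n_tof) for
    TOF data, (n_angles, n_radial) otherwise; a leading slice axis is
    allowed for thin stacks."""

    data: np.ndarray
    geom: ScannerGeometry
    tof: bool = True

    def __post_init__(self):
        self.data = np.asarray(self.data)
        expect = (self.geom.n_angles, self.geom.n_radial)
        if self.tof:
            expect = expect + (self.geom.n_tof,)
        if self.data.shape[-len(expect):] != expect:
            raise ValueError(f"sinogram shape {self.data.shape} does not match "
                             f"geometry {expect}")
        if np.any(self.data < 0):
            raise ValueError("sinogram values must be non-negative")

    @property
    def per_slice(self) -> bool:
        return self.data.ndim == (4 if self.tof else 3)


def _psf_blur(img: np.ndarray, geom: ScannerGeometry) -> np.ndarray:
    if geom.psf_fwhm_mm <= 0:
        return img
    sigma_px = geom.psf_fwhm_mm * _FWHM_TO_SIGMA / geom.voxel_size_mm
    # constant-mode Gaussian correlation is self-adjoint, keeping the
    # projector pair matched when the PSF is enabled
    return gaussian_filter(img, sigma=sigma_px, mode="constant")


def _as_slices(img: np.ndarray, geom: ScannerGeometry):
    img = np.asarray(img, dtype=np.float64)
    if img.ndim == 2:
        stack = img[None]
        squeeze = True
    elif img.ndim == 3:
        stack = img
        squeeze = False
    else:
        raise ValueError("image must be 2-D or a 3-D slice stack")
    if stack.shape[-2:] != geom.img_shape:
        raise ValueError(f"image grid {stack.shape[-2:]} does not match "
                         f"geometry grid {geom.img_shape}")
    return stack, squeeze


def forward_project(img, geom: ScannerGeometry, tof: bool = True,
                    angles: tuple[int, ...] | None = None) -> np.ndarray:
    """Line-integral projection of an image (cm-weighted).  Returns an
    array shaped (angle, radial[, tof]) with a leading slice axis when the
    input is a stack."""
    stack, squeeze = _as_slices(img, geom)
    A = geom.system_matrix(tof, angles)
    n_ang = geom.n_angles if angles is None else len(angles)
    shape = (n_ang, geom.n_radial, geom.n_tof) if tof else (n_ang, geom.n_radial)
    out = np.empty((stack.shape[0],) + shape)
    for i, sl in enumerate(stack):
        out[i] = (A @ _psf_blur(sl, geom).ravel()).reshape(shape)
    return out[0] if squeeze else out


def back_project(sino, geom: ScannerGeometry, tof: bool = True,
                 angles: tuple[int, ...] | None = None) -> np.ndarray:
    """Exact adjoint of :func:`forward_project`."""
    data = sino.data if isinstance(sino, Sinogram) else np.asarray(sino, dtype=np.float64)
    A = geom.system_matrix(tof, angles)
    n_ang = geom.n_angles if angles is None else len(angles)
    shape = (n_ang, geom.n_radial, geom.n_tof) if tof else (n_ang, geom.n_radial)
    if data.shape == shape:
        stack = data[None]
        squeeze = True
    elif data.ndim == len(shape) + 1 and data.shape[1:] == shape:
        stack = data
        squeeze = False
    else:
        raise ValueError(f"sinogram shape {data.shape} does not match {shape}")
    out = np.empty((stack.shape[0],) + geom.img_shape)
    for i, sl in enumerate(stack):
        out[i] = _psf_blur((A.T @ sl.ravel()).reshape(geom.img_shape), geom)
    return out[0] if squeeze else out


def attenuation_factors(mu, geom: ScannerGeometry,
                        angles: tuple[int, ...] | None = None) -> np.ndarray:
    """Survival probabilities a = exp(-P mu) per (angle, radial) bin,
    in (0, 1]; broadcast across TOF bins by the caller."""
    mu = np.asarray(mu, dtype=np.float64)
    if np.any(mu < 0):
        raise ValueError("attenuation coefficients must be non-negative")
    return np.exp(-forward_project(mu, geom, tof=False, angles=angles))


def emission_expectation(activity, mu, geom: ScannerGeometry,
                         total_counts: float | None = None,
                         background: float = 0.0):
    """Mean TOF sinogram a * P(lambda) (+ uniform background), optionally
    scaled so the summed activity term equals ``total_counts``.  Returns
    (expectation, scale)."""
    proj = forward_project(activity, geom, tof=True)
    att = attenuation_factors(mu, geom)
    ybar = proj * att[..., None]
    scale = 1.0
    if total_counts is not None:
        tot = ybar.sum()
        if tot <= 0:
            if total_counts > 0:
                raise ValueError("zero total expectation cannot be scaled "
                                 "to positive total_counts")
        else:
            scale = float(total_counts) / tot
            ybar = ybar * scale
    return ybar + background, scale


def simulate_emission(activity, mu, geom: ScannerGeometry,
                      total_counts: float = 1e6, background: float = 0.0,
                      seed: int = 0) -> Sinogram:
    """Poisson emission data with attenuation, seeded and reproducible."""
    activity = np.asarray(activity, dtype=np.float64)
    if np.any(activity < 0):
        raise ValueError("activity must be non-negative")
    ybar, _ = emission_expectation(activity, mu, geom, total_counts, background)
    rng = np.random.default_rng(seed)
    counts = rng.poisson(ybar).astype(np.float64)
    return Sinogram(counts, geom, tof=True)
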