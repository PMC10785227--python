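"""Shared fixtures: small geometries and phantom cases sized for
seconds-long unit tests."""

import numpy as np
import pytest

from uqmlaa.humu import hu_to_mu
from uqmlaa.petsim import ScannerGeometry
from uqmlaa.phantom import default_pelvis_spec, make_phantom


@pytest.fixture(scope="session")
def small_geom():
    return ScannerGeometry(img_shape=(48, 48), voxel_size_mm=3.0,
                           n_angles=32, n_radial=48, n_tof=5,
                           tof_fwhm_mm=50.0, n_subsets=4)


@pytest.fixture(scope="session")
def small_case():
    spec = default_pelvis_spec(seed=42, grid_shape=(1, 48, 48),
                               voxel_size_mm=(3.0, 3.0, 3.0))
    return make_phantom(spec)


@pytest.fixture(scope="session")
def small_recon_inputs(small_case, small_geom):
    """Noiseless emission expectation + truth for the small case."""
    from uqmlaa.petsim import emission_expectation
    mu = hu_to_mu(small_case.ct[0])
    act = small_case.activity[0]
    ybar, _ = emission_expectation(act, mu, small_geom)
    return {"activity": act, "mu": mu, "ybar": ybar,
            "body": small_case.body_truth[0]}


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
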