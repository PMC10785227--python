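"""Reconstruction engines: EM fixed points, hand-computed toy updates,
prior limits, surrogate monotonicity, mode equivalences."""

import numpy as np
import pytest

from uqmlaa.humu import hu_to_mu
from uqmlaa.mlaa import (ReconConfig, mlaa_run, osem_activity_update,
                         osem_reconstruct, ostr_attenuation_update,
                         penalized_objective)
from uqmlaa.petsim import (ScannerGeometry, emission_expectation,
                           forward_project, simulate_emission)


class TestOsemUpdate:
    def test_fixed_point_on_consistent_data(self, small_geom,
                                            small_recon_inputs):
        body = small_recon_inputs["body"]
        mu = small_recon_inputs["mu"]
        lam0 = np.where(body, 1.0, 0.0)
        ybar, _ = emission_expectation(lam0, mu, small_geom)
        lam1 = osem_activity_update(lam0, ybar, mu, small_geom)
        assert np.abs(lam1 - lam0)[body].max() <= 1e-10

    def test_zero_data_zeroes_activity(self, small_geom, small_recon_inputs):
        body = small_recon_inputs["body"]
        lam = np.where(body, 1.0, 0.0)
        zero = np.zeros((small_geom.n_angles, small_geom.n_radial,
                         small_geom.n_tof))
        out = osem_activity_update(lam, zero, small_recon_inputs["mu"],
                                   small_geom)
        assert np.abs(out).max() == 0.0

    def test_matches_hand_computed_mlem_step(self):
        # tiny system: dense-matrix MLEM arithmetic as the oracle
        geom = ScannerGeometry(img_shape=(4, 4), voxel_size_mm=4.0,
                               n_angles=4, n_radial=4, n_tof=1, n_subsets=1)
        rng = np.random.default_rng(0)
        lam = rng.random((4, 4)) + 0.1
        truth = rng.random((4, 4)) + 0.5
        y = forward_project(truth, geom, tof=True)
        A = np.asarray(geom.system_matrix(True).todense())
        proj = A @ lam.ravel()
        ratio = np.divide(y.ravel(), proj, out=np.zeros_like(proj),
                          where=proj > 0)
        sens = A.T @ np.ones(A.shape[0])
        expected = lam.ravel() * np.divide(A.T @ ratio, sens,
                                           out=np.ones_like(sens),
                                           where=sens > 0)
        got = osem_activity_update(lam, y, np.zeros((4, 4)), geom)
        assert np.abs(got.ravel() - expected).max() <= 1e-10

    def test_preserves_non_negativity(self, small_geom, small_recon_inputs,
                                      rng):
        lam = np.abs(rng.random(small_geom.img_shape))
        y = rng.poisson(5.0, (small_geom.n_angles, small_geom.n_radial,
                              small_geom.n_tof)).astype(float)
        out = osem_activity_update(lam, y, small_recon_inputs["mu"],
                                   small_geom)
        assert np.all(out >= 0)


class TestOstrUpdate:
    def test_prior_dominated_limit(self, small_geom, small_recon_inputs):
        body = small_recon_inputs["body"]
        mu_mr = small_recon_inputs["mu"]
        lam = small_recon_inputs["activity"]
        beta = np.where(body, 1e12, 0.0)
        mu = mu_mr.copy()
        for _ in range(3):
            mu = ostr_attenuation_update(mu, small_recon_inputs["ybar"], lam,
                                         beta, mu_mr, 0.0, small_geom, body)
        scale = mu_mr[body].max()
        assert np.abs(mu - mu_mr)[body].max() <= 1e-3 * scale

    def test_stationary_near_truth_without_priors(self, small_geom,
                                                  small_recon_inputs):
        body = small_recon_inputs["body"]
        mu = small_recon_inputs["mu"].copy()
        lam = small_recon_inputs["activity"]
        y = small_recon_inputs["ybar"]
        zero_beta = np.zeros_like(mu)
        args = (zero_beta, mu, 0.0, body)
        obj0 = penalized_objective(lam, mu, y, small_geom, zero_beta, mu,
                                   0.0, body)
        mu1 = ostr_attenuation_update(mu, y, lam, zero_beta, mu, 0.0,
                                      small_geom, body,
                                      small_geom.partition(1))
        obj1 = penalized_objective(lam, mu1, y, small_geom, zero_beta, mu,
                                   0.0, body)
        assert obj1 >= obj0 - 1e-8 * abs(obj0)

    def test_monotone_objective_single_subset(self):
        spec_geom = ScannerGeometry(img_shape=(32, 32), voxel_size_mm=4.0,
                                    n_angles=16, n_radial=32, n_tof=3,
                                    n_subsets=1)
        from uqmlaa.phantom import default_pelvis_spec, make_phantom
        case = make_phantom(default_pelvis_spec(
            seed=5, grid_shape=(1, 32, 32), voxel_size_mm=(4.0, 4.0, 4.0)))
        mu_true = hu_to_mu(case.ct[0])
        body = case.body_truth[0]
        sino = simulate_emission(case.activity[0], mu_true, spec_geom,
                                 total_counts=2e5, seed=2)
        beta = np.where(body, 1e4, 0.0)
        lam = np.where(body, 1.0, 0.0)
        mu = np.where(body, 0.096, 0.0)
        objs = []
        part = spec_geom.partition(1)
        for _ in range(20):
            mu = ostr_attenuation_update(mu, sino.data, lam, beta, mu_true,
                                         2e4, spec_geom, body, part)
            objs.append(penalized_objective(lam, mu, sino.data, spec_geom,
                                            beta, mu_true, 2e4, body))
        diffs = np.diff(objs)
        assert np.all(diffs >= -1e-8 * np.abs(objs[:-1]))

    def test_respects_bounds_and_negative_beta_rejected(
            self, small_geom, small_recon_inputs):
        body = small_recon_inputs["body"]
        mu = small_recon_inputs["mu"]
        out = ostr_attenuation_update(mu, small_recon_inputs["ybar"],
                                      small_recon_inputs["activity"],
                                      np.zeros_like(mu), mu, 0.0, small_geom,
                                      body, mu_max=0.12)
        assert out.max() <= 0.12 and out.min() >= 0.0
        with pytest.raises(ValueError):
            ostr_attenuation_update(mu, small_recon_inputs["ybar"],
                                    small_recon_inputs["activity"],
                                    np.full_like(mu, -1.0), mu, 0.0,
                                    small_geom, body)


@pytest.fixture(scope="module")
def sino(small_case, small_geom):
    mu = hu_to_mu(small_case.ct[0])
    return simulate_emission(small_case.activity[0], mu, small_geom,
                             total_counts=5e5, seed=11)


class TestMlaaRun:
    def test_naive_mode_needs_no_prior(self, sino, small_case, small_geom):
        cfg = ReconConfig(n_subsets=4, outer_iterations=2)
        res = mlaa_run(sino, "naive", cfg, body=small_case.body_truth[0])
        assert res.activity.min() >= 0
        assert res.mu.min() >= 0 and res.mu.max() <= cfg.mu_max
        assert np.all(np.isfinite(res.objective_trace))

    def test_upct_requires_inputs(self, sino, small_case):
        with pytest.raises(ValueError, match="upct mode needs"):
            mlaa_run(sino, "upct", ReconConfig(n_subsets=4),
                     body=small_case.body_truth[0])
        with pytest.raises(ValueError, match="unknown mode"):
            mlaa_run(sino, "bogus", ReconConfig(n_subsets=4),
                     body=small_case.body_truth[0])

    def test_upct_reduces_to_uniform_when_betamap_constant(
            self, sino, small_case, small_geom):
        body = small_case.body_truth[0]
        mu_mr = hu_to_mu(small_case.ct[0])
        cfg = ReconConfig(n_subsets=4, outer_iterations=2)
        betamap = np.where(body, 7e5, 0.0)
        a = mlaa_run(sino, "upct", cfg, body=body, betamap=betamap,
                     mu_prior=mu_mr)
        b = mlaa_run(sino, "regularized_uniform", cfg, body=body,
                     mu_prior=mu_mr, beta_uniform=7e5)
        assert np.array_equal(a.activity, b.activity)
        assert np.array_equal(a.mu, b.mu)

    def test_upct_with_zero_beta_matches_naive(self, sino, small_case):
        body = small_case.body_truth[0]
        cfg = ReconConfig(n_subsets=4, outer_iterations=2)
        water = np.where(body, cfg.mu_init_naive, 0.0)
        a = mlaa_run(sino, "upct", cfg, body=body,
                     betamap=np.zeros_like(water), mu_prior=water)
        b = mlaa_run(sino, "naive", cfg, body=body)
        assert np.array_equal(a.activity, b.activity)
        assert np.array_equal(a.mu, b.mu)


class TestOsemReconstruct:
    def test_attenuation_correction_direction(self, small_geom, small_case):
        mu = hu_to_mu(small_case.ct[0])
        body = small_case.body_truth[0]
        sino = simulate_emission(small_case.activity[0], mu, small_geom,
                                 total_counts=5e5, seed=4)
        cfg = ReconConfig(n_subsets=4)
        with_mu = osem_reconstruct(sino, mu, cfg, body=body)
        without = osem_reconstruct(sino, np.zeros_like(mu), cfg, body=body)
        assert without[body].sum() < with_mu[body].sum()

    def test_bit_identical_reruns(self, small_geom, small_case):
        mu = hu_to_mu(small_case.ct[0])
        sino = simulate_emission(small_case.activity[0], mu, small_geom,
                                 total_counts=5e5, seed=4)
        cfg = ReconConfig(n_subsets=4)
        a = osem_reconstruct(sino, mu, cfg, body=small_case.body_truth[0])
        b = osem_reconstruct(sino, mu, cfg, body=small_case.body_truth[0])
        assert np.array_equal(a, b)
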