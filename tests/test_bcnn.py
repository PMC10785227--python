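"""Regressor: composite loss oracle, backprop gradient check, training
contracts, Monte Carlo dropout estimator."""

import numpy as np
import pytest

import uqmlaa.bcnn as bcnn
from uqmlaa.bcnn import (MCConfig, NetConfig, TrainConfig, _UNet,
                         composite_loss, composite_loss_grad,
                         mc_dropout_infer, train)
from uqmlaa.phantom import PhantomCase


def _loss_bruteforce(y, yhat, lg, ll):
    """Independent loss evaluation with explicit loops over the stencils:
    forward differences padded with a trailing zero, Laplacian with
    edge-replicated neighbours."""
    y = np.asarray(y, float)
    yhat = np.asarray(yhat, float)
    n = y.size
    total = np.abs(y - yhat).sum() / n
    for d in (y, yhat):
        pass
    for axis, weight in ((0, lg), (1, lg)):
        acc = 0.0
        for i in range(y.shape[0]):
            for j in range(y.shape[1]):
                if axis == 0:
                    gy = y[i + 1, j] - y[i, j] if i + 1 < y.shape[0] else 0.0
                    gh = (yhat[i + 1, j] - yhat[i, j]
                          if i + 1 < y.shape[0] else 0.0)
                else:
                    gy = y[i, j + 1] - y[i, j] if j + 1 < y.shape[1] else 0.0
                    gh = (yhat[i, j + 1] - yhat[i, j]
                          if j + 1 < y.shape[1] else 0.0)
                acc += (gy - gh) ** 2
        total += weight * acc / n

    def lap(a, i, j):
        up = a[max(i - 1, 0), j]
        dn = a[min(i + 1, a.shape[0] - 1), j]
        lf = a[i, max(j - 1, 0)]
        rt = a[i, min(j + 1, a.shape[1] - 1)]
        return up + dn + lf + rt - 4.0 * a[i, j]

    acc = 0.0
    for i in range(y.shape[0]):
        for j in range(y.shape[1]):
            acc += (lap(y, i, j) - lap(yhat, i, j)) ** 2
    total += ll * acc / n
    return total


class TestCompositeLoss:
    def test_identity_is_zero(self, rng):
        y = rng.random((8, 8)) * 100
        assert composite_loss(y, y) == 0.0

    def test_constant_offset_gives_l1_only(self, rng):
        y = rng.random((8, 8)) * 100
        assert composite_loss(y, y + 5.0) == pytest.approx(5.0, abs=1e-12)
        assert composite_loss(y, y - 3.0) == pytest.approx(3.0, abs=1e-12)

    def test_matches_bruteforce_oracle(self, rng):
        y = rng.random((4, 4)) * 200
        yhat = rng.random((4, 4)) * 200
        expected = _loss_bruteforce(y, yhat, 0.01, 0.01)
        assert composite_loss(y, yhat) == pytest.approx(expected, rel=1e-12)

    def test_zero_weights_reduce_to_l1(self, rng):
        y, yhat = rng.random((6, 6)), rng.random((6, 6))
        assert composite_loss(y, yhat, 0.0, 0.0) == pytest.approx(
            np.abs(y - yhat).mean(), rel=1e-12)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            composite_loss(np.zeros((4, 4)), np.zeros((4, 5)))

    def test_gradient_matches_finite_difference(self, rng):
        y = rng.random((6, 6)) * 50
        yhat = rng.random((6, 6)) * 50
        g = composite_loss_grad(y, yhat)
        eps = 1e-6
        for idx in [(0, 0), (2, 3), (5, 5)]:
            p = yhat.copy()
            p[idx] += eps
            m = yhat.copy()
            m[idx] -= eps
            fd = (composite_loss(y, p) - composite_loss(y, m)) / (2 * eps)
            assert g[idx] == pytest.approx(fd, rel=1e-4, abs=1e-8)


class TestBackprop:
    def test_network_gradients_exact(self, rng, monkeypatch):
        # float64 network + linear readout isolates the backprop path
        monkeypatch.setattr(bcnn, "_DTYPE", np.float64)
        net = _UNet(NetConfig(depth=3, base_channels=4, dropout=0.0,
                              patch_size=(16, 16)), np.random.default_rng(1))
        x = rng.random((2, 3, 16, 16))
        w = rng.random((2, 16, 16))

        def f():
            return float((net.forward(x, None) * w).sum())

        f()
        net.backward(w)
        grads = [g.copy() for g in net.grads()]
        for pi, p in enumerate(net.params()):
            flat = p.reshape(-1)
            for k in (0, flat.size // 2):
                old = flat[k]
                flat[k] = old + 1e-6
                lp = f()
                flat[k] = old - 1e-6
                lm = f()
                flat[k] = old
                fd = (lp - lm) / 2e-6
                assert grads[pi].reshape(-1)[k] == pytest.approx(
                    fd, rel=1e-4, abs=1e-7)


def _single_patch_case(seed=0, n=32):
    from scipy.ndimage import gaussian_filter
    rng = np.random.default_rng(seed)
    mr = gaussian_filter(rng.random((3, 1, n, n)), sigma=(0, 0, 2, 2))
    mr = (mr - mr.min()) / (mr.max() - mr.min())
    ct = 1000.0 * (mr.mean(axis=0) - 0.3)  # smooth, learnable target
    return PhantomCase(mr=mr, ct=ct, activity=np.ones((1, n, n)),
                       labels=np.full((1, n, n), 2, dtype=np.int16),
                       lesions=[], implant_mask=np.zeros((1, n, n), bool),
                       body_truth=np.ones((1, n, n), bool))


class TestTraining:
    def test_overfit_single_patch(self):
        case = _single_patch_case()
        cfg = NetConfig(depth=2, base_channels=8, dropout=0.0,
                        patch_size=(32, 32))
        model = train([case], cfg, TrainConfig(iterations=2000, seed=0))
        initial = model.loss_history[0]
        final = model.loss_history[-20:].mean()
        assert final < 0.1 * initial

    def test_identical_seeds_identical_curves(self):
        case = _single_patch_case()
        cfg = NetConfig(depth=2, base_channels=4, dropout=0.2,
                        patch_size=(32, 32))
        a = train([case], cfg, TrainConfig(iterations=30, seed=5))
        b = train([case], cfg, TrainConfig(iterations=30, seed=5))
        assert np.array_equal(a.loss_history, b.loss_history)
        for pa, pb in zip(a.params, b.params):
            assert np.array_equal(pa, pb)

    def test_implant_case_refused(self):
        case = _single_patch_case()
        case.implant_mask[0, 4, 4] = True
        with pytest.raises(ValueError, match="implant"):
            train([case], NetConfig(depth=2, base_channels=4,
                                    patch_size=(32, 32)),
                  TrainConfig(iterations=1))

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            train([], None, TrainConfig(iterations=1))


@pytest.fixture(scope="module")
def tiny_model():
    cfg = NetConfig(depth=2, base_channels=4, dropout=0.2,
                    patch_size=(16, 16))
    net = _UNet(cfg, np.random.default_rng(3))
    return bcnn.ModelState(params=net.params(), net_cfg=cfg)


class TestMCDropout:
    def test_estimator_matches_stored_samples(self, tiny_model, rng):
        mr = rng.random((3, 24, 24))
        pct, var, samples = mc_dropout_infer(tiny_model, mr,
                                             MCConfig(n_samples=16, seed=2),
                                             return_samples=True)
        region = np.s_[8:16, 8:16]
        mean_o = samples[:, region[0], region[1]].mean(axis=0)
        var_o = ((samples[:, region[0], region[1]] - mean_o) ** 2).mean(axis=0)
        assert np.abs(pct[region] - mean_o).max() <= 1e-10
        assert np.abs(var[region] - var_o).max() <= 1e-10
        assert np.all(var >= 0)

    def test_zero_dropout_zero_variance(self, rng):
        cfg = NetConfig(depth=2, base_channels=4, dropout=0.0,
                        patch_size=(16, 16))
        net = _UNet(cfg, np.random.default_rng(4))
        model = bcnn.ModelState(params=net.params(), net_cfg=cfg)
        mr = rng.random((3, 16, 16))
        pct, var = mc_dropout_infer(model, mr, MCConfig(n_samples=4, seed=0))
        assert np.all(var == 0.0)
        determ = net.forward(mr[None].astype(np.float64), None)[0]
        assert np.abs(pct - determ).max() <= 1e-4

    def test_bit_reproducible(self, tiny_model, rng):
        mr = rng.random((3, 16, 16))
        a = mc_dropout_infer(tiny_model, mr, MCConfig(n_samples=8, seed=9))
        b = mc_dropout_infer(tiny_model, mr, MCConfig(n_samples=8, seed=9))
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_requires_two_samples(self, tiny_model, rng):
        with pytest.raises(ValueError):
            MCConfig(n_samples=1)
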