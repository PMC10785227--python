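"""Evaluation suite: error-statistics algebra, lesion classification,
exact Wilcoxon signed-rank test."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from uqmlaa.metrics import (classify_lesion, lesion_report,
                            masked_error_stats, suvmax,
                            wilcoxon_signed_rank)
from uqmlaa.phantom import LesionROI


def _roi_from_mask(mask, klass="soft"):
    return LesionROI(indices=tuple(np.nonzero(mask)), klass=klass,
                     multiplier=4.0)


class TestErrorStats:
    def test_identical_images_all_zero(self, rng):
        img = rng.random((2, 8, 8))
        s = masked_error_stats(img, img, np.ones_like(img, dtype=bool))
        assert (s.rmse, s.mae, s.mean_error, s.std_error) == (0, 0, 0, 0)

    def test_hand_arithmetic(self):
        est = np.array([[[1.0, 2.0, 3.0]]])
        ref = np.ones_like(est)
        s = masked_error_stats(est, ref, np.ones_like(est, dtype=bool))
        assert s.mean_error == pytest.approx(1.0)
        assert s.mae == pytest.approx(1.0)
        assert s.std_error == pytest.approx(np.sqrt(2.0 / 3.0))
        assert s.rmse == pytest.approx(np.sqrt(5.0 / 3.0))
        assert s.n_voxels == 3

    @given(st.integers(0, 10000))
    @settings(deadline=None, max_examples=30)
    def test_rmse_decomposition_identity(self, seed):
        rng = np.random.default_rng(seed)
        est, ref = rng.normal(size=(2, 40)) * 10
        s = masked_error_stats(est, ref, np.ones(40, dtype=bool))
        assert s.rmse ** 2 == pytest.approx(
            s.mean_error ** 2 + s.std_error ** 2, rel=1e-10)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            masked_error_stats(np.zeros(4), np.zeros(4),
                               np.zeros(4, dtype=bool))


class TestClassifyLesion:
    def _masks(self, shape=(5, 32, 32)):
        bone = np.zeros(shape, dtype=bool)
        implant = np.zeros(shape, dtype=bool)
        return bone, implant

    def test_inside_bone_is_bone(self):
        bone, implant = self._masks()
        bone[2, 10:14, 10:14] = True
        les = np.zeros_like(bone)
        les[2, 11:13, 11:13] = True
        klass, _ = classify_lesion(_roi_from_mask(les), bone, implant,
                                   (2.0, 2.0, 2.0))
        assert klass == "bone"

    @pytest.mark.parametrize("voxel_mm,expected", [(0.99, "bone"),
                                                   (1.01, "soft")])
    def test_ten_mm_rule(self, voxel_mm, expected):
        # bone plane at column 5, lesion voxel 10 columns away: the
        # physical gap is 9.9 mm or 10.1 mm depending on the voxel size
        shape = (1, 32, 32)
        bone, implant = self._masks(shape)
        bone[0, :, 5] = True
        les = np.zeros(shape, dtype=bool)
        les[0, 16, 15] = True
        klass, _ = classify_lesion(_roi_from_mask(les), bone, implant,
                                   (1.0, 1.0, voxel_mm))
        assert klass == expected

    def test_in_plane_slice_overlap(self):
        shape = (25, 16, 16)
        bone, implant = self._masks(shape)
        implant[10:15, 8, 8] = True
        les_in = np.zeros(shape, dtype=bool)
        les_in[13:17, 4, 4] = True
        les_out = np.zeros(shape, dtype=bool)
        les_out[20:23, 4, 4] = True
        assert classify_lesion(_roi_from_mask(les_in), bone, implant,
                               (2.0, 2.0, 2.0))[1] == "in-plane"
        assert classify_lesion(_roi_from_mask(les_out), bone, implant,
                               (2.0, 2.0, 2.0))[1] == "out-plane"

    def test_voxel_order_invariance(self):
        bone, implant = self._masks()
        bone[2, 4, 4] = True
        les = np.zeros_like(bone)
        les[2, 6:9, 6:9] = True
        roi = _roi_from_mask(les)
        perm = np.random.default_rng(0).permutation(roi.n_voxels)
        roi2 = LesionROI(indices=tuple(ix[perm] for ix in roi.indices),
                         klass=roi.klass, multiplier=roi.multiplier)
        assert classify_lesion(roi, bone, implant, (2.0, 2.0, 2.0)) == \
            classify_lesion(roi2, bone, implant, (2.0, 2.0, 2.0))


class TestSuvmax:
    def test_constant_and_hot_voxel(self):
        pet = np.full((1, 8, 8), 3.0)
        les = np.zeros((1, 8, 8), dtype=bool)
        les[0, 2:5, 2:5] = True
        roi = _roi_from_mask(les)
        assert suvmax(pet, roi, suv_scale=2.0) == 6.0
        pet[0, 3, 3] = 6.0
        assert suvmax(pet, roi, suv_scale=2.0) == 12.0

    def test_monotone_under_increase(self, rng):
        pet = rng.random((1, 8, 8))
        les = np.zeros((1, 8, 8), dtype=bool)
        les[0, 2:6, 2:6] = True
        roi = _roi_from_mask(les)
        assert suvmax(pet + 0.5, roi) >= suvmax(pet, roi)


def _wilcoxon_bruteforce(d):
    """Enumerate all sign assignments (midranks, zeros dropped)."""
    d = np.asarray(d, dtype=float)
    d = d[d != 0]
    n = d.size
    if n == 0:
        return 1.0
    from scipy.stats import rankdata
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = [np.dot(signs, ranks) for signs in
          itertools.product([0.0, 1.0], repeat=n)]
    ws = np.asarray(ws)
    lo = (ws <= w_obs + 1e-9).mean()
    hi = (ws >= w_obs - 1e-9).mean()
    return min(1.0, 2.0 * min(lo, hi))


class TestWilcoxon:
    def test_identical_samples_p_one(self):
        a = np.array([1.0, 2.0, 3.0])
        assert wilcoxon_signed_rank(a, a) == 1.0

    def test_three_positive_differences(self):
        a = np.array([2.0, 4.0, 6.0])
        b = np.array([1.0, 2.0, 3.0])
        assert wilcoxon_signed_rank(a, b) == pytest.approx(0.25)

    def test_symmetry(self, rng):
        a = rng.normal(size=12)
        b = rng.normal(size=12)
        assert wilcoxon_signed_rank(a, b) == pytest.approx(
            wilcoxon_signed_rank(b, a), rel=1e-12)

    @given(st.integers(0, 5000), st.integers(3, 9))
    @settings(deadline=None, max_examples=25)
    def test_matches_bruteforce_enumeration(self, seed, n):
        rng = np.random.default_rng(seed)
        d = rng.integers(-5, 6, size=n).astype(float)  # ties and zeros
        assert wilcoxon_signed_rank(d, np.zeros(n)) == pytest.approx(
            _wilcoxon_bruteforce(d), rel=1e-10)

    def test_matches_scipy_exact_without_ties(self, rng):
        from scipy.stats import wilcoxon as scipy_wilcoxon
        a = rng.normal(size=10)
        b = rng.normal(size=10)
        expected = scipy_wilcoxon(a, b, alternative="two-sided",
                                  method="exact").pvalue
        assert wilcoxon_signed_rank(a, b) == pytest.approx(expected,
                                                           rel=1e-10)

    def test_normal_approximation_large_n(self, rng):
        a = rng.normal(size=40)
        b = a - rng.normal(0.5, 1.0, size=40)
        p = wilcoxon_signed_rank(a, b)
        from scipy.stats import wilcoxon as scipy_wilcoxon
        expected = scipy_wilcoxon(a, b, alternative="two-sided",
                                  method="approx",
                                  correction=False).pvalue
        assert p == pytest.approx(expected, rel=1e-6)


def test_lesion_report_shape(rng):
    shape = (1, 16, 16)
    les = np.zeros(shape, dtype=bool)
    les[0, 4:7, 4:7] = True
    roi = _roi_from_mask(les)
    ref = rng.random(shape) + 1.0
    pets = {"a": ref * 1.1, "b": ref * 0.9}
    rep = lesion_report(ref, pets, [roi], np.zeros(shape, bool),
                        np.zeros(shape, bool), (2.0, 2.0, 2.0))
    assert len(rep) == 2
    assert set(rep["method"]) == {"a", "b"}
    assert (rep["suvmax_bias"].abs() < 0.2).all()
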