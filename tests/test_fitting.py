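"""Unit tests for voxel-wise NLLS fitting, maps, ROI stats, region growing."""

import numpy as np
import pytest
from sklearn.base import clone

from aladdin_acbv import ARTERY, KineticParams, SequenceParams, bssfp_model
from aladdin_acbv.fitting import (
    FitConfig,
    KineticModelFitter,
    fit_map,
    fit_voxel,
    grow_roi,
    roi_stats,
)
from aladdin_acbv.recon import MultiphaseSignal, phase_times

GM = KineticParams(f=197.0, delta=661.0, att=628.0, alpha=1.0)


@pytest.fixture(scope="module")
def gm_curve(seq, times):
    return bssfp_model(times, GM, seq, ARTERY)


class TestFitVoxel:
    def test_noiseless_recovery_within_half_percent(self, seq, times, gm_curve):
        curve = MultiphaseSignal(times=times, ds=gm_curve, s0=1.0)
        kp, diag = fit_voxel(curve, FitConfig(alpha=1.0), seq, ARTERY)
        assert diag.converged
        assert kp.f == pytest.approx(GM.f, rel=5e-3)
        assert kp.delta == pytest.approx(GM.delta, rel=5e-3)
        assert kp.att == pytest.approx(GM.att, rel=5e-3)

    def test_all_zero_curve_flagged_non_perfused(self, seq, times):
        curve = MultiphaseSignal(times=times, ds=np.zeros(9), s0=1.0)
        kp, diag = fit_voxel(curve, FitConfig(), seq, ARTERY)
        assert diag.converged and diag.non_perfused
        assert kp.f == 0.0
        assert diag.acbv == 0.0

    def test_scaling_consistency(self, seq, times, gm_curve):
        """Scaling curve and S0 together leaves parameters unchanged."""
        c1 = MultiphaseSignal(times=times, ds=gm_curve, s0=1.0)
        c2 = MultiphaseSignal(times=times, ds=7.3 * gm_curve, s0=1.0)
        kp1, _ = fit_voxel(c1, FitConfig(alpha=1.0, s0_b=1.0), seq, ARTERY)
        kp2, _ = fit_voxel(c2, FitConfig(alpha=1.0, s0_b=7.3), seq, ARTERY)
        assert kp2.f == pytest.approx(kp1.f, rel=1e-6)
        assert kp2.delta == pytest.approx(kp1.delta, rel=1e-6)
        assert kp2.att == pytest.approx(kp1.att, rel=1e-6)

    def test_too_few_phases_rejected(self, seq):
        curve = MultiphaseSignal(times=np.array([100.0, 200.0, 300.0]),
                                 ds=np.zeros(3), s0=1.0)
        with pytest.raises(ValueError, match="4 phases"):
            fit_voxel(curve, FitConfig(), seq, ARTERY)

    def test_t1_model_fit_recovers_t1_truth(self, seq, times):
        from aladdin_acbv import t1_model

        kp_true = KineticParams(f=140.0, delta=427.0, att=484.0, alpha=1.0)
        curve = MultiphaseSignal(times=times, ds=t1_model(times, kp_true), s0=1.0)
        kp, diag = fit_voxel(curve, FitConfig(model="t1", alpha=1.0), seq, ARTERY)
        assert diag.converged
        assert kp.f == pytest.approx(kp_true.f, rel=5e-3)
        assert kp.delta == pytest.approx(kp_true.delta, rel=5e-3)


class TestEstimator:
    def test_sklearn_contract(self, gm_curve):
        est = KineticModelFitter(alpha=1.0)
        params = est.get_params()
        assert params["model"] == "bssfp"
        est2 = clone(est).set_params(model="t1")
        assert est2.model == "t1"
        est.fit(gm_curve[None, :])
        assert est.f_.shape == (1,)
        assert est.converged_[0]
        assert est.acbv_[0] == pytest.approx(GM.acbv, rel=1e-2)

    def test_predict_reproduces_noiseless_input(self, gm_curve):
        est = KineticModelFitter(alpha=1.0).fit(gm_curve[None, :])
        pred = est.predict()
        np.testing.assert_allclose(pred[0], gm_curve, rtol=1e-6, atol=1e-12)

    def test_phase_count_mismatch_raises(self, gm_curve):
        with pytest.raises(ValueError, match="phases"):
            KineticModelFitter().fit(gm_curve[None, :4])


@pytest.fixture(scope="module")
def two_region_stack(seq, times):
    kp_a = GM
    kp_b = KineticParams(f=120.0, delta=400.0, att=300.0, alpha=1.0)
    stack = np.zeros((9, 4, 4))
    mask = np.zeros((4, 4), dtype=bool)
    mask[0, :2] = True  # region A
    mask[2, :2] = True  # region B
    stack[:, 0, :2] = bssfp_model(times, kp_a, seq, ARTERY)[:, None]
    stack[:, 2, :2] = bssfp_model(times, kp_b, seq, ARTERY)[:, None]
    return stack, mask, kp_a, kp_b


class TestFitMap:
    def test_two_region_phantom_recovery(self, seq, times, two_region_stack):
        stack, mask, kp_a, kp_b = two_region_stack
        maps = fit_map(stack, times, mask, FitConfig(alpha=1.0), seq, ARTERY)
        assert np.all(maps.converged_map[mask])
        assert np.median(maps.f_map[0, :2]) == pytest.approx(kp_a.f, rel=1e-2)
        assert np.median(maps.f_map[2, :2]) == pytest.approx(kp_b.f, rel=1e-2)
        assert np.median(maps.delta_map[2, :2]) == pytest.approx(kp_b.delta, rel=1e-2)
        # aCBV map is elementwise F * delta / 60000
        sel = maps.converged_map
        np.testing.assert_allclose(
            maps.acbv_map[sel], maps.f_map[sel] * maps.delta_map[sel] / 60000.0,
            rtol=1e-12)

    def test_single_voxel_matches_fit_voxel(self, seq, times, two_region_stack):
        stack, _, kp_a, _ = two_region_stack
        mask1 = np.zeros((4, 4), dtype=bool)
        mask1[0, 0] = True
        maps = fit_map(stack, times, mask1, FitConfig(alpha=1.0), seq, ARTERY)
        curve = MultiphaseSignal(times=times, ds=stack[:, 0, 0], s0=1.0)
        kp, diag = fit_voxel(curve, FitConfig(alpha=1.0), seq, ARTERY)
        assert maps.f_map[0, 0] == kp.f
        assert maps.rss_map[0, 0] == diag.rss

    def test_empty_mask_rejected(self, seq, times, two_region_stack):
        stack, *_ = two_region_stack
        with pytest.raises(ValueError, match="empty"):
            fit_map(stack, times, np.zeros((4, 4), dtype=bool),
                    FitConfig(), seq, ARTERY)

    def test_voxel_order_independence(self, seq, times, two_region_stack):
        """Permuting voxel positions permutes outputs identically."""
        stack, mask, *_ = two_region_stack
        perm_stack = stack[:, ::-1, :]
        perm_mask = mask[::-1, :]
        maps = fit_map(stack, times, mask, FitConfig(alpha=1.0), seq, ARTERY)
        maps_p = fit_map(perm_stack, times, perm_mask, FitConfig(alpha=1.0),
                         seq, ARTERY)
        np.testing.assert_array_equal(maps_p.f_map[::-1, :], maps.f_map)


class TestRoiStats:
    def _uniform_maps(self, value=2.0, shape=(3, 3)):
        from aladdin_acbv.fitting import ParameterMaps

        ones = np.full(shape, value)
        return ParameterMaps(
            f_map=ones, delta_map=ones, att_map=ones, acbv_map=ones,
            rss_map=np.zeros(shape), converged_map=np.ones(shape, dtype=bool),
            non_perfused_map=np.zeros(shape, dtype=bool),
            mask=np.ones(shape, dtype=bool))

    def test_uniform_roi(self):
        maps = self._uniform_maps(2.0)
        s = roi_stats(maps, np.ones((3, 3), dtype=bool))
        assert s.mean["aCBV"] == 2.0
        assert s.sd["aCBV"] == 0.0
        assert s.n_voxels == 9

    def test_two_voxel_mean(self):
        maps = self._uniform_maps(0.0)
        maps.acbv_map[0, 0], maps.acbv_map[0, 1] = 1.0, 3.0
        roi = np.zeros((3, 3), dtype=bool)
        roi[0, :2] = True
        assert roi_stats(maps, roi).mean["aCBV"] == 2.0

    def test_no_converged_voxels_rejected(self):
        maps = self._uniform_maps()
        maps.converged_map[:] = False
        with pytest.raises(ValueError, match="converged"):
            roi_stats(maps, np.ones((3, 3), dtype=bool))


class TestGrowRoi:
    def test_uniform_image_fills_plane(self):
        mask = grow_roi(np.ones((8, 8)), (3, 3), 0.1)
        assert mask.all()

    def test_contrast_blocks_growth(self):
        img = np.ones((8, 8))
        img[:, 4:] = 2.0
        mask = grow_roi(img, (0, 0), 0.5)
        assert mask[:, :4].all() and not mask[:, 4:].any()

    def test_ribbon_phantom_recovered_exactly(self):
        """10% contrast ribbon, 5% tolerance: region growing returns the
        generator's GM mask exactly."""
        from aladdin_acbv.synthetic_data import default_region_masks

        masks = default_region_masks((32, 32))
        img = np.full((32, 32), 0.8)  # WM-like everywhere else
        img[masks["gm"]] = 1.0
        img[masks["background"]] = 0.5
        seed = tuple(np.argwhere(masks["gm"])[0])
        grown = grow_roi(img, seed, 0.05)
        np.testing.assert_array_equal(grown, masks["gm"])

    def test_seed_outside_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            grow_roi(np.ones((4, 4)), (9, 0), 0.1)
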