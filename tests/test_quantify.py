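"""Evaluation metrics: SUV, RCs, peak VOI, MSSIM, sphericity, summaries."""

import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from petrestore import quantify
from petrestore.quantify import SSIMConfig, TumourMetrics


class TestSUV:
    def test_reference_value(self):
        # 5 kBq/ml with 350 MBq injected into 70 kg -> SUV 1
        assert quantify.suv(5.0, 350.0, 70.0) == pytest.approx(1.0)

    def test_zero_concentration(self):
        assert quantify.suv(0.0, 350.0, 70.0) == 0.0

    def test_proportional_to_weight(self):
        assert quantify.suv(5.0, 350.0, 140.0) == pytest.approx(2.0 * quantify.suv(5.0, 350.0, 70.0))

    @pytest.mark.parametrize("injected,weight", [(0.0, 70.0), (350.0, 0.0)])
    def test_nonpositive_inputs_rejected(self, injected, weight):
        with pytest.raises(ValueError):
            quantify.suv(5.0, injected, weight)


@pytest.fixture()
def toy():
    rng = np.random.default_rng(0)
    gt = rng.random((20, 20, 20)) * 10 + 5
    mask = np.zeros((20, 20, 20), dtype=bool)
    mask[7:13, 7:13, 7:13] = True
    return gt, mask


class TestRecoveryCoefficients:
    def test_identity_prediction_gives_unit_rcs(self, toy):
        gt, mask = toy
        rc = quantify.rc_metrics(gt, gt, mask, (2.0, 2.0, 2.0))
        assert rc.rc_max == pytest.approx(1.0)
        assert rc.rc_median == pytest.approx(1.0)
        assert rc.rc_peak == pytest.approx(1.0)

    def test_max_ratio(self, toy):
        gt, mask = toy
        pred = gt * 0.9
        rc = quantify.rc_metrics(pred, gt, mask, (2.0, 2.0, 2.0))
        assert rc.rc_max == pytest.approx(0.9)

    def test_median_matches_explicit_sort(self):
        rng = np.random.default_rng(1)
        gt = rng.random((5, 5, 5)) + 1.0
        pred = rng.random((5, 5, 5)) + 1.0
        mask = rng.random((5, 5, 5)) > 0.4
        rc = quantify.rc_metrics(pred, gt, mask, (20.0, 20.0, 20.0))
        med = lambda v: float(np.sort(v[mask].ravel())[v[mask].size // 2]) if v[mask].size % 2 \
            else float(np.mean(np.sort(v[mask].ravel())[v[mask].size // 2 - 1 : v[mask].size // 2 + 1]))
        assert rc.rc_median == pytest.approx(med(pred) / med(gt))

    def test_median_skipped_for_halves(self, toy):
        gt, mask = toy
        rc = quantify.rc_metrics(gt, gt, mask, (2.0, 2.0, 2.0), pattern="halves")
        assert rc.rc_median is None

    def test_rcs_invariant_to_joint_rescaling(self, toy):
        gt, mask = toy
        pred = gt * 0.8 + 1.0
        a = quantify.rc_metrics(pred, gt, mask, (2.0, 2.0, 2.0))
        b = quantify.rc_metrics(3.0 * pred, 3.0 * gt, mask, (2.0, 2.0, 2.0))
        assert a.rc_max == pytest.approx(b.rc_max)
        assert a.rc_median == pytest.approx(b.rc_median)
        assert a.rc_peak == pytest.approx(b.rc_peak)

    def test_empty_mask_rejected(self, toy):
        gt, _ = toy
        with pytest.raises(ValueError):
            quantify.rc_metrics(gt, gt, np.zeros_like(gt, dtype=bool), (2.0, 2.0, 2.0))


class TestPeakActivity:
    def test_uniform_volume_peak_equals_value(self):
        vol = np.full((20, 20, 20), 7.0)
        mask = np.zeros((20, 20, 20), bool)
        mask[8:12, 8:12, 8:12] = True
        assert quantify.peak_activity(vol, mask, (2.0, 2.0, 2.0)) == pytest.approx(7.0)

    def test_matches_exhaustive_brute_force(self):
        rng = np.random.default_rng(2)
        vol = rng.random((20, 20, 20)) * 10
        mask = np.zeros((20, 20, 20), bool)
        mask[6:14, 6:14, 6:14] = True
        voxel = (2.0, 2.0, 2.0)
        r = (3.0 * 1000.0 / (4 * math.pi)) ** (1 / 3)
        half = [int(r // s) for s in voxel]
        offs = [np.arange(-h, h + 1) * s for h, s in zip(half, voxel)]
        gx, gy, gz = np.meshgrid(*offs, indexing="ij")
        ball = gx**2 + gy**2 + gz**2 <= r**2
        best = -np.inf
        for c in np.argwhere(mask):
            if any(c[d] < half[d] or c[d] >= 20 - half[d] for d in range(3)):
                continue
            region = vol[
                c[0] - half[0] : c[0] + half[0] + 1,
                c[1] - half[1] : c[1] + half[1] + 1,
                c[2] - half[2] : c[2] + half[2] + 1,
            ]
            best = max(best, region[ball].mean())
        assert quantify.peak_activity(vol, mask, voxel) == pytest.approx(best, rel=1e-9)

    def test_small_hot_sphere_is_diluted(self):
        # 0.5 ml tumour inside the 1 cm^3 VOI: peak < max
        grid = np.full((24, 24, 24), 1.0)
        xs, ys, zs = np.meshgrid(*([np.arange(24) * 2.0 + 1.0] * 3), indexing="ij")
        sphere = (xs - 24) ** 2 + (ys - 24) ** 2 + (zs - 24) ** 2 <= 4.92**2
        grid[sphere] = 20.0
        assert quantify.peak_activity(grid, sphere, (2.0, 2.0, 2.0)) < 20.0

    def test_no_valid_centre_rejected(self):
        vol = np.ones((6, 6, 6))
        mask = np.ones((6, 6, 6), bool)
        with pytest.raises(ValueError):
            quantify.peak_activity(vol, mask, (1.0, 1.0, 1.0))


class TestMSSIM:
    def test_identical_images_score_one(self):
        x = np.random.default_rng(3).random((12, 12, 12))
        assert quantify.mssim(x, x) == pytest.approx(1.0)

    def test_symmetric(self):
        rng = np.random.default_rng(4)
        x, y = rng.random((10, 10, 10)), rng.random((10, 10, 10))
        assert quantify.mssim(x, y) == pytest.approx(quantify.mssim(y, x))

    def test_bounded_by_one(self):
        rng = np.random.default_rng(5)
        x, y = rng.random((10, 10, 10)), rng.random((10, 10, 10))
        assert quantify.mssim(x, y) <= 1.0

    def test_luminance_shift_closed_form(self):
        # constant images: contrast and structure terms drop out
        x = np.full((9, 9, 9), 0.4)
        y = np.full((9, 9, 9), 0.6)
        cfg = SSIMConfig(data_range=1.0)
        c1 = (0.01) ** 2
        expected = (2 * 0.4 * 0.6 + c1) / (0.4**2 + 0.6**2 + c1)
        assert quantify.mssim(x, y, cfg) == pytest.approx(expected, rel=1e-9)

    def test_matches_reference_implementation(self):
        from skimage.metrics import structural_similarity

        rng = np.random.default_rng(6)
        x = rng.random((16, 16, 16))
        y = np.clip(x + 0.2 * rng.random((16, 16, 16)), 0, 1)
        L = float(max(x.max(), y.max()) - min(x.min(), y.min()))
        ref = structural_similarity(
            x, y, win_size=7, data_range=L, gaussian_weights=False
        )
        assert quantify.mssim(x, y) == pytest.approx(ref, abs=1e-6)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            quantify.mssim(np.zeros((8, 8, 8)), np.zeros((8, 8, 9)))


class TestSphericity:
    @settings(deadline=None, derandomize=True, max_examples=40)
    @given(
        r=st.floats(0.5, 100.0),
        s=st.floats(0.01, 100.0),
    )
    def test_formula_is_scale_invariant_and_maximal_for_spheres(self, r, s):
        # sphericity is dimensionless: V -> s^3 V, A -> s^2 A leaves it fixed;
        # and no closed surface beats the sphere's value of 1
        v = 4.0 / 3.0 * math.pi * r**3
        a = 4.0 * math.pi * r**2
        base = quantify.sphericity_from_measures(v, a)
        scaled = quantify.sphericity_from_measures(s**3 * v, s**2 * a)
        assert scaled == pytest.approx(base, rel=1e-9)
        assert base == pytest.approx(1.0, rel=1e-9)

    def test_formula_on_analytic_sphere_is_exactly_one(self):
        r = 10.0
        v = 4.0 / 3.0 * math.pi * r**3
        a = 4.0 * math.pi * r**2
        assert quantify.sphericity_from_measures(v, a) == pytest.approx(1.0, rel=1e-12)

    def test_voxelized_sphere_high_but_below_analytic_limit(self):
        # marching cubes on the binary mask overestimates the area by a
        # bounded staircase factor, so a digital sphere sits a little under 1
        n = 64
        c = (n - 1) / 2.0
        idx = np.indices((n, n, n))
        mask = ((idx[0] - c) ** 2 + (idx[1] - c) ** 2 + (idx[2] - c) ** 2) <= 24.0**2
        value = quantify.sphericity(mask, (1.0, 1.0, 1.0))
        assert 0.88 <= value <= 1.0

    def test_cube_value(self):
        mask = np.zeros((40, 40, 40), bool)
        mask[4:36, 4:36, 4:36] = True
        expected = (36 * math.pi) ** (1 / 3) / 6  # ~0.806
        assert quantify.sphericity(mask, (1.0, 1.0, 1.0)) == pytest.approx(expected, rel=0.02)

    def test_elongation_strictly_decreases_sphericity(self):
        idx = np.indices((72, 72, 72))
        c = 35.5
        values = []
        for f in (1.0, 1.5, 2.2):
            mask = (
                ((idx[0] - c) / (16.0 * f)) ** 2
                + ((idx[1] - c) / 16.0) ** 2
                + ((idx[2] - c) / (16.0 / f)) ** 2
            ) <= 1.0
            values.append(quantify.sphericity(mask, (1.0, 1.0, 1.0)))
        assert values[0] > values[1] > values[2]

    def test_bounded_in_unit_interval_for_random_blobs(self):
        from scipy import ndimage as ndi

        rng = np.random.default_rng(7)
        for _ in range(4):
            field = ndi.gaussian_filter(rng.normal(size=(24, 24, 24)), 3)
            mask = field > np.quantile(field, 0.9)
            lbl, n = ndi.label(mask)
            largest = lbl == np.argmax(np.bincount(lbl.ravel())[1:]) + 1
            assert 0.0 < quantify.sphericity(largest, (1, 1, 1)) <= 1.0

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            quantify.sphericity(np.zeros((4, 4, 4), bool), (1, 1, 1))


class TestHalvesRatio:
    def _masks(self):
        a = np.zeros((8, 8, 8), bool)
        b = np.zeros((8, 8, 8), bool)
        a[2:6, 2:6, 2:4] = True
        b[2:6, 2:6, 4:6] = True
        return a, b

    def test_identity_prediction_not_underestimated(self):
        a, b = self._masks()
        gt = np.where(a, 20.0, np.where(b, 10.0, 1.0))
        pred_ratio, true_ratio, under = quantify.halves_ratio_analysis(gt, gt, (a, b))
        assert pred_ratio == pytest.approx(true_ratio)
        assert not under

    def test_arithmetic_example(self):
        a, b = self._masks()
        gt = np.where(a, 20.0, np.where(b, 10.0, 1.0))
        pred = np.where(a, 18.0, np.where(b, 12.0, 1.0))
        pred_ratio, true_ratio, under = quantify.halves_ratio_analysis(pred, gt, (a, b))
        assert true_ratio == pytest.approx(2.0)
        assert pred_ratio == pytest.approx(1.5)
        assert under

    def test_cohort_underestimation_count(self):
        a, b = self._masks()
        gt = np.where(a, 20.0, np.where(b, 10.0, 1.0))
        preds = [np.where(a, hi, np.where(b, 10.0, 1.0)) for hi in (15.0, 18.0, 25.0)]
        under = [quantify.halves_ratio_analysis(p, gt, (a, b))[2] for p in preds]
        assert sum(under) == 2

    def test_empty_half_rejected(self):
        a, b = self._masks()
        with pytest.raises(ValueError):
            quantify.halves_ratio_analysis(np.ones((8, 8, 8)), np.ones((8, 8, 8)), (a, np.zeros_like(b)))


def _report(volume_ml, rc_max=1.0, rc_median=1.0, rc_peak=1.0):
    return TumourMetrics(
        rc_max=rc_max, rc_peak=rc_peak, rc_median=rc_median, mssim=0.5,
        volume_ml=volume_ml, sphericity=0.9, pattern="uniform",
    )


class TestBinnedSummary:
    def test_unit_rcs_summarise_to_one_with_zero_sd(self):
        reports = [_report(v) for v in (5.5, 6.0, 8.0)]
        table = quantify.binned_rc_summary(reports, "large")
        assert np.allclose(table["mean"], 1.0)
        assert np.allclose(table["sd"], 0.0)

    def test_hand_computed_eight_tumour_table(self):
        # two tumours per 0.25 ml segment with known RC_max values
        vols = [1.1, 1.2, 1.3, 1.4, 1.6, 1.7, 1.8, 1.9]
        rcs = [0.5, 0.7, 0.9, 1.1, 1.0, 1.2, 0.6, 0.8]
        reports = [_report(v, rc_max=r) for v, r in zip(vols, rcs)]
        table = quantify.binned_rc_summary(reports, "small")
        expected = np.mean([0.6, 1.0, 1.1, 0.7])  # per-segment means averaged
        assert table.loc["rc_max", "mean"] == pytest.approx(expected)

    def test_segment_averaging_differs_from_pooled_mean(self):
        # unbalanced segments: 3 tumours in one segment, 1 in another
        reports = [
            _report(1.05, rc_max=0.4),
            _report(1.10, rc_max=0.4),
            _report(1.15, rc_max=0.4),
            _report(1.90, rc_max=1.2),
        ]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            table = quantify.binned_rc_summary(reports, "small")
        pooled = np.mean([0.4, 0.4, 0.4, 1.2])
        assert table.loc["rc_max", "mean"] == pytest.approx(0.8)
        assert table.loc["rc_max", "mean"] != pytest.approx(pooled)

    def test_empty_segment_warns_and_is_excluded(self):
        reports = [_report(1.1, rc_max=0.5), _report(1.9, rc_max=1.5)]
        with pytest.warns(UserWarning, match="segment"):
            table = quantify.binned_rc_summary(reports, "small")
        assert table.loc["rc_max", "mean"] == pytest.approx(1.0)

    def test_no_large_tumours_rejected(self):
        with pytest.raises(ValueError):
            quantify.binned_rc_summary([_report(1.0)], "large")


class TestDetection:
    def test_flat_background_not_detected(self):
        mask = np.zeros((8, 8, 8), bool)
        mask[3:5, 3:5, 3:5] = True
        pred = np.full((8, 8, 8), 2.0)
        assert not quantify.detect_tumour(pred, mask, background_level=2.0)

    def test_ground_truth_detected(self):
        mask = np.zeros((8, 8, 8), bool)
        mask[3:5, 3:5, 3:5] = True
        pred = np.where(mask, 20.0, 2.0)
        assert quantify.detect_tumour(pred, mask, background_level=2.0)

    def test_detections_monotone_in_threshold(self):
        mask = np.zeros((8, 8, 8), bool)
        mask[3:5, 3:5, 3:5] = True
        preds = [np.where(mask, level, 2.0) for level in (2.5, 3.5, 6.0)]
        counts = [
            sum(quantify.detect_tumour(p, mask, 2.0, factor=f) for p in preds)
            for f in (1.1, 1.5, 2.5)
        ]
        assert counts == sorted(counts, reverse=True)
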