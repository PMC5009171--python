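import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from helpers import brute_auc, brute_confusion, brute_dice
from tractconcord.errors import GridMismatchError, UndefinedRateError
from tractconcord.overlap import (
    ConfusionCounts,
    average_reports,
    confusion_counts,
    dice_si,
    fn_dilation_profile,
    roc_and_si_curves,
    tpr_fpr,
)
from tractconcord.tractography import ConnectivityMap


def random_masks(rng, shape=(8, 8, 8), p=0.3):
    return rng.random(shape) < p, rng.random(shape) < p


class TestConfusionCounts:
    def test_pred_equals_ref(self, rng):
        pred, _ = random_masks(rng)
        roi = np.ones_like(pred)
        c = confusion_counts(pred, pred, roi)
        assert c.fp == 0 and c.fn == 0 and c.tp == pred.sum()

    def test_empty_pred(self, rng):
        _, ref = random_masks(rng)
        roi = np.ones_like(ref)
        c = confusion_counts(np.zeros_like(ref), ref, roi)
        assert c.tp == 0 and c.fp == 0 and c.fn == ref.sum()

    def test_matches_bruteforce(self, rng):
        for _ in range(20):
            pred, ref = random_masks(rng)
            roi = rng.random(pred.shape) < 0.7
            if not roi.any():
                continue
            c = confusion_counts(pred, ref, roi)
            assert (c.tp, c.fp, c.tn, c.fn) == brute_confusion(pred, ref, roi)
            assert c.total == roi.sum()

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            confusion_counts(np.zeros((2, 2, 2), bool), np.zeros((3, 3, 3), bool),
                             np.ones((2, 2, 2), bool))

    def test_empty_roi(self):
        z = np.zeros((2, 2, 2), bool)
        with pytest.raises(ValueError):
            confusion_counts(z, z, z)


class TestRates:
    def test_arithmetic(self):
        tpr, fpr = tpr_fpr(ConfusionCounts(tp=3, fn=1, fp=1, tn=9))
        assert tpr == 0.75 and fpr == 0.1

    def test_perfect_prediction(self):
        tpr, fpr = tpr_fpr(ConfusionCounts(tp=5, fn=0, fp=0, tn=5))
        assert (tpr, fpr) == (1.0, 0.0)

    def test_all_positive_prediction(self):
        tpr, fpr = tpr_fpr(ConfusionCounts(tp=5, fn=0, fp=5, tn=0))
        assert (tpr, fpr) == (1.0, 1.0)

    def test_undefined_rates_raise(self):
        with pytest.raises(UndefinedRateError):
            tpr_fpr(ConfusionCounts(tp=0, fn=0, fp=1, tn=1))
        with pytest.raises(UndefinedRateError):
            tpr_fpr(ConfusionCounts(tp=1, fn=1, fp=0, tn=0))


class TestDice:
    def test_identical_masks(self, rng):
        pred, _ = random_masks(rng)
        assert dice_si(pred, pred) == 1.0

    def test_disjoint_masks(self):
        a = np.zeros((4, 4, 4), bool)
        b = np.zeros((4, 4, 4), bool)
        a[0, 0, 0] = True
        b[1, 1, 1] = True
        assert dice_si(a, b) == 0.0

    def test_known_overlap(self):
        a = np.zeros((4, 4, 4), bool)
        b = np.zeros((4, 4, 4), bool)
        a.flat[:4] = True  # |pred| = 4
        b.flat[1:7] = True  # |ref| = 6, overlap 3
        assert dice_si(a, b) == pytest.approx(0.6)

    def test_both_empty_is_zero(self):
        z = np.zeros((3, 3, 3), bool)
        assert dice_si(z, z) == 0.0

    def test_symmetry(self, rng):
        for _ in range(10):
            a, b = random_masks(rng)
            assert dice_si(a, b) == dice_si(b, a)

    def test_matches_bruteforce(self, rng):
        for _ in range(20):
            a, b = random_masks(rng)
            assert dice_si(a, b) == brute_dice(a, b)


def make_random_map(rng, shape=(8, 8, 8), n_accepted=50):
    counts = rng.integers(1, n_accepted, size=shape)  # all voxels visited
    return ConnectivityMap(counts.astype(np.int64), n_accepted=n_accepted,
                           n_attempted=2 * n_accepted, voxel_size_mm=1.0)


class TestRocAndSiCurves:
    def test_auc_matches_rank_statistic(self, rng):
        for _ in range(10):
            cmap = make_random_map(rng)
            ref = rng.random(cmap.counts.shape) < 0.4
            roi = np.ones_like(ref)
            if not ref.any() or ref.all():
                continue
            values = cmap.normalized
            thresholds = np.unique(values)
            report = roc_and_si_curves(cmap, ref, {"all": roi}, thresholds)
            expected = brute_auc(values, ref, roi)
            assert report.summary["all"]["auc"] == pytest.approx(expected, abs=1e-12)

    def test_perfect_separation_auc_one(self):
        counts = np.ones((4, 4, 4), dtype=np.int64)
        ref = np.zeros((4, 4, 4), bool)
        ref[:2] = True
        counts[ref] = 10
        cmap = ConnectivityMap(counts, n_accepted=20, n_attempted=40, voxel_size_mm=1.0)
        report = roc_and_si_curves(cmap, ref, {"all": np.ones_like(ref)},
                                   np.unique(cmap.normalized))
        assert report.summary["all"]["auc"] == pytest.approx(1.0)

    def test_rates_monotone_in_threshold(self, rng):
        cmap = make_random_map(rng)
        ref = rng.random(cmap.counts.shape) < 0.4
        thresholds = np.linspace(0, float(cmap.normalized.max()), 50)
        report = roc_and_si_curves(cmap, ref, {"all": np.ones_like(ref)}, thresholds)
        assert (np.diff(report.rows["TPR"]) <= 1e-12).all()
        assert (np.diff(report.rows["FPR"]) <= 1e-12).all()

    def test_threshold_zero_dominates(self, rng):
        cmap = make_random_map(rng)
        ref = rng.random(cmap.counts.shape) < 0.4
        thresholds = np.linspace(0, float(cmap.normalized.max()), 20)
        rows = roc_and_si_curves(cmap, ref, {"all": np.ones_like(ref)},
                                 thresholds).rows
        assert rows["TPR"].iloc[0] == rows["TPR"].max()
        assert rows["FPR"].iloc[0] == rows["FPR"].max()

    def test_optimal_threshold_attains_max_si(self, rng):
        cmap = make_random_map(rng)
        ref = rng.random(cmap.counts.shape) < 0.4
        thresholds = np.unique(cmap.normalized)
        report = roc_and_si_curves(cmap, ref, {"all": np.ones_like(ref)}, thresholds)
        s = report.summary["all"]
        sub = report.rows[report.rows["threshold"] == s["optimal_threshold"]]
        assert sub["SI"].iloc[0] == pytest.approx(s["max_si"])

    def test_unsorted_thresholds_rejected(self, rng):
        cmap = make_random_map(rng)
        ref = np.zeros(cmap.counts.shape, bool)
        ref[0] = True
        with pytest.raises(ValueError):
            roc_and_si_curves(cmap, ref, {"all": np.ones_like(ref)},
                              np.array([0.5, 0.1]))

    def test_degenerate_roi_raises(self, rng):
        cmap = make_random_map(rng)
        ref = np.ones(cmap.counts.shape, bool)  # no negatives anywhere
        with pytest.raises(UndefinedRateError):
            roc_and_si_curves(cmap, ref, {"all": np.ones_like(ref)},
                              np.array([0.0, 0.5]))


class TestDilationProfile:
    def test_pred_equals_ref_profile_is_one(self, rng):
        pred = rng.random((8, 8, 8)) < 0.3
        roi = np.ones_like(pred)
        prof = fn_dilation_profile(pred, pred, roi, 1.0, 3.0)
        assert (prof["covered_fraction"] == 1.0).all()

    def test_erosion_dilation_duality(self):
        from scipy import ndimage

        s = ndimage.generate_binary_structure(3, 1)
        core = np.zeros((12, 12, 12), bool)
        core[4:8, 4:8, 4:8] = True
        ref = ndimage.binary_dilation(core, s)  # open w.r.t. the cross element
        pred = ndimage.binary_erosion(ref, s)
        prof = fn_dilation_profile(pred, ref, np.ones_like(ref), 1.0, 2.0)
        assert prof["covered_fraction"].iloc[1] == 1.0  # margin = 1 voxel

    def test_single_voxel_cross_coverage(self):
        """6-connected dilation of one voxel covers 7 of the 27 voxels of
        the surrounding 3x3x3 cube."""
        pred = np.zeros((7, 7, 7), bool)
        pred[3, 3, 3] = True
        ref = np.zeros((7, 7, 7), bool)
        ref[2:5, 2:5, 2:5] = True
        prof = fn_dilation_profile(pred, ref, np.ones_like(ref), 1.0, 1.0)
        assert prof["covered_fraction"].iloc[1] == pytest.approx(7 / 27)

    def test_non_decreasing_and_reaches_one(self, rng):
        pred = np.zeros((10, 10, 10), bool)
        pred[5, 5, 5] = True
        ref = rng.random((10, 10, 10)) < 0.3
        ref[5, 5, 5] = True
        prof = fn_dilation_profile(pred, ref, np.ones_like(ref), 1.0, 30.0)
        cov = prof["covered_fraction"].to_numpy()
        assert (np.diff(cov) >= 0).all()
        assert cov[-1] == 1.0

    def test_empty_pred_flagged(self):
        ref = np.zeros((5, 5, 5), bool)
        ref[2, 2, 2] = True
        prof = fn_dilation_profile(np.zeros_like(ref), ref, np.ones_like(ref),
                                   1.0, 2.0)
        assert (prof["covered_fraction"] == 0.0).all()
        assert prof.attrs["empty_pred"]

    def test_margin_in_mm(self):
        pred = np.zeros((6, 6, 6), bool)
        pred[0, 0, 0] = True
        ref = pred.copy()
        prof = fn_dilation_profile(pred, ref, np.ones_like(ref), 0.5, 2.0)
        assert list(prof["margin_mm"]) == [0.0, 0.5, 1.0, 1.5, 2.0]


bool_volumes = arrays(np.bool_, (4, 4, 4), elements=st.booleans())


class TestPropertyBased:
    @given(a=bool_volumes, b=bool_volumes)
    @settings(max_examples=50, deadline=None)
    def test_dice_symmetric_and_bounded(self, a, b):
        si = dice_si(a, b)
        assert si == dice_si(b, a)
        assert 0.0 <= si <= 1.0

    @given(pred=bool_volumes, ref=bool_volumes)
    @settings(max_examples=50, deadline=None)
    def test_confusion_partitions_roi(self, pred, ref):
        roi = np.ones((4, 4, 4), bool)
        c = confusion_counts(pred, ref, roi)
        assert c.total == roi.sum()
        assert c.tp + c.fn == (ref & roi).sum()
        assert c.tp + c.fp == (pred & roi).sum()

    @given(seed=st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_threshold_containment(self, seed):
        from tractconcord.tractography import threshold_map

        cmap = make_random_map(np.random.default_rng(seed))
        prev = None
        for t in np.linspace(0, 1.0, 8):
            mask = threshold_map(cmap, t)
            if prev is not None:
                assert not (mask & ~prev).any()
            prev = mask


def make_report(rng, si_shift=0.0):
    cmap = make_random_map(rng)
    ref = rng.random(cmap.counts.shape) < 0.4
    thresholds = np.linspace(0, 0.5, 10)
    rep = roc_and_si_curves(cmap, ref, {"all": np.ones_like(ref)}, thresholds)
    if si_shift:
        rep.rows["SI"] = np.clip(rep.rows["SI"] + si_shift, 0, 1)
    return rep


class TestAverageReports:
    def test_identity(self, rng):
        rep = make_report(rng)
        out = average_reports([rep])
        pd.testing.assert_frame_equal(
            out.rows[["TPR", "FPR", "SI"]], rep.rows[["TPR", "FPR", "SI"]])

    def test_mean_of_two(self, rng):
        a = make_report(np.random.default_rng(0))
        b = make_report(np.random.default_rng(0), si_shift=0.2)
        out = average_reports([a, b])
        expected = (a.rows["SI"] + b.rows["SI"]) / 2
        assert np.allclose(out.rows["SI"], expected)
        assert (out.rows["TP"] == a.rows["TP"] + b.rows["TP"]).all()

    def test_order_invariance(self):
        reports = [make_report(np.random.default_rng(0), s)
                   for s in (0.0, 0.1, 0.2)]
        fwd = average_reports(reports)
        rev = average_reports(reports[::-1])
        assert np.allclose(fwd.rows["SI"], rev.rows["SI"])
        assert fwd.summary == rev.summary

    def test_grid_mismatch_raises(self, rng):
        a = make_report(np.random.default_rng(0))
        cmap = make_random_map(np.random.default_rng(1))
        ref = np.zeros(cmap.counts.shape, bool)
        ref[0] = True
        b = roc_and_si_curves(cmap, ref, {"all": np.ones_like(ref)},
                              np.linspace(0, 0.4, 7))
        with pytest.raises(GridMismatchError):
            average_reports([a, b])
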