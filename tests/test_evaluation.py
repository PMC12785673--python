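"""Dice/IoU, HD95, ECE, Cohen's d, stratified summaries."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import cdist

from lesionfocus.evaluation import (EvalConfig, cohens_d, dice_iou_per_slice,
                                    expected_calibration_error, hd95,
                                    stratify_summary)
from lesionfocus.image_io import LABELS


def _masks_from(pred_hole, gt_hole, shape=(8, 8)):
    pred = np.zeros(shape, dtype=np.int64)
    gt = np.zeros(shape, dtype=np.int64)
    for (r, c) in pred_hole:
        pred[r, c] = LABELS["hole"]
    for (r, c) in gt_hole:
        gt[r, c] = LABELS["hole"]
    return pred, gt


class TestDiceIoU:
    def test_identical_nonempty_masks_score_one(self):
        pred, gt = _masks_from([(1, 1), (1, 2)], [(1, 1), (1, 2)])
        out = dice_iou_per_slice(pred, gt)
        assert out["hole"]["dice"] == pytest.approx(1.0)
        assert out["hole"]["iou"] == pytest.approx(1.0)

    def test_partial_overlap_pixel_counts(self):
        # pred covers 1 px of a 2-px lesion: dice 2/3, iou 1/2
        pred, gt = _masks_from([(1, 1)], [(1, 1), (1, 2)])
        out = dice_iou_per_slice(pred, gt)
        assert out["hole"]["dice"] == pytest.approx(2 / 3, abs=1e-6)
        assert out["hole"]["iou"] == pytest.approx(1 / 2, abs=1e-6)

    def test_absent_absent_neutral_value(self):
        pred, gt = _masks_from([], [])
        out = dice_iou_per_slice(pred, gt)
        assert out["hole"]["dice"] == 1.0 and out["hole"]["iou"] == 1.0

    def test_present_only_mode_marks_absent_as_nan(self):
        pred, gt = _masks_from([(1, 1)], [])
        out = dice_iou_per_slice(pred, gt, EvalConfig(present_only=True))
        assert np.isnan(out["hole"]["dice"])

    def test_iou_dice_identity_per_slice(self, rng):
        for _ in range(20):
            pred = rng.integers(0, 3, (16, 16))
            gt = rng.integers(0, 3, (16, 16))
            out = dice_iou_per_slice(pred, gt)
            for vals in out.values():
                d = vals["dice"]
                assert vals["iou"] == pytest.approx(d / (2 - d), abs=1e-4)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            dice_iou_per_slice(np.zeros((4, 4), int), np.zeros((5, 5), int))


def _brute_hd95(a, b):
    """All-pairs oracle with the same 4-neighbor boundary definition."""
    def boundary(m):
        pts = []
        h, w = m.shape
        for r in range(h):
            for c in range(w):
                if not m[r, c]:
                    continue
                nbrs = [(r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1)]
                if any(not (0 <= rr < h and 0 <= cc < w) or not m[rr, cc]
                       for rr, cc in nbrs):
                    pts.append((r, c))
        return np.array(pts, dtype=float)

    pa, pb = boundary(a), boundary(b)
    d = cdist(pa, pb)
    return max(np.percentile(d.min(axis=1), 95),
               np.percentile(d.min(axis=0), 95))


class TestHD95:
    def test_identical_masks_zero(self):
        m = np.zeros((10, 10), bool)
        m[2:6, 2:6] = True
        assert hd95(m, m) == 0.0

    def test_two_single_pixels_euclidean(self):
        a = np.zeros((8, 8), bool)
        b = np.zeros((8, 8), bool)
        a[0, 0] = True
        b[3, 4] = True
        assert hd95(a, b) == pytest.approx(5.0)

    def test_translated_square(self):
        a = np.zeros((20, 20), bool)
        b = np.zeros((20, 20), bool)
        a[5:15, 2:12] = True
        b[5:15, 5:15] = True
        assert hd95(a, b) == pytest.approx(3.0)

    def test_empty_mask_undefined(self):
        m = np.zeros((5, 5), bool)
        m[1, 1] = True
        assert np.isnan(hd95(m, np.zeros((5, 5), bool)))

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(30):
            a = rng.uniform(size=(32, 32)) < 0.2
            b = rng.uniform(size=(32, 32)) < 0.2
            if not a.any() or not b.any():
                continue
            assert hd95(a, b) == pytest.approx(_brute_hd95(a, b), abs=1e-9)


class TestECE:
    @staticmethod
    def _prob_from(conf, correct, n=1000):
        """n pixels, two classes; prediction confidence `conf`."""
        gt = np.zeros((1, n), dtype=np.int64)
        p = np.zeros((2, 1, n))
        p[0] = conf
        p[1] = 1 - conf
        n_wrong = int(round(n * (1 - correct)))
        gt[0, :n_wrong] = 1  # argmax=0 is wrong there
        return p, gt

    def test_confident_and_correct_is_zero(self):
        p, gt = self._prob_from(1.0, 1.0)
        assert expected_calibration_error([p], [gt]) == 0.0

    def test_single_bin_gap(self):
        # confidence 0.8, accuracy 0.5 -> |0.8 - 0.5| = 0.3
        p, gt = self._prob_from(0.8, 0.5)
        cfg = EvalConfig(ece_bins=2)
        assert expected_calibration_error([p], [gt], cfg) == pytest.approx(
            0.3, abs=1e-9)

    def test_invariant_to_pixel_order(self, rng):
        p = rng.dirichlet(np.ones(5), size=(1, 400)).transpose(2, 0, 1)
        gt = rng.integers(0, 5, (1, 400))
        perm = rng.permutation(400)
        assert expected_calibration_error([p], [gt]) == pytest.approx(
            expected_calibration_error([p[:, :, perm]], [gt[:, perm]]))

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            expected_calibration_error([], [])


class TestCohensD:
    def test_cyst_size_contrast_worked_example(self):
        # small vs medium/large cyst Dice groups
        d = cohens_d(0.784, 0.202, 252, 0.906, 0.036, 118)
        assert d == pytest.approx(-0.73, abs=0.005)
        assert (0.784 - 0.906) == pytest.approx(-0.122)

    def test_equal_means_zero(self):
        assert cohens_d(0.5, 0.1, 10, 0.5, 0.2, 10) == 0.0

    def test_unit_effect_identity(self):
        assert cohens_d(1.0, 1.0, 10_000, 0.0, 1.0, 10_000) == pytest.approx(
            1.0, abs=1e-9)

    def test_degenerate_variance_is_nan(self):
        assert np.isnan(cohens_d(1.0, 0.0, 5, 0.0, 0.0, 5))

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            cohens_d(1.0, 1.0, 1, 0.0, 1.0, 10)


class TestStratifySummary:
    def test_quartiles_of_four_records(self):
        df = pd.DataFrame({"dice": [1.0, 2.0, 3.0, 4.0]})
        out = stratify_summary(df, ["dice"], quartile_of="dice")
        assert list(out["n"]) == [1, 1, 1, 1]
        assert list(out["group"]) == ["Q1", "Q2", "Q3", "Q4"]

    def test_flagged_vs_clean_delta(self):
        df = pd.DataFrame({"dice": [0.5, 0.5, 0.6, 0.6],
                           "flag": [False, False, True, True]})
        out = stratify_summary(df, ["dice"], flag_key="flag")
        delta = out.loc[out["group"] == "delta", "dice_mean"].iloc[0]
        assert delta == pytest.approx(0.1)

    def test_planted_group_gap_recovered(self, rng):
        small = rng.normal(0.78, 0.01, 300)
        large = rng.normal(0.90, 0.01, 300)
        df = pd.DataFrame({
            "dice": np.concatenate([small, large]),
            "size_group": ["small"] * 300 + ["large"] * 300,
        })
        out = stratify_summary(df, ["dice"], group_key="size_group")
        means = dict(zip(out["group"], out["dice_mean"]))
        assert means["large"] - means["small"] == pytest.approx(0.12, abs=0.01)

    def test_exactly_one_mode_required(self):
        with pytest.raises(ValueError):
            stratify_summary(pd.DataFrame({"x": [1]}), ["x"])
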