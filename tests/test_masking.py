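"""Downstream masking: QC-mask application, OOF corruption, scoring deltas."""
import numpy as np
import pytest

from wsiqc.errors import SchemeError
from wsiqc.slide_model import ARTIFACT_SCHEME, LabelMask, Raster, TISSUE_SCHEME
from wsiqc.masking import (
    DetectionSet,
    accuracy_delta,
    apply_qc_mask,
    corrupt_roi_with_oof,
    filter_detections,
)
from wsiqc.synthetic import gen_tissue_texture

FOLD = ARTIFACT_SCHEME.index("fold")
OOF = ARTIFACT_SCHEME.index("out_of_focus")


def _amask(arr, mpp=1.0):
    return LabelMask(np.asarray(arr, dtype=np.uint8), mpp, ARTIFACT_SCHEME)


def _patch(seed=0, size=64):
    rng = np.random.default_rng(seed)
    return Raster(rng.integers(0, 256, (size, size, 3), dtype=np.uint8), 1.0)


class TestApplyQcMask:
    def test_clear_mask_leaves_patch_unchanged(self):
        patch = _patch(1)
        labels = np.ones((64, 64))  # clean tissue everywhere
        out, ignore = apply_qc_mask(patch, _amask(labels), "white")
        np.testing.assert_array_equal(out.pixels, patch.pixels)
        assert not ignore.any()

    def test_fold_block_filled_and_flagged(self):
        patch = _patch(2)
        labels = np.ones((64, 64))
        labels[10:20, 30:40] = FOLD
        out, ignore = apply_qc_mask(patch, _amask(labels), "white")
        block = np.zeros((64, 64), dtype=bool)
        block[10:20, 30:40] = True
        np.testing.assert_array_equal(ignore, block)
        assert (out.pixels[block] == 255).all()
        np.testing.assert_array_equal(out.pixels[~block], patch.pixels[~block])

    def test_ignore_label_policy_keeps_pixels(self):
        patch = _patch(3)
        labels = np.full((64, 64), FOLD)
        out, ignore = apply_qc_mask(patch, _amask(labels), "ignore_label")
        np.testing.assert_array_equal(out.pixels, patch.pixels)
        assert ignore.all()

    def test_masked_scoring_equals_clean_half(self):
        # left half artifact, right half clean: scoring with the ignore
        # mask must equal scoring the clean half alone
        from wsiqc.metrics import dice_per_class

        rng = np.random.default_rng(4)
        gt = rng.integers(0, 7, (32, 32)).astype(np.uint8)
        pred = rng.integers(0, 7, (32, 32)).astype(np.uint8)
        qc = np.ones((32, 32))
        qc[:, :16] = FOLD
        _, ignore = apply_qc_mask(_patch(5, 32), _amask(qc), "ignore_label")
        kept_scores, _ = dice_per_class(
            _amask(pred[~ignore.reshape(32, 32)][None, :]),
            _amask(gt[~ignore.reshape(32, 32)][None, :]),
        )
        right_scores, _ = dice_per_class(
            _amask(pred[:, 16:]), _amask(gt[:, 16:])
        )
        assert kept_scores == pytest.approx(right_scores, nan_ok=True)

    def test_tissue_scheme_rejected(self):
        bad = LabelMask(np.zeros((64, 64), dtype=np.uint8), 1.0, TISSUE_SCHEME)
        with pytest.raises(SchemeError):
            apply_qc_mask(_patch(6), bad)


class TestCorruptRoi:
    def test_default_reaches_30_percent(self):
        roi = gen_tissue_texture((256, 256), 1.0, 0.7, seed=7)
        out = corrupt_roi_with_oof(roi, seed=8)
        assert (out.gt.labels == OOF).mean() >= 0.30

    def test_identity_kernel(self):
        roi = gen_tissue_texture((128, 128), 1.0, 0.7, seed=9)
        out = corrupt_roi_with_oof(roi, kernel_sizes=[1], seed=10)
        np.testing.assert_array_equal(out.image.pixels, roi.image.pixels)

    def test_corruption_confined_to_binary_map(self):
        roi = gen_tissue_texture((128, 128), 1.0, 0.7, seed=11)
        out = corrupt_roi_with_oof(roi, seed=12)
        changed = (out.image.pixels != roi.image.pixels).any(axis=2)
        assert changed.any()
        assert not changed[~out.meta["oof_region"]].any()


class TestAccuracyDelta:
    def _scheme_masks(self, *arrays):
        return [_amask(a) for a in arrays]

    def test_corrected_equals_baseline_outside_ignore(self):
        rng = np.random.default_rng(13)
        gt = rng.integers(0, 7, (16, 16))
        base = rng.integers(0, 7, (16, 16))
        ignore = np.zeros((16, 16), dtype=bool)
        ignore[:8] = True
        corrected = base.copy()
        corrected[ignore] = rng.integers(0, 7, int(ignore.sum()))  # garbage under ignore
        gt_m, base_m, corr_m = self._scheme_masks(gt, base, corrected)
        table = accuracy_delta(gt_m, base_m, base_m, corr_m, ignore)
        # sentinel garbage must not leak into the corrected row: compare to
        # baseline scored on the kept pixels only
        from wsiqc.metrics import dice_per_class

        kept_scores, _ = dice_per_class(
            _amask(base[~ignore][None, :]), _amask(gt[~ignore][None, :])
        )
        corr_rows = table[table.condition == "corrected"].set_index("class")
        for name, expected in kept_scores.items():
            assert corr_rows.loc[name, "dice"] == pytest.approx(expected, nan_ok=True)

    def test_toy_sensitivity_specificity(self):
        # one-vs-rest counts for class 'fold': TP=3, FN=1, FP=1, TN=5
        gt = np.array([FOLD, FOLD, FOLD, FOLD, 1, 1, 1, 0, 0, 0])
        pred = np.array([FOLD, FOLD, FOLD, 1, FOLD, 1, 1, 0, 0, 0])
        gt_m, pred_m = self._scheme_masks(gt[None, :], pred[None, :])
        table = accuracy_delta(gt_m, pred_m, pred_m, pred_m, np.zeros((1, 10), dtype=bool))
        row = table[(table.condition == "baseline") & (table["class"] == "fold")].iloc[0]
        assert row.sensitivity == pytest.approx(0.75)
        assert row.specificity == pytest.approx(5 / 6, abs=1e-4)

    def test_identical_inputs_zero_delta(self):
        rng = np.random.default_rng(14)
        gt = rng.integers(0, 7, (12, 12))
        m = _amask(gt)
        table = accuracy_delta(m, m, m, m, np.zeros((12, 12), dtype=bool))
        defined = table.dropna(subset=["dice"])
        assert (defined.dice == 1.0).all()
        pivot = defined.pivot(index="class", columns="condition", values="dice")
        assert (pivot.baseline == pivot.corrupted).all()
        assert (pivot.baseline == pivot.corrected).all()


class TestFilterDetections:
    def _dets(self, points):
        return DetectionSet(points=points, mpp=1.0)

    def test_empty_set(self):
        mask = _amask(np.ones((8, 8)))
        assert len(filter_detections(self._dets([]), mask)) == 0

    def test_detection_on_fold_removed(self):
        labels = np.ones((8, 8))
        labels[4, 4] = FOLD
        mask = _amask(labels)
        out = filter_detections(self._dets([(4.0, 4.0, "tumor"), (1.0, 1.0, "tumor")]), mask)
        assert out.points == [(1.0, 1.0, "tumor")]

    def test_matches_per_point_oracle(self):
        rng = np.random.default_rng(15)
        labels = rng.integers(0, 7, (32, 32))
        mask = _amask(labels)
        points = [
            (float(rng.integers(0, 32)), float(rng.integers(0, 32)), "c")
            for _ in range(50)
        ]
        out = filter_detections(self._dets(points), mask)
        expected = [p for p in points if labels[int(p[1]), int(p[0])] < 2]
        assert out.points == expected

    def test_idempotent(self):
        rng = np.random.default_rng(16)
        labels = rng.integers(0, 7, (16, 16))
        mask = _amask(labels)
        dets = self._dets([(float(x), float(y), "c") for x in range(16) for y in range(16)])
        once = filter_detections(dets, mask)
        twice = filter_detections(once, mask)
        assert once.points == twice.points

    def test_monotone_in_mask(self):
        rng = np.random.default_rng(17)
        labels = rng.integers(0, 3, (16, 16))  # background/tissue/fold
        bigger = labels.copy()
        bigger[labels == 1] = np.where(
            rng.random((labels == 1).sum()) < 0.5, FOLD, 1
        )
        dets = self._dets([(float(x), float(y), "c") for x in range(16) for y in range(16)])
        kept_small = set(filter_detections(dets, _amask(labels)).points)
        kept_big = set(filter_detections(dets, _amask(bigger)).points)
        assert kept_big <= kept_small

    def test_out_of_extent_rejected(self, caplog):
        mask = _amask(np.ones((8, 8)))
        out = filter_detections(self._dets([(20.0, 1.0, "c")]), mask)
        assert len(out) == 0
        assert any("outside extent" in r.message for r in caplog.records)
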