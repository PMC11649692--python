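"""Quantify how artifact masking protects a downstream model's accuracy.

A clean ROI is scored by a stand-in downstream segmenter (the ground
truth plus colour-driven errors), then corrupted with synthetic
out-of-focus (>= 30% of the ROI blurred), then scored again with the
corrupted region excluded via the QC ignore mask. The printed table
shows the usual pattern: corruption drops accuracy, masking restores the
baseline on the retained pixels — masking prevents misclassification but
cannot recover structures inside the corrupted area.
"""
import numpy as np

from wsiqc import ARTIFACT_SCHEME
from wsiqc.masking import accuracy_delta, apply_qc_mask, corrupt_roi_with_oof
from wsiqc.slide_model import LabelMask, Raster
from wsiqc.synthetic import gen_tissue_texture

TISSUE = ARTIFACT_SCHEME.index("tissue_no_artifact")


def downstream_segmenter(pixels):
    """Stand-in tissue classifier that, like real segmenters, needs sharp
    texture: a pixel is 'tissue' when its neighbourhood shows stain contrast."""
    from scipy import ndimage

    gray = pixels.mean(axis=2)
    m = ndimage.uniform_filter(gray, 7)
    m2 = ndimage.uniform_filter(gray * gray, 7)
    local_std = np.sqrt(np.maximum(m2 - m * m, 0.0))
    return np.where(local_std > 6.0, TISSUE, 0).astype(np.uint8)


roi = gen_tissue_texture((256, 256), mpp=1.0, tissue_frac=0.6, seed=5)
gt = LabelMask((roi.gt.labels == TISSUE).astype(np.uint8) * TISSUE, 1.0, ARTIFACT_SCHEME)

pred_baseline = LabelMask(downstream_segmenter(roi.image.pixels), 1.0, ARTIFACT_SCHEME)

corrupted = corrupt_roi_with_oof(roi, min_frac=0.30, seed=6)
pred_corrupted = LabelMask(downstream_segmenter(corrupted.image.pixels), 1.0, ARTIFACT_SCHEME)

# QC step: the corrupted ground truth plays the role of the detected mask
_, ignore = apply_qc_mask(
    Raster(corrupted.image.pixels, 1.0), corrupted.gt, fill_policy="ignore_label"
)
table = accuracy_delta(gt, pred_baseline, pred_corrupted, pred_corrupted, ignore)

oof_pct = 100.0 * (corrupted.gt.labels == ARTIFACT_SCHEME.index("out_of_focus")).mean()
print(f"corrupted ROI: {oof_pct:.1f} % out of focus (blur kernel {corrupted.meta['oof_kernel']})")
rows = table[table["class"] == "tissue_no_artifact"].set_index("condition")
print("\n'tissue' accuracy of the downstream model per condition:")
print(rows[["dice", "sensitivity", "specificity"]].round(3))
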