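"""Downstream use-case machinery: artifact masking before other models.

Artifact masks from the QC pipeline are applied ahead of downstream
tissue-segmentation or cell-detection models in two ways:

* region masking (:func:`apply_qc_mask`) — artifact pixels are either
  filled white or flagged in an ignore mask; downstream *scoring* must
  exclude ignored pixels, since masking prevents misclassification in
  corrupted areas but cannot recover structures hidden by the artifact;
* detection filtering (:func:`filter_detections`) — point-like cell
  detections landing on artifact pixels are dropped.

:func:`corrupt_roi_with_oof` degrades clean regions of interest with the
synthetic out-of-focus procedure (Gaussian blur under a random binary map
covering at least 30% of the ROI by default) so the accuracy effect of
masking can be quantified with :func:`accuracy_delta`.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DomainError, SchemeError, ShapeError
from .slide_model import LabelMask, Raster
from .synthetic import DEFAULT_KERNEL_SIZES, LabeledSlide, OofSpec, inject_oof
from .tiling import resample_labels

__all__ = [
    "DetectionSet",
    "apply_qc_mask",
    "corrupt_roi_with_oof",
    "accuracy_delta",
    "filter_detections",
]

logger = logging.getLogger(__name__)


@dataclass
class DetectionSet:
    """Point-like detections (cell centres) at a stated resolution."""

    points: list[tuple[float, float, str]]  # (x, y, class label)
    mpp: float

    def __len__(self) -> int:
        return len(self.points)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.points, columns=["x", "y", "label"]).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, mpp: float) -> "DetectionSet":
        df = pd.read_csv(path)
        return cls(
            points=[(float(r.x), float(r.y), str(r.label)) for r in df.itertuples()],
            mpp=mpp,
        )


def _artifact_region(mask: LabelMask, patch_h: int, patch_w: int) -> np.ndarray:
    if mask.scheme.kind != "artifact":
        raise SchemeError("apply_qc_mask needs an artifact-scheme mask")
    labels = mask.labels
    if labels.shape != (patch_h, patch_w):
        labels = resample_labels(labels, patch_h, patch_w)
    # artifact classes are everything beyond background and clean tissue
    return labels >= 2


def apply_qc_mask(
    patch: Raster, artifact_mask: LabelMask, fill_policy: str = "ignore_label"
) -> tuple[Raster, np.ndarray]:
    """Mask artifact pixels in a patch; returns (patch, ignore mask).

    ``white`` fills artifact pixels with white; ``ignore_label`` leaves
    the image untouched. Either way the boolean ignore mask marks exactly
    the artifact pixels, and downstream scoring must exclude them.
    Non-artifact pixels are never altered.
    """
    if fill_policy not in ("white", "ignore_label"):
        raise DomainError("fill_policy must be 'white' or 'ignore_label'")
    ignore = _artifact_region(artifact_mask, patch.height, patch.width)
    pixels = patch.pixels.copy()
    if fill_policy == "white":
        pixels[ignore] = 255
    return Raster(pixels, patch.mpp), ignore


def corrupt_roi_with_oof(
    roi: LabeledSlide,
    min_frac: float = 0.30,
    kernel_sizes: Sequence[int] = DEFAULT_KERNEL_SIZES,
    seed: int = 0,
) -> LabeledSlide:
    """Degrade a clean ROI with synthetic out-of-focus.

    Delegates to :func:`wsiqc.synthetic.inject_oof`: a random smooth
    binary map covering at least ``min_frac`` of the ROI is blurred with a
    Gaussian kernel drawn from ``kernel_sizes``; the corrupted region is
    recorded in the ground truth for scoring.
    """
    return inject_oof(
        roi, OofSpec(min_frac=min_frac, kernel_sizes=tuple(kernel_sizes), seed=seed)
    )


def _binary_scores(
    pred: np.ndarray, gt: np.ndarray, class_idx: int
) -> tuple[float, float, float]:
    """One-vs-rest (dice, sensitivity, specificity) for a class."""
    p = pred == class_idx
    g = gt == class_idx
    tp = int((p & g).sum())
    fn = int((~p & g).sum())
    fp = int((p & ~g).sum())
    tn = int((~p & ~g).sum())
    dice = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else float("nan")
    sens = tp / (tp + fn) if (tp + fn) else float("nan")
    spec = tn / (tn + fp) if (tn + fp) else float("nan")
    return dice, sens, spec


def accuracy_delta(
    gt: LabelMask,
    pred_baseline: LabelMask,
    pred_corrupted: LabelMask,
    pred_corrected: LabelMask,
    ignore: np.ndarray,
) -> pd.DataFrame:
    """Condition x class table of Dice / sensitivity / specificity.

    Rows cover three conditions: ``baseline`` (clean ROI), ``corrupted``
    (degraded ROI, no QC), and ``corrected`` (degraded ROI with artifact
    masking) — the corrected condition is scored with the ignored
    (artifact) pixels excluded, the other two on all pixels.
    """
    masks = {
        "baseline": pred_baseline,
        "corrupted": pred_corrupted,
        "corrected": pred_corrected,
    }
    shape = gt.labels.shape
    for name, m in masks.items():
        if m.labels.shape != shape:
            raise ShapeError(f"{name} prediction shape {m.labels.shape} != {shape}")
        if m.scheme.names != gt.scheme.names:
            raise SchemeError(f"{name} prediction uses a different scheme")
    ignore = np.asarray(ignore, dtype=bool)
    if ignore.shape != shape:
        raise ShapeError("ignore mask shape mismatch")

    rows = []
    g_flat = gt.labels.reshape(-1)
    keep = ~ignore.reshape(-1)
    for condition, m in masks.items():
        p_flat = m.labels.reshape(-1)
        if condition == "corrected":
            p_use, g_use = p_flat[keep], g_flat[keep]
        else:
            p_use, g_use = p_flat, g_flat
        for c, name in enumerate(gt.scheme.names):
            dice, sens, spec = _binary_scores(p_use, g_use, c)
            rows.append(
                {
                    "condition": condition,
                    "class": name,
                    "dice": dice,
                    "sensitivity": sens,
                    "specificity": spec,
                }
            )
    return pd.DataFrame(rows)


def filter_detections(dets: DetectionSet, artifact_mask: LabelMask) -> DetectionSet:
    """Drop detections whose centre lies on an artifact-class pixel.

    Coordinates must be at the mask's MPP (resample first otherwise).
    Out-of-extent points are rejected with a log entry. Order is
    preserved; the operation is idempotent and monotone in the mask.
    """
    if artifact_mask.scheme.kind != "artifact":
        raise SchemeError("filter_detections needs an artifact-scheme mask")
    h, w = artifact_mask.labels.shape
    kept = []
    for (x, y, label) in dets.points:
        ix, iy = int(x), int(y)
        if not (0 <= ix < w and 0 <= iy < h):
            logger.warning("detection (%.1f, %.1f) outside extent, rejected", x, y)
            continue
        if artifact_mask.labels[iy, ix] >= 2:
            continue
        kept.append((x, y, label))
    return DetectionSet(points=kept, mpp=dets.mpp)
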