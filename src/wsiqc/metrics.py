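"""Segmentation accuracy metrics: per-class Dice, confusion matrices, and
row-normalised misclassification tables.

Dice for class c is ``2|P_c ∩ G_c| / (|P_c| + |G_c|)``. Classes absent from
both prediction and ground truth are reported as undefined (NaN) and are
excluded from the mean rather than scored 1.0 — scoring them perfect would
inflate results on artifact-free slides.

Dataset evaluation pools pixels over all patches before computing Dice
(micro aggregation), yielding one score per class; per-patch macro
averaging is available as an option.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DataError, SchemeError, ShapeError
from .slide_model import ClassScheme, LabelMask
from .synthetic import LabeledSlide

__all__ = [
    "ConfusionMatrix",
    "dice_per_class",
    "confusion_matrix",
    "misclassification_table",
    "evaluate_dataset",
]


def _check_pair(pred: LabelMask, gt: LabelMask) -> None:
    if pred.labels.shape != gt.labels.shape:
        raise ShapeError(
            f"prediction {pred.labels.shape} vs ground truth {gt.labels.shape}"
        )
    if pred.scheme.names != gt.scheme.names:
        raise SchemeError("prediction and ground truth use different schemes")


def dice_per_class(pred: LabelMask, gt: LabelMask) -> tuple[dict[str, float], float]:
    """Per-class Dice scores and their mean over defined classes.

    Returns ``(scores, mean)`` where ``scores`` maps every class name to
    its Dice, with NaN for classes absent from both masks; ``mean``
    averages the defined classes only.
    """
    _check_pair(pred, gt)
    scheme = gt.scheme
    p = pred.labels.reshape(-1)
    g = gt.labels.reshape(-1)
    K = len(scheme)
    p_counts = np.bincount(p, minlength=K).astype(np.float64)
    g_counts = np.bincount(g, minlength=K).astype(np.float64)
    inter = np.bincount(g[p == g], minlength=K).astype(np.float64)
    scores: dict[str, float] = {}
    defined = []
    for c, name in enumerate(scheme.names):
        denom = p_counts[c] + g_counts[c]
        if denom == 0:
            scores[name] = float("nan")
        else:
            d = 2.0 * inter[c] / denom
            scores[name] = d
            defined.append(d)
    mean = float(np.mean(defined)) if defined else float("nan")
    return scores, mean


@dataclass
class ConfusionMatrix:
    """K x K pixel counts; rows are ground truth, columns are prediction."""

    counts: np.ndarray
    scheme: ClassScheme

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        K = len(self.scheme)
        if self.counts.shape != (K, K):
            raise ShapeError(f"counts must be {K}x{K}")
        if (self.counts < 0).any():
            raise ShapeError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=list(self.scheme.names), columns=list(self.scheme.names)
        )


def confusion_matrix(pred: LabelMask, gt: LabelMask) -> ConfusionMatrix:
    """``counts[i, j]`` = pixels with ground truth i predicted as j."""
    _check_pair(pred, gt)
    K = len(gt.scheme)
    flat = gt.labels.reshape(-1).astype(np.int64) * K + pred.labels.reshape(-1)
    counts = np.bincount(flat, minlength=K * K).reshape(K, K)
    return ConfusionMatrix(counts=counts, scheme=gt.scheme)


def misclassification_table(cm: ConfusionMatrix) -> tuple[pd.DataFrame, list[str]]:
    """Row-normalised percentages: where did each true class's pixels go.

    Each reported row sums to 100. Classes with zero ground-truth pixels
    are omitted and returned in the second element.
    """
    counts = cm.counts.astype(np.float64)
    row_sums = counts.sum(axis=1)
    keep = row_sums > 0
    omitted = [name for name, k in zip(cm.scheme.names, keep) if not k]
    pct = 100.0 * counts[keep] / row_sums[keep, None]
    idx = [name for name, k in zip(cm.scheme.names, keep) if k]
    return pd.DataFrame(pct, index=idx, columns=list(cm.scheme.names)), omitted


def evaluate_dataset(
    bundle,
    pairs: Sequence[LabeledSlide],
    aggregation: str = "micro",
) -> pd.DataFrame:
    """Per-class Dice for a trained model over labelled pairs.

    ``micro`` (default) pools pixels over all pairs before computing one
    Dice per class; ``macro`` averages per-pair Dice over pairs where the
    class is defined. Returns a one-row-per-class DataFrame with columns
    ``dice`` and ``n_gt_pixels``.
    """
    from .segmentation import predict, _labels_for_scheme

    if not pairs:
        raise DataError("empty evaluation set")
    if aggregation not in ("micro", "macro"):
        raise DataError("aggregation must be 'micro' or 'macro'")
    scheme = bundle.config.scheme
    K = len(scheme)

    if aggregation == "micro":
        inter = np.zeros(K)
        p_counts = np.zeros(K)
        g_counts = np.zeros(K)
        for pair in pairs:
            (pred_mask, _), = predict(bundle, [pair.image])
            p = pred_mask.labels.reshape(-1)
            g = _labels_for_scheme(pair, scheme).reshape(-1)
            p_counts += np.bincount(p, minlength=K)
            g_counts += np.bincount(g, minlength=K)
            inter += np.bincount(g[p == g], minlength=K)
        denom = p_counts + g_counts
        dice = np.where(denom > 0, 2.0 * inter / np.maximum(denom, 1), np.nan)
        return pd.DataFrame(
            {"dice": dice, "n_gt_pixels": g_counts.astype(int)},
            index=list(scheme.names),
        )

    per_class: list[list[float]] = [[] for _ in range(K)]
    g_tot = np.zeros(K)
    for pair in pairs:
        (pred_mask, _), = predict(bundle, [pair.image])
        gt_mask = LabelMask(_labels_for_scheme(pair, scheme), pair.gt.mpp, scheme)
        scores, _ = dice_per_class(pred_mask, gt_mask)
        g_tot += np.bincount(gt_mask.labels.reshape(-1), minlength=K)
        for c, name in enumerate(scheme.names):
            if not np.isnan(scores[name]):
                per_class[c].append(scores[name])
    dice = np.array([np.mean(v) if v else np.nan for v in per_class])
    return pd.DataFrame(
        {"dice": dice, "n_gt_pixels": g_tot.astype(int)}, index=list(scheme.names)
    )
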