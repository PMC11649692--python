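"""Patch-grid planning, tissue-gated tile filtering, and mask stitching.

Grids are planned at a single target MPP; under the default
``shift_to_fit`` edge policy, boxes that would overrun an edge are shifted
back to end flush with it (so a ``(w, h, p, p)`` plan has exactly
``ceil(w/p) * ceil(h/p)`` boxes and fully covers the extent without
padding). Under ``pad`` the grid is regular and the slide is conceptually
padded; extraction fills the overhang.

Overlapping tiles are resolved last-written-wins in row-major plan order;
with stride == patch size (the default) no overlaps occur.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

from .errors import DomainError, SchemeError, ShapeError
from .slide_model import Box, ClassScheme, LabelMask, PatchGrid

__all__ = [
    "TilePlan",
    "plan_tiles",
    "filter_tiles_by_tissue",
    "stitch_masks",
    "resample_mask",
    "resample_labels",
    "extract_patch",
]

EdgePolicy = Literal["shift_to_fit", "pad"]


@dataclass
class TilePlan:
    grid: PatchGrid
    slide_dims: tuple[int, int]  # (w, h) at the plan's MPP
    edge_policy: EdgePolicy = "shift_to_fit"
    mpp: float | None = None

    @property
    def boxes(self) -> list[Box]:
        return self.grid.boxes

    def __len__(self) -> int:
        return len(self.grid.boxes)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "boxes": self.grid.boxes,
                    "patch_size": self.grid.patch_size,
                    "stride": self.grid.stride,
                    "slide_dims": self.slide_dims,
                    "edge_policy": self.edge_policy,
                    "mpp": self.mpp,
                }
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "TilePlan":
        d = json.loads(Path(path).read_text())
        return cls(
            grid=PatchGrid(
                boxes=[tuple(b) for b in d["boxes"]],
                patch_size=d["patch_size"],
                stride=d["stride"],
            ),
            slide_dims=tuple(d["slide_dims"]),
            edge_policy=d["edge_policy"],
            mpp=d["mpp"],
        )


def _axis_coords(dim: int, patch: int, stride: int, policy: EdgePolicy) -> list[int]:
    if policy == "shift_to_fit":
        if dim <= patch:
            return [0]
        xs = []
        x = 0
        while x + patch < dim:
            xs.append(x)
            x += stride
        last = dim - patch
        if not xs or xs[-1] != last:
            xs.append(last)
        return xs
    # pad: regular grid, overhang handled at extraction time
    return list(range(0, dim, stride))


def plan_tiles(
    w: int,
    h: int,
    patch_size: int,
    stride: int | None = None,
    edge_policy: EdgePolicy = "shift_to_fit",
    mpp: float | None = None,
) -> TilePlan:
    """Row-major grid of ``patch_size`` boxes covering a ``w x h`` extent.

    With ``shift_to_fit``, edge boxes are shifted back to end flush; an
    extent smaller than the patch yields a single clipped box. With
    ``pad``, boxes keep the full patch size and may overrun the extent.
    """
    stride = patch_size if stride is None else stride
    if patch_size < 1 or stride < 1:
        raise DomainError("patch_size and stride must be >= 1")
    if w < 1 or h < 1:
        raise DomainError("extent must be at least 1x1")
    boxes: list[Box] = []
    seen = set()
    for y in _axis_coords(h, patch_size, stride, edge_policy):
        for x in _axis_coords(w, patch_size, stride, edge_policy):
            bw = min(patch_size, w - x) if edge_policy == "shift_to_fit" else patch_size
            bh = min(patch_size, h - y) if edge_policy == "shift_to_fit" else patch_size
            box = (x, y, bw, bh)
            if box not in seen:
                seen.add(box)
                boxes.append(box)
    return TilePlan(
        grid=PatchGrid(boxes=boxes, patch_size=patch_size, stride=stride),
        slide_dims=(w, h),
        edge_policy=edge_policy,
        mpp=mpp,
    )


def resample_labels(labels: np.ndarray, out_h: int, out_w: int) -> np.ndarray:
    """Nearest-neighbour resample of an integer label array (no new labels)."""
    h, w = labels.shape
    ys = np.minimum(((np.arange(out_h) + 0.5) * h / out_h).astype(np.int64), h - 1)
    xs = np.minimum(((np.arange(out_w) + 0.5) * w / out_w).astype(np.int64), w - 1)
    return labels[np.ix_(ys, xs)]


def resample_mask(mask: LabelMask, target_mpp: float) -> LabelMask:
    """Nearest-neighbour resample of a mask to a new MPP.

    Output dims are ``round(dims * mpp / target_mpp)``; the output label
    set is always a subset of the input's.
    """
    if not (target_mpp > 0):
        raise DomainError("target_mpp must be positive")
    if abs(target_mpp - mask.mpp) < 1e-12:
        return LabelMask(mask.labels.copy(), mask.mpp, mask.scheme)
    scale = mask.mpp / target_mpp
    out_w = max(1, int(np.floor(mask.width * scale + 0.5)))
    out_h = max(1, int(np.floor(mask.height * scale + 0.5)))
    return LabelMask(resample_labels(mask.labels, out_h, out_w), target_mpp, mask.scheme)


def filter_tiles_by_tissue(
    plan: TilePlan, tissue_mask: LabelMask, min_tissue_frac: float = 0.0
) -> TilePlan:
    """Keep boxes whose tissue fraction meets the threshold.

    The tissue mask (2-class scheme, any MPP) is resampled to the plan's
    extent first. A box is retained iff its tissue fraction is positive
    and >= ``min_tissue_frac`` — with the default threshold of 0 this
    means "touches tissue at all". Box order is preserved.
    """
    if tissue_mask.scheme.kind != "tissue":
        raise SchemeError("filter_tiles_by_tissue needs a tissue-scheme mask")
    w, h = plan.slide_dims
    tl = resample_labels(tissue_mask.labels, h, w)
    tissue = tl == 1
    kept: list[Box] = []
    for (x, y, bw, bh) in plan.boxes:
        sub = tissue[y : min(y + bh, h), x : min(x + bw, w)]
        frac = float(sub.mean()) if sub.size else 0.0
        if frac > 0 and frac >= min_tissue_frac:
            kept.append((x, y, bw, bh))
    return TilePlan(
        grid=PatchGrid(boxes=kept, patch_size=plan.grid.patch_size, stride=plan.grid.stride),
        slide_dims=plan.slide_dims,
        edge_policy=plan.edge_policy,
        mpp=plan.mpp,
    )


def stitch_masks(
    patch_masks: Sequence[LabelMask],
    plan: TilePlan,
    fill: int = 0,
    scheme: ClassScheme | None = None,
    mpp: float | None = None,
) -> LabelMask:
    """Paste per-patch masks back onto the slide canvas.

    One mask per plan box, in order. Uncovered pixels get ``fill``;
    overlaps are resolved last-written-wins in plan order. Masks larger
    than their box (pad policy) are cropped to the canvas.
    """
    if len(patch_masks) != len(plan.boxes):
        raise ShapeError(
            f"{len(patch_masks)} masks for {len(plan.boxes)} boxes"
        )
    if patch_masks:
        scheme = scheme or patch_masks[0].scheme
        mpp = mpp if mpp is not None else patch_masks[0].mpp
    if scheme is None:
        raise SchemeError("empty plan requires an explicit scheme")
    if mpp is None:
        mpp = plan.mpp if plan.mpp is not None else 1.0
    w, h = plan.slide_dims
    canvas = np.full((h, w), fill, dtype=np.uint8)
    for mask, (x, y, bw, bh) in zip(patch_masks, plan.boxes):
        ch = min(mask.height, h - y)
        cw = min(mask.width, w - x)
        if ch <= 0 or cw <= 0:
            continue
        canvas[y : y + ch, x : x + cw] = mask.labels[:ch, :cw]
    return LabelMask(canvas, mpp, scheme)


def extract_patch(
    array: np.ndarray, box: Box, patch_size: int | None = None, fill=0
) -> np.ndarray:
    """Crop ``box`` from a 2-D or 3-D array, padding with ``fill`` if needed.

    When ``patch_size`` is given the result is padded (bottom/right) up to
    ``patch_size`` squared — used for clipped edge tiles fed to a
    fixed-input-size model.
    """
    x, y, bw, bh = box
    h, w = array.shape[:2]
    crop = array[y : min(y + bh, h), x : min(x + bw, w)]
    th = patch_size if patch_size is not None else bh
    tw = patch_size if patch_size is not None else bw
    if crop.shape[0] == th and crop.shape[1] == tw:
        return crop.copy()
    pad_shape = (th, tw) + array.shape[2:]
    out = np.full(pad_shape, fill, dtype=array.dtype)
    out[: crop.shape[0], : crop.shape[1]] = crop
    return out
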