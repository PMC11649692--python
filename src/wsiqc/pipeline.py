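"""Two-stage slide QC pipeline: tissue detection gating artifact detection.

A slide is first segmented into tissue vs. background at low magnification
(MPP 10, i.e. ~1x objective); the resulting tissue mask gates the
multi-class artifact model, which runs at one of three magnification
variants (10x/7x/5x, MPP 1.0/1.4286/2.0) and only inside tissue — every
pixel the tissue module calls background is forced to background in the
artifact mask, and tiles containing no tissue are skipped entirely.

The per-slide summary reports tissue area in mm² and the percentage of
tissue area occupied by each artifact class; percentages, including the
artifact-free remainder, always sum to 100.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
from PIL import Image

from .errors import DomainError, SchemeError
from .slide_model import (
    ARTIFACT_SCHEME,
    ClassScheme,
    LabelMask,
    Raster,
    SlidePyramid,
    TISSUE_SCHEME,
    read_region,
)
from .segmentation import ModelBundle, predict
from .tiling import (
    TilePlan,
    extract_patch,
    filter_tiles_by_tissue,
    plan_tiles,
    resample_labels,
    resample_mask,
    stitch_masks,
)

__all__ = [
    "SlideSummary",
    "TISSUE_MPP",
    "VARIANT_MPP",
    "run_tissue_module",
    "run_artifact_module",
    "slide_summary",
    "make_overlay",
    "export_outputs",
    "load_mask_png",
    "polygons_from_mask",
]

#: Tissue detection runs at ~1x objective magnification.
TISSUE_MPP = 10.0

#: Artifact-model variants and their working resolutions.
VARIANT_MPP = {"10x": 1.0, "7x": 10.0 / 7.0, "5x": 2.0}

_ARTIFACT_CLASSES = ("fold", "dark_spot_foreign", "pen_marking", "air_bubble_edge", "out_of_focus")


@dataclass
class SlideSummary:
    """Per-slide QC summary feeding the benchmark statistics."""

    slide_id: str
    tissue_area_mm2: float
    class_pct: dict[str, float]  # artifact classes, % of tissue area
    artifact_free_pct: float
    any_artifact_pct: float
    variant: str | None = None
    valid: bool = True

    def to_dict(self) -> dict:
        return asdict(self)


def _predict_tiles(
    slide: SlidePyramid, bundle: ModelBundle, plan: TilePlan, target_mpp: float
) -> list[LabelMask]:
    """Predict every plan box, padding clipped edge tiles with white."""
    p = bundle.config.patch_size
    masks = []
    for box in plan.boxes:
        x, y, bw, bh = box
        raster = read_region(slide, target_mpp, (x, y, bw, bh))
        if bw != p or bh != p:
            padded = extract_patch(raster.pixels, (0, 0, bw, bh), patch_size=p, fill=255)
            raster = Raster(padded, target_mpp)
        (mask, _), = predict(bundle, [raster])
        masks.append(LabelMask(mask.labels[:bh, :bw], target_mpp, mask.scheme))
    return masks


def run_tissue_module(slide: SlidePyramid, bundle: ModelBundle) -> LabelMask:
    """Tissue/background mask of the whole slide at MPP 10."""
    if bundle.config.scheme.kind != "tissue":
        raise SchemeError("run_tissue_module needs a tissue-scheme bundle")
    w, h = slide.dims_at(TISSUE_MPP)
    plan = plan_tiles(w, h, bundle.config.patch_size, edge_policy="shift_to_fit", mpp=TISSUE_MPP)
    masks = _predict_tiles(slide, bundle, plan, TISSUE_MPP)
    return stitch_masks(masks, plan, fill=0, scheme=TISSUE_SCHEME, mpp=TISSUE_MPP)


def run_artifact_module(
    slide: SlidePyramid,
    tissue_mask: LabelMask,
    bundle: ModelBundle,
    variant: str = "10x",
    min_tissue_frac: float = 0.0,
) -> LabelMask:
    """Multi-class artifact mask at the variant's resolution, tissue-gated.

    Tiles without tissue are skipped; after stitching, every pixel outside
    the (resampled) tissue mask is forced to background, so the artifact
    mask inherits the background class from the tissue module.
    """
    if bundle.config.scheme.kind != "artifact":
        raise SchemeError("run_artifact_module needs an artifact-scheme bundle")
    if variant not in VARIANT_MPP:
        raise DomainError(f"variant must be one of {sorted(VARIANT_MPP)}")
    target_mpp = VARIANT_MPP[variant]
    if abs(bundle.config.mpp - target_mpp) > 1e-3 * max(target_mpp, 1.0):
        raise DomainError(
            f"bundle mpp {bundle.config.mpp} does not match variant {variant} "
            f"(mpp {target_mpp:.4f})"
        )
    if tissue_mask.scheme.kind != "tissue":
        raise SchemeError("tissue_mask must use the tissue scheme")

    w, h = slide.dims_at(target_mpp)
    plan = plan_tiles(w, h, bundle.config.patch_size, edge_policy="shift_to_fit", mpp=target_mpp)
    plan = filter_tiles_by_tissue(plan, tissue_mask, min_tissue_frac)
    masks = _predict_tiles(slide, bundle, plan, target_mpp)
    stitched = stitch_masks(masks, plan, fill=0, scheme=ARTIFACT_SCHEME, mpp=target_mpp)

    tissue = resample_labels(tissue_mask.labels, h, w) == 1
    labels = stitched.labels
    labels[~tissue] = 0
    return LabelMask(labels, target_mpp, ARTIFACT_SCHEME)


def slide_summary(mask: LabelMask, slide_id: str, variant: str | None = None) -> SlideSummary:
    """Artifact burden of one slide from its artifact mask.

    Tissue area counts every non-background pixel; each class percentage
    is (class pixels / tissue pixels) * 100. A mask without tissue yields
    NaN percentages and ``valid=False``.
    """
    if mask.scheme.kind != "artifact":
        raise SchemeError("slide_summary needs an artifact-scheme mask")
    labels = mask.labels
    tissue_px = int((labels > 0).sum())
    area_mm2 = tissue_px * (mask.mpp / 1000.0) ** 2
    if tissue_px == 0:
        nan = float("nan")
        return SlideSummary(
            slide_id=slide_id,
            tissue_area_mm2=0.0,
            class_pct={c: nan for c in _ARTIFACT_CLASSES},
            artifact_free_pct=nan,
            any_artifact_pct=nan,
            variant=variant,
            valid=False,
        )
    class_pct = {
        name: 100.0 * int((labels == mask.scheme.index(name)).sum()) / tissue_px
        for name in _ARTIFACT_CLASSES
    }
    free = 100.0 * int((labels == mask.scheme.index("tissue_no_artifact")).sum()) / tissue_px
    return SlideSummary(
        slide_id=slide_id,
        tissue_area_mm2=area_mm2,
        class_pct=class_pct,
        artifact_free_pct=free,
        any_artifact_pct=100.0 - free,
        variant=variant,
    )


def make_overlay(image: Raster, mask: LabelMask, alpha: float = 0.5) -> Raster:
    """Blend the class palette onto the image over labelled pixels.

    Background pixels are untouched; the mask is resampled (nearest) to
    the image geometry first.
    """
    if not (0.0 <= alpha <= 1.0):
        raise DomainError("alpha must be in [0, 1]")
    labels = resample_labels(mask.labels, image.height, image.width)
    palette = mask.scheme.palette_array().astype(np.float64)
    out = image.pixels.astype(np.float64).copy()
    labelled = labels > 0
    out[labelled] = (1.0 - alpha) * out[labelled] + alpha * palette[labels[labelled]]
    return Raster(np.clip(np.rint(out), 0, 255).astype(np.uint8), image.mpp)


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------

def _runs_to_boxes(row: np.ndarray, y: int) -> list[tuple[int, int, int, int]]:
    """Horizontal runs of True in one row as (x0, y0, x1, y1) unit-row boxes."""
    diff = np.diff(np.concatenate(([0], row.view(np.int8), [0])))
    starts = np.nonzero(diff == 1)[0]
    ends = np.nonzero(diff == -1)[0]
    return [(int(s), y, int(e), y + 1) for s, e in zip(starts, ends)]


def polygons_from_mask(mask: LabelMask, class_idx: int):
    """Pixel-exact shapely (multi)polygon of one class, in pixel coordinates."""
    from shapely import box as shapely_box, union_all

    region = mask.labels == class_idx
    boxes = []
    for y in range(region.shape[0]):
        boxes.extend(_runs_to_boxes(region[y], y))
    if not boxes:
        return None
    return union_all([shapely_box(x0, y0, x1, y1) for x0, y0, x1, y1 in boxes])


def export_outputs(
    mask: LabelMask,
    summary: SlideSummary,
    out_dir: str | Path,
    stem: str | None = None,
) -> dict[str, Path]:
    """Write the paletted PNG mask, per-class GeoJSON polygons, JSON summary.

    The PNG round-trips bit-exactly through :func:`load_mask_png`; the
    GeoJSON carries one Feature per class present (coordinates in pixels
    at the mask's MPP, class name and MPP in ``properties``).
    """
    from shapely.geometry import mapping

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stem = stem or summary.slide_id

    png_path = out_dir / f"{stem}_mask.png"
    pal = Image.fromarray(mask.labels, mode="P")
    pal.putpalette(mask.scheme.palette_array().flatten().tolist())
    pal.save(png_path)

    features = []
    for c, name in enumerate(mask.scheme.names):
        if c == 0:
            continue
        geom = polygons_from_mask(mask, c)
        if geom is None:
            continue
        features.append(
            {
                "type": "Feature",
                "geometry": mapping(geom),
                "properties": {"class": name, "class_index": c, "mpp": mask.mpp},
            }
        )
    geojson_path = out_dir / f"{stem}_mask.geojson"
    geojson_path.write_text(
        json.dumps({"type": "FeatureCollection", "features": features})
    )

    summary_path = out_dir / f"{stem}_summary.json"
    summary_path.write_text(json.dumps(summary.to_dict(), indent=1))
    return {"mask_png": png_path, "geojson": geojson_path, "summary": summary_path}


def load_mask_png(path: str | Path, mpp: float, scheme: ClassScheme) -> LabelMask:
    """Read back a paletted mask PNG written by :func:`export_outputs`."""
    img = Image.open(path)
    return LabelMask(np.asarray(img, dtype=np.uint8), mpp, scheme)
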