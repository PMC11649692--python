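"""Core raster / pyramid / class-scheme data model.

Conventions used throughout the package:

* Coordinates are 0-based with x growing rightwards and y downwards.
  Boxes are ``(x, y, w, h)`` and half-open, expressed at the microns-per-pixel
  (MPP) of the raster they index.
* Magnification <-> resolution follows the linear rule ``mpp = 10 / power``,
  anchored at the two standard pairs 40x ~ 0.25 MPP and 10x ~ 1.0 MPP.
  Scanners with odd base resolutions are handled by resampling, never by
  re-anchoring this rule.
* Images are downsampled by area averaging; label masks are resampled with
  nearest-neighbour so they can never gain labels that were not present.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
from PIL import Image

from .errors import (
    BoundsError,
    DomainError,
    MappingError,
    ResolutionError,
    SchemeError,
)

__all__ = [
    "Raster",
    "SlidePyramid",
    "ClassScheme",
    "LabelMask",
    "PatchGrid",
    "TISSUE_SCHEME",
    "ARTIFACT_SCHEME",
    "RAW_ANNOTATION_CLASSES",
    "ARTIFACT_CLASS_NAMES",
    "mpp_for_power",
    "merge_annotation_classes",
    "read_region",
    "pyramid_from_array",
    "open_slide",
]

Box = tuple[int, int, int, int]


# ---------------------------------------------------------------------------
# class schemes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClassScheme:
    """Ordered list of class names with a display palette.

    Index 0 is always ``background``. Two schemes are used: the 2-class
    tissue scheme (tissue detection) and the 7-class artifact scheme
    (multi-class artifact detection, after merging visually similar
    annotation classes).
    """

    names: tuple[str, ...]
    palette: tuple[tuple[int, int, int], ...]
    kind: Literal["tissue", "artifact"]

    def __post_init__(self) -> None:
        if len(self.names) != len(set(self.names)):
            raise SchemeError("class names must be unique")
        if len(self.palette) != len(self.names):
            raise SchemeError("palette must have one colour per class")
        if self.names[0] != "background":
            raise SchemeError("index 0 must be 'background'")

    def __len__(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError as exc:
            raise MappingError(f"unknown class {name!r}") from exc

    def palette_array(self) -> np.ndarray:
        """Palette as a (K, 3) uint8 array."""
        return np.asarray(self.palette, dtype=np.uint8)


TISSUE_SCHEME = ClassScheme(
    names=("background", "tissue"),
    palette=((255, 255, 255), (90, 170, 90)),
    kind="tissue",
)

ARTIFACT_CLASS_NAMES = (
    "background",
    "tissue_no_artifact",
    "fold",
    "dark_spot_foreign",
    "pen_marking",
    "air_bubble_edge",
    "out_of_focus",
)

ARTIFACT_SCHEME = ClassScheme(
    names=ARTIFACT_CLASS_NAMES,
    palette=(
        (255, 255, 255),   # background: white, as in slide overlays
        (120, 200, 120),   # tissue without artifacts
        (220, 60, 60),     # fold
        (40, 110, 40),     # dark spot / foreign object
        (50, 70, 220),     # pen marking
        (240, 170, 40),    # air bubble / slide edge
        (160, 90, 210),    # out of focus
    ),
    kind="artifact",
)

#: The nine raw annotation classes before merging.
RAW_ANNOTATION_CLASSES = (
    "background",
    "tissue",
    "fold",
    "dark_spot",
    "foreign_object",
    "pen_marking",
    "air_bubble",
    "slide_edge",
    "out_of_focus",
)

_MERGE_MAP = {
    "background": "background",
    "tissue": "tissue_no_artifact",
    "fold": "fold",
    "dark_spot": "dark_spot_foreign",
    "foreign_object": "dark_spot_foreign",
    "pen_marking": "pen_marking",
    "air_bubble": "air_bubble_edge",
    "slide_edge": "air_bubble_edge",
    "out_of_focus": "out_of_focus",
}


def merge_annotation_classes(raw_label: str) -> int:
    """Map one of the nine raw annotation classes to the 7-class scheme.

    Air bubbles and slide edges are merged into one class, as are dark
    spots and foreign objects, because they are visually near-identical;
    all other classes map to the identically named target class. Returns
    the index in :data:`ARTIFACT_SCHEME`.
    """
    try:
        target = _MERGE_MAP[raw_label]
    except KeyError as exc:
        raise MappingError(f"unknown raw annotation class {raw_label!r}") from exc
    return ARTIFACT_SCHEME.index(target)


# ---------------------------------------------------------------------------
# rasters and masks
# ---------------------------------------------------------------------------

@dataclass
class Raster:
    """An 8-bit RGB raster with a physical resolution in microns per pixel."""

    pixels: np.ndarray
    mpp: float

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.uint8)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise DomainError("pixels must be an (H, W, 3) array")
        if self.pixels.shape[0] < 1 or self.pixels.shape[1] < 1:
            raise DomainError("raster must be at least 1x1")
        if not (self.mpp > 0):
            raise DomainError("mpp must be positive")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass
class LabelMask:
    """Integer class raster bound to a :class:`ClassScheme` and an MPP."""

    labels: np.ndarray
    mpp: float
    scheme: ClassScheme

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise DomainError("labels must be a 2-D array")
        if self.labels.shape[0] < 1 or self.labels.shape[1] < 1:
            raise DomainError("mask must be at least 1x1")
        if not (self.mpp > 0):
            raise DomainError("mpp must be positive")
        if self.labels.size and (
            self.labels.min() < 0 or self.labels.max() >= len(self.scheme)
        ):
            raise SchemeError("labels outside the class scheme")
        self.labels = self.labels.astype(np.uint8, copy=False)

    @property
    def height(self) -> int:
        return self.labels.shape[0]

    @property
    def width(self) -> int:
        return self.labels.shape[1]


@dataclass
class PatchGrid:
    """A list of half-open patch boxes at a stated resolution."""

    boxes: list[Box]
    patch_size: int
    stride: int


# ---------------------------------------------------------------------------
# magnification convention
# ---------------------------------------------------------------------------

def mpp_for_power(power: float) -> float:
    """Microns per pixel for an objective magnification.

    Linear convention ``mpp = 10 / power``: 40x -> 0.25, 10x -> 1.0,
    7x -> 1.4286, 5x -> 2.0, 1x -> 10.0.
    """
    if not (power > 0):
        raise DomainError("objective power must be positive")
    return 10.0 / float(power)


# ---------------------------------------------------------------------------
# pyramids
# ---------------------------------------------------------------------------

def _dims_at(width: int, height: int, src_mpp: float, dst_mpp: float) -> tuple[int, int]:
    """Raster extent when resampled from ``src_mpp`` to ``dst_mpp``.

    Uses round-half-up, matching the dimension contract of the pipeline.
    """
    scale = src_mpp / dst_mpp
    return (
        max(1, int(math.floor(width * scale + 0.5))),
        max(1, int(math.floor(height * scale + 0.5))),
    )


def _box_downsample(img: np.ndarray, w: int, h: int) -> np.ndarray:
    """Area-average (box filter) resize of an RGB uint8 image."""
    pil = Image.fromarray(img)
    return np.asarray(pil.resize((w, h), resample=Image.Resampling.BOX))


@dataclass
class SlidePyramid:
    """Multi-resolution RGB pyramid; level 0 is the base (finest) level."""

    levels: list[Raster]
    base_mpp: float = field(init=False)

    def __post_init__(self) -> None:
        if not self.levels:
            raise DomainError("pyramid must have at least one level")
        self.base_mpp = self.levels[0].mpp
        ds = self.downsamples
        if any(b <= a for a, b in zip(ds, ds[1:])):
            raise DomainError("level downsamples must be strictly increasing")
        if abs(ds[0] - 1.0) > 1e-9:
            raise DomainError("level 0 must have downsample 1")
        base = self.levels[0]
        for lvl, d in zip(self.levels, ds):
            ew = math.ceil(base.width / d)
            eh = math.ceil(base.height / d)
            if abs(lvl.width - ew) > 1 or abs(lvl.height - eh) > 1:
                raise DomainError(
                    f"level dims {lvl.width}x{lvl.height} inconsistent with "
                    f"downsample {d:g}"
                )

    @property
    def downsamples(self) -> list[float]:
        return [lvl.mpp / self.levels[0].mpp for lvl in self.levels]

    @property
    def width(self) -> int:
        return self.levels[0].width

    @property
    def height(self) -> int:
        return self.levels[0].height

    def dims_at(self, target_mpp: float) -> tuple[int, int]:
        """Slide extent (w, h) when viewed at ``target_mpp``."""
        return _dims_at(self.width, self.height, self.base_mpp, target_mpp)


def pyramid_from_array(
    pixels: np.ndarray, mpp: float, levels: int | None = None, min_size: int = 64
) -> SlidePyramid:
    """Wrap a plain RGB array as a pyramid, building 2x box-filtered levels.

    ``levels=None`` keeps halving until the smaller dimension drops below
    ``min_size``; ``levels=1`` wraps the array as a single-level pyramid.
    """
    base = Raster(pixels, mpp)
    out = [base]
    while (levels is None and min(out[-1].width, out[-1].height) >= 2 * min_size) or (
        levels is not None and len(out) < levels
    ):
        prev = out[-1]
        w, h = math.ceil(prev.width / 2), math.ceil(prev.height / 2)
        if w == prev.width and h == prev.height:
            break
        out.append(Raster(_box_downsample(prev.pixels, w, h), prev.mpp * 2))
    return SlidePyramid(out)


def read_region(slide: SlidePyramid, target_mpp: float, box: Box) -> Raster:
    """Read a region at an arbitrary resolution coarser than the base level.

    ``box`` is ``(x, y, w, h)`` at ``target_mpp``. The nearest pyramid level
    with ``level_mpp <= target_mpp`` is cropped and box-filter resampled to
    exactly ``(w, h)``. A request at the base MPP is a bit-exact crop.
    """
    if not (target_mpp > 0):
        raise DomainError("target_mpp must be positive")
    if target_mpp < slide.base_mpp - 1e-9:
        raise ResolutionError(
            f"target mpp {target_mpp} finer than base mpp {slide.base_mpp}"
        )
    x, y, w, h = box
    if w < 1 or h < 1:
        raise DomainError("box must have positive size")
    ew, eh = slide.dims_at(target_mpp)
    if x < 0 or y < 0 or x + w > ew or y + h > eh:
        raise BoundsError(f"box {box} outside extent {(ew, eh)} at mpp {target_mpp}")

    # nearest level not coarser than the request
    candidates = [lvl for lvl in slide.levels if lvl.mpp <= target_mpp + 1e-9]
    level = max(candidates, key=lambda lvl: lvl.mpp)
    scale = target_mpp / level.mpp

    if abs(scale - 1.0) < 1e-9:
        return Raster(level.pixels[y : y + h, x : x + w].copy(), target_mpp)

    sx0 = int(math.floor(x * scale))
    sy0 = int(math.floor(y * scale))
    sx1 = min(level.width, int(math.ceil((x + w) * scale)))
    sy1 = min(level.height, int(math.ceil((y + h) * scale)))
    crop = level.pixels[sy0:sy1, sx0:sx1]
    return Raster(_box_downsample(crop, w, h), target_mpp)


# ---------------------------------------------------------------------------
# file readers
# ---------------------------------------------------------------------------

_TIFF_SUFFIXES = {".tif", ".tiff", ".svs"}


def _sidecar_mpp(path: Path) -> float | None:
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        if "mpp" in meta:
            return float(meta["mpp"])
    return None


def _tiff_page_mpp(page) -> float | None:
    """MPP from TIFF resolution tags (RESUNIT cm or inch)."""
    tags = page.tags
    if "XResolution" not in tags or "ResolutionUnit" not in tags:
        return None
    num, den = tags["XResolution"].value
    if num == 0 or den == 0:
        return None
    px_per_unit = num / den
    unit = int(tags["ResolutionUnit"].value)
    if unit == 3:  # centimetre
        return 10_000.0 / px_per_unit
    if unit == 2:  # inch
        return 25_400.0 / px_per_unit
    return None


def open_slide(path: str | Path, mpp: float | None = None) -> SlidePyramid:
    """Open a pyramidal TIFF/SVS-style file or a plain PNG/JPEG raster.

    MPP is taken from, in order: the ``mpp`` argument, a ``<name>.<ext>.json``
    sidecar (``{"mpp": ...}``), or — for TIFF — the resolution tags.
    Plain rasters are wrapped as single-level pyramids.
    """
    path = Path(path)
    if path.suffix.lower() in _TIFF_SUFFIXES:
        import tifffile

        with tifffile.TiffFile(path) as tf:
            series = tf.series[0]
            arrays = [np.asarray(lvl.asarray()) for lvl in series.levels]
            if mpp is None:
                mpp = _sidecar_mpp(path)
            if mpp is None:
                mpp = _tiff_page_mpp(series.pages[0])
        if mpp is None:
            raise DomainError(f"no MPP metadata for {path}; pass mpp=")
        levels = []
        base_w = arrays[0].shape[1]
        for arr in arrays:
            if arr.ndim == 2:
                arr = np.stack([arr] * 3, axis=-1)
            ds = base_w / arr.shape[1]
            levels.append(Raster(arr, mpp * ds))
        return SlidePyramid(levels)

    img = np.asarray(Image.open(path).convert("RGB"))
    if mpp is None:
        mpp = _sidecar_mpp(path)
    if mpp is None:
        raise DomainError(f"no MPP metadata for {path}; pass mpp=")
    return SlidePyramid([Raster(img, mpp)])
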