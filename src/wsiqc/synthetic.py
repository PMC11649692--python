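"""Synthetic H&E-like slides with injected artifacts and exact ground truth.

Generates stained-tissue look-alikes on a near-white background and injects
the artifact families seen on real glass slides — tissue folds, air-bubble /
slide-edge rims, dark spots and thread-like foreign objects, pen markings,
melanin-like pigment (a labelled confounder that alters the image but not
the ground truth), and synthetic out-of-focus (OOF) regions produced by
Gaussian-blurring the image under a random smooth binary map so that at
least a minimum fraction of the region is out of focus.

Every generator is a pure function of its seed: the same spec always yields
the bit-identical image and ground-truth mask.

Ground-truth precedence when artifacts overlap (opaque occludes translucent):

    pen_marking > air_bubble_edge > fold > dark_spot_foreign
        > out_of_focus > tissue_no_artifact > background

Pen markings and bubble rims may extend over background and are labelled
there too; OOF is only ever labelled where the pre-OOF label was
``tissue_no_artifact``.
"""
from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from PIL import Image
from scipy import ndimage

from .errors import DomainError, GenerationError, MappingError
from .slide_model import ARTIFACT_SCHEME, ClassScheme, LabelMask, Raster

__all__ = [
    "ArtifactSpec",
    "OofSpec",
    "SlideSpec",
    "LabeledSlide",
    "PRECEDENCE",
    "DEFAULT_KERNEL_SIZES",
    "gen_tissue_texture",
    "inject_artifact",
    "inject_oof",
    "compose_synthetic_slide",
    "random_slide_spec",
    "gen_dataset",
    "write_dataset",
]

ARTIFACT_KINDS = ("fold", "dark_spot_foreign", "pen_marking", "air_bubble_edge", "pigment")

#: Default Gaussian kernel sizes for synthetic out-of-focus: odd sizes 3..17.
DEFAULT_KERNEL_SIZES: tuple[int, ...] = tuple(range(3, 18, 2))

#: Ground-truth precedence rank per artifact-scheme class (higher wins).
PRECEDENCE: dict[str, int] = {
    "background": 0,
    "tissue_no_artifact": 1,
    "out_of_focus": 2,
    "dark_spot_foreign": 3,
    "fold": 4,
    "air_bubble_edge": 5,
    "pen_marking": 6,
}

_RANK = np.zeros(len(ARTIFACT_SCHEME), dtype=np.int64)
for _name, _rank in PRECEDENCE.items():
    _RANK[ARTIFACT_SCHEME.index(_name)] = _rank

_BG = ARTIFACT_SCHEME.index("background")
_TISSUE = ARTIFACT_SCHEME.index("tissue_no_artifact")
_OOF = ARTIFACT_SCHEME.index("out_of_focus")


# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ArtifactSpec:
    """One artifact to inject: a kind, kind-specific geometry, severity, seed.

    Geometry keys not supplied are drawn reproducibly from ``seed``.
    ``severity`` in [0, 1] scales opacity/darkening of the artifact.
    """

    kind: str
    geometry: dict = field(default_factory=dict)
    severity: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ARTIFACT_KINDS:
            raise MappingError(f"unknown artifact kind {self.kind!r}")
        if not (0.0 <= self.severity <= 1.0):
            raise DomainError("severity must be in [0, 1]")


@dataclass(frozen=True)
class OofSpec:
    """Synthetic out-of-focus spec: minimum covered fraction and kernel sizes."""

    min_frac: float = 0.30
    kernel_sizes: tuple[int, ...] = DEFAULT_KERNEL_SIZES
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.min_frac <= 1.0):
            raise DomainError("min_frac must be in (0, 1]")
        if not self.kernel_sizes:
            raise DomainError("kernel_sizes must be non-empty")
        for k in self.kernel_sizes:
            if k < 1 or k % 2 == 0:
                raise DomainError("kernel sizes must be odd and >= 1")


@dataclass(frozen=True)
class SlideSpec:
    """Full recipe for one synthetic slide."""

    size: tuple[int, int] = (512, 512)  # (w, h) px
    mpp: float = 1.0
    tissue_frac: float = 0.65
    artifacts: tuple[ArtifactSpec, ...] = ()
    oof: OofSpec | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        w, h = self.size
        if w < 64 or h < 64:
            raise DomainError("slide must be at least 64x64 px")
        if not (0.0 < self.tissue_frac < 1.0):
            raise DomainError("tissue_frac must be in (0, 1)")
        if not (self.mpp > 0):
            raise DomainError("mpp must be positive")
        object.__setattr__(self, "artifacts", tuple(self.artifacts))


@dataclass
class LabeledSlide:
    """A synthetic image with its pixel-exact artifact-scheme ground truth."""

    image: Raster
    gt: LabelMask
    provenance: SlideSpec | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.image.pixels.shape[:2] != self.gt.labels.shape:
            raise DomainError("image and ground truth dims must match")
        if abs(self.image.mpp - self.gt.mpp) > 1e-9:
            raise DomainError("image and ground truth MPP must match")
        if self.gt.scheme.kind != "artifact":
            raise DomainError("ground truth must use the artifact scheme")


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _smooth_noise(rng: np.random.Generator, shape: tuple[int, int], sigma: float) -> np.ndarray:
    """Low-frequency scalar field in roughly [0, 1] (smoothed uniform noise)."""
    field_ = ndimage.gaussian_filter(rng.random(shape), sigma=sigma, mode="reflect")
    lo, hi = field_.min(), field_.max()
    return (field_ - lo) / (hi - lo + 1e-12)


def _write_label(gt: np.ndarray, region: np.ndarray, class_idx: int) -> None:
    """Write ``class_idx`` into ``gt`` over ``region`` under precedence."""
    gt[region & (_RANK[gt] < _RANK[class_idx])] = class_idx


def _disk_mask(shape: tuple[int, int], cx: float, cy: float, r: float) -> np.ndarray:
    h, w = shape
    yy, xx = np.ogrid[:h, :w]
    return (xx - cx) ** 2 + (yy - cy) ** 2 <= r * r


def _curve_mask(
    shape: tuple[int, int],
    p0: tuple[float, float],
    p1: tuple[float, float],
    amp: float,
    width: float,
) -> np.ndarray:
    """Thick, slightly wavy stroke from p0 to p1 (union of disks)."""
    h, w = shape
    n = int(max(abs(p1[0] - p0[0]), abs(p1[1] - p0[1]), 2)) * 2
    t = np.linspace(0.0, 1.0, n)
    dx, dy = p1[0] - p0[0], p1[1] - p0[1]
    norm = math.hypot(dx, dy) + 1e-9
    nx, ny = -dy / norm, dx / norm
    wig = amp * np.sin(2 * math.pi * 1.7 * t)
    xs = p0[0] + t * dx + wig * nx
    ys = p0[1] + t * dy + wig * ny
    mask = np.zeros(shape, dtype=bool)
    r = max(1, int(round(width / 2)))
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    disk = (xx ** 2 + yy ** 2) <= r * r
    dys, dxs = np.nonzero(disk)
    dys, dxs = dys - r, dxs - r
    for x, y in zip(xs, ys):
        ix, iy = int(round(x)), int(round(y))
        py = iy + dys
        px = ix + dxs
        ok = (py >= 0) & (py < h) & (px >= 0) & (px < w)
        mask[py[ok], px[ok]] = True
    return mask


def _ellipse_mask(
    shape: tuple[int, int],
    cx: float,
    cy: float,
    a: float,
    b: float,
    theta: float,
) -> np.ndarray:
    """Normalised elliptical radius <= 1."""
    h, w = shape
    yy, xx = np.mgrid[:h, :w]
    ct, st = math.cos(theta), math.sin(theta)
    u = (xx - cx) * ct + (yy - cy) * st
    v = -(xx - cx) * st + (yy - cy) * ct
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def _ellipse_radius(
    shape: tuple[int, int], cx: float, cy: float, a: float, b: float, theta: float
) -> np.ndarray:
    h, w = shape
    yy, xx = np.mgrid[:h, :w]
    ct, st = math.cos(theta), math.sin(theta)
    u = (xx - cx) * ct + (yy - cy) * st
    v = -(xx - cx) * st + (yy - cy) * ct
    return np.sqrt((u / a) ** 2 + (v / b) ** 2)


def _blend(img: np.ndarray, region: np.ndarray, colour: Sequence[float], alpha: float) -> None:
    """In-place alpha blend of a flat colour into ``img`` over ``region``."""
    c = np.asarray(colour, dtype=np.float64)
    img[region] = np.clip(
        (1.0 - alpha) * img[region].astype(np.float64) + alpha * c, 0, 255
    ).astype(np.uint8)


def _gaussian_kernel1d(ksize: int) -> np.ndarray:
    """1-D Gaussian of length ``ksize`` with the OpenCV sigma convention."""
    if ksize == 1:
        return np.array([1.0])
    sigma = 0.3 * ((ksize - 1) * 0.5 - 1) + 0.8
    x = np.arange(ksize) - (ksize - 1) / 2
    k = np.exp(-(x ** 2) / (2 * sigma ** 2))
    return k / k.sum()


def gaussian_blur(img: np.ndarray, ksize: int) -> np.ndarray:
    """Separable Gaussian blur of an RGB uint8 image with an odd kernel size.

    ``ksize=1`` is the exact identity.
    """
    if ksize == 1:
        return img.copy()
    k = _gaussian_kernel1d(ksize)
    out = img.astype(np.float64)
    out = ndimage.convolve1d(out, k, axis=0, mode="reflect")
    out = ndimage.convolve1d(out, k, axis=1, mode="reflect")
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# tissue texture
# ---------------------------------------------------------------------------

_EOSIN_PINK = np.array([228.0, 148.0, 186.0])
_HEMATOX_PURPLE = np.array([126.0, 82.0, 158.0])
_NUCLEUS = np.array([72.0, 44.0, 112.0])


def gen_tissue_texture(
    size: tuple[int, int],
    mpp: float = 1.0,
    tissue_frac: float = 0.65,
    seed: int = 0,
) -> LabeledSlide:
    """Generate artifact-free H&E-like tissue on a near-white background.

    The tissue support is a low-frequency noise field thresholded at the
    ``1 - tissue_frac`` quantile, so the achieved coverage is essentially
    exact. Tissue pixels blend eosin pink with hematoxylin purple plus a
    dark nuclear speckle and fine intensity noise (the texture the OOF
    blur later destroys); background pixels stay in [233, 252] per channel.
    """
    spec = SlideSpec(size=size, mpp=mpp, tissue_frac=tissue_frac, seed=seed)
    w, h = size
    rng = np.random.default_rng(seed)

    support_field = _smooth_noise(rng, (h, w), sigma=min(h, w) / 8)
    thr = np.quantile(support_field, 1.0 - tissue_frac)
    tissue = support_field >= thr

    # background: bright, slightly noisy
    img = (238.0 + 14.0 * rng.random((h, w, 3))).astype(np.float64)

    # tissue: pink/purple blend + nuclei + fine texture
    stain = _smooth_noise(rng, (h, w), sigma=6.0)[..., None]
    tissue_rgb = _EOSIN_PINK * (1 - stain) + _HEMATOX_PURPLE * stain
    nuc_field = ndimage.gaussian_filter(rng.random((h, w)), sigma=1.2, mode="reflect")
    nuclei = nuc_field > np.quantile(nuc_field, 0.88)
    fine = rng.normal(0.0, 9.0, size=(h, w, 1))
    tissue_rgb = tissue_rgb + fine
    tissue_rgb[nuclei] = _NUCLEUS + fine[nuclei]
    img[tissue] = tissue_rgb[tissue]

    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    # keep the background contract airtight after noise/rounding
    bg = ~tissue
    img[bg] = np.maximum(img[bg], 233)

    gt = np.where(tissue, _TISSUE, _BG).astype(np.uint8)
    return LabeledSlide(
        image=Raster(img, mpp),
        gt=LabelMask(gt, mpp, ARTIFACT_SCHEME),
        provenance=spec,
    )


# ---------------------------------------------------------------------------
# artifact injection
# ---------------------------------------------------------------------------

def _geom(rng: np.random.Generator, geometry: dict, key: str, default):
    return geometry[key] if key in geometry else default(rng)


def inject_artifact(labeled: LabeledSlide, spec: ArtifactSpec) -> LabeledSlide:
    """Inject one artifact, altering the image and (except pigment) the mask.

    * ``fold`` — a darkened, duplicated band along a wavy stroke.
    * ``air_bubble_edge`` — washed-out ellipse interior with a dark rim.
    * ``dark_spot_foreign`` — small dark blobs plus a thread-like curve.
    * ``pen_marking`` — saturated opaque stroke.
    * ``pigment`` — dark brown blobs; image only, ground truth unchanged
      (a deliberate confounder resembling melanin).

    Ground truth is written under the fixed precedence order, so opaque
    artifacts occlude translucent ones regardless of injection order.
    """
    img = labeled.image.pixels.copy()
    gt = labeled.gt.labels.copy()
    h, w = gt.shape
    rng = np.random.default_rng(spec.seed)
    g = spec.geometry
    sev = spec.severity

    if spec.kind == "fold":
        p0 = _geom(rng, g, "p0", lambda r: (r.uniform(0.1, 0.9) * w, r.uniform(0.1, 0.9) * h))
        p1 = _geom(rng, g, "p1", lambda r: (r.uniform(0.1, 0.9) * w, r.uniform(0.1, 0.9) * h))
        width = _geom(rng, g, "width", lambda r: r.uniform(0.03, 0.08) * min(w, h))
        band = _curve_mask((h, w), p0, p1, amp=width * 0.8, width=width)
        # duplicated section: overlay a shifted copy, then darken
        shift = max(2, int(round(width / 3)))
        shifted = np.roll(np.roll(img, shift, axis=0), shift, axis=1)
        dark = 1.0 - (0.35 + 0.25 * sev)
        mixed = 0.55 * img[band].astype(np.float64) + 0.45 * shifted[band].astype(np.float64)
        img[band] = np.clip(mixed * dark, 0, 255).astype(np.uint8)
        _write_label(gt, band, ARTIFACT_SCHEME.index("fold"))

    elif spec.kind == "air_bubble_edge":
        cx = _geom(rng, g, "cx", lambda r: r.uniform(0.2, 0.8) * w)
        cy = _geom(rng, g, "cy", lambda r: r.uniform(0.2, 0.8) * h)
        a = _geom(rng, g, "a", lambda r: r.uniform(0.12, 0.3) * w)
        b = _geom(rng, g, "b", lambda r: r.uniform(0.12, 0.3) * h)
        theta = _geom(rng, g, "theta", lambda r: r.uniform(0, math.pi))
        rr = _ellipse_radius((h, w), cx, cy, a, b, theta)
        inside = rr <= 1.0
        rim = (rr <= 1.0) & (rr >= 0.86)
        _blend(img, inside & ~rim, (236.0, 236.0, 238.0), 0.35 + 0.35 * sev)
        _blend(img, rim, (60.0, 58.0, 62.0), 0.55 + 0.4 * sev)
        _write_label(gt, inside, ARTIFACT_SCHEME.index("air_bubble_edge"))

    elif spec.kind == "dark_spot_foreign":
        n_blobs = _geom(rng, g, "n_blobs", lambda r: int(r.integers(3, 9)))
        region = np.zeros((h, w), dtype=bool)
        for _ in range(n_blobs):
            cx, cy = rng.uniform(0.1, 0.9) * w, rng.uniform(0.1, 0.9) * h
            r0 = rng.uniform(1.5, 0.02 * min(w, h) + 2.0)
            region |= _disk_mask((h, w), cx, cy, r0)
        if _geom(rng, g, "thread", lambda r: bool(r.random() < 0.5)):
            p0 = (rng.uniform(0.1, 0.9) * w, rng.uniform(0.1, 0.9) * h)
            p1 = (rng.uniform(0.1, 0.9) * w, rng.uniform(0.1, 0.9) * h)
            region |= _curve_mask((h, w), p0, p1, amp=6.0, width=2.0)
        _blend(img, region, (52.0, 48.0, 46.0), 0.6 + 0.4 * sev)
        _write_label(gt, region, ARTIFACT_SCHEME.index("dark_spot_foreign"))

    elif spec.kind == "pen_marking":
        palette = [(20.0, 120.0, 60.0), (30.0, 60.0, 200.0), (25.0, 25.0, 25.0), (190.0, 30.0, 40.0)]
        colour = _geom(rng, g, "colour", lambda r: palette[int(r.integers(len(palette)))])
        p0 = _geom(rng, g, "p0", lambda r: (r.uniform(0.05, 0.95) * w, r.uniform(0.05, 0.95) * h))
        p1 = _geom(rng, g, "p1", lambda r: (r.uniform(0.05, 0.95) * w, r.uniform(0.05, 0.95) * h))
        width = _geom(rng, g, "width", lambda r: r.uniform(0.015, 0.04) * min(w, h))
        stroke = _curve_mask((h, w), p0, p1, amp=width, width=width)
        _blend(img, stroke, colour, 0.55 + 0.45 * sev)
        _write_label(gt, stroke, ARTIFACT_SCHEME.index("pen_marking"))

    elif spec.kind == "pigment":
        n_blobs = _geom(rng, g, "n_blobs", lambda r: int(r.integers(4, 10)))
        region = np.zeros((h, w), dtype=bool)
        for _ in range(n_blobs):
            cx, cy = rng.uniform(0.1, 0.9) * w, rng.uniform(0.1, 0.9) * h
            r0 = rng.uniform(1.0, 0.015 * min(w, h) + 1.5)
            region |= _disk_mask((h, w), cx, cy, r0)
        # image only: melanin-like brown; the ground truth stays unchanged
        _blend(img, region, (92.0, 62.0, 32.0), 0.5 + 0.4 * sev)

    else:  # pragma: no cover - guarded by ArtifactSpec
        raise MappingError(f"unknown artifact kind {spec.kind!r}")

    return LabeledSlide(
        image=Raster(img, labeled.image.mpp),
        gt=LabelMask(gt, labeled.gt.mpp, ARTIFACT_SCHEME),
        provenance=labeled.provenance,
        meta=dict(labeled.meta),
    )


# ---------------------------------------------------------------------------
# synthetic out-of-focus
# ---------------------------------------------------------------------------

def inject_oof(labeled: LabeledSlide, oof: OofSpec) -> LabeledSlide:
    """Blur a random smooth region so >= ``min_frac`` of the slide is OOF.

    A low-frequency noise field is thresholded at the exact per-pixel
    quantile that makes the selected region cover at least
    ``min_frac * (total pixels)`` eligible pixels, where eligible means the
    current ground-truth label is ``tissue_no_artifact`` (OOF never
    relabels background or a higher-precedence artifact). The image is
    blurred inside the selected region with one Gaussian kernel whose size
    is drawn uniformly from ``kernel_sizes``; the blur never leaks outside
    the region. The chosen kernel size is recorded in ``meta['oof_kernel']``.
    """
    gt = labeled.gt.labels.copy()
    h, w = gt.shape
    n_total = h * w
    rng = np.random.default_rng(oof.seed)

    eligible = gt == _TISSUE
    k_needed = int(math.ceil(oof.min_frac * n_total))
    already = int((gt == _OOF).sum())
    if eligible.sum() + already < k_needed:
        raise GenerationError(
            f"cannot reach OOF fraction {oof.min_frac:.2f}: only "
            f"{eligible.sum() / n_total:.2%} of pixels are eligible tissue"
        )

    noise = _smooth_noise(rng, (h, w), sigma=min(h, w) / 6)
    elig_vals = np.sort(noise[eligible])
    need_new = max(0, k_needed - already)
    if need_new == 0:
        thr = -np.inf
    else:
        thr = elig_vals[need_new - 1]
    region = noise <= thr

    ksize = int(rng.choice(np.asarray(oof.kernel_sizes)))
    img = labeled.image.pixels.copy()
    if ksize > 1 and region.any():
        blurred = gaussian_blur(labeled.image.pixels, ksize)
        img[region] = blurred[region]

    _write_label(gt, region & eligible, _OOF)

    meta = dict(labeled.meta)
    meta["oof_kernel"] = ksize
    meta["oof_region"] = region
    return LabeledSlide(
        image=Raster(img, labeled.image.mpp),
        gt=LabelMask(gt, labeled.gt.mpp, ARTIFACT_SCHEME),
        provenance=labeled.provenance,
        meta=meta,
    )


# ---------------------------------------------------------------------------
# composition and datasets
# ---------------------------------------------------------------------------

def compose_synthetic_slide(spec: SlideSpec) -> LabeledSlide:
    """Texture, then artifacts in list order, then OOF last.

    Artifact specs with ``seed=None``-like defaults are re-seeded
    deterministically from the slide seed and their position, so the whole
    slide is a pure function of ``spec``.
    """
    out = gen_tissue_texture(spec.size, spec.mpp, spec.tissue_frac, spec.seed)
    for i, art in enumerate(spec.artifacts):
        derived = (spec.seed * 9176 + 31 * (i + 1)) % (2**31)
        art_seed = art.seed if art.seed != 0 else derived
        out = inject_artifact(out, replace(art, seed=art_seed))
    if spec.oof is not None:
        oof_seed = spec.oof.seed if spec.oof.seed != 0 else (spec.seed * 7919 + 17) % (2**31)
        out = inject_oof(out, replace(spec.oof, seed=oof_seed))
    out.provenance = spec
    return out


def random_slide_spec(
    seed: int,
    size: tuple[int, int] = (512, 512),
    mpp: float = 1.0,
    kinds: Sequence[str] | None = None,
    with_oof: bool = False,
    tissue_frac: float | None = None,
) -> SlideSpec:
    """A reproducible random slide recipe containing the given artifact kinds."""
    rng = np.random.default_rng(seed)
    if tissue_frac is None:
        tissue_frac = float(rng.uniform(0.5, 0.8))
    arts = tuple(
        ArtifactSpec(kind=k, seed=int(rng.integers(1, 2**31)))
        for k in (kinds or ())
    )
    oof = OofSpec(seed=int(rng.integers(1, 2**31))) if with_oof else None
    return SlideSpec(
        size=size, mpp=mpp, tissue_frac=tissue_frac, artifacts=arts, oof=oof, seed=seed
    )


_BALANCE_CYCLE = ("fold", "dark_spot_foreign", "pen_marking", "air_bubble_edge", "oof")


def gen_dataset(
    n: int,
    patch_size: int = 96,
    mpp: float = 1.0,
    seed: int = 0,
    balanced: bool = True,
) -> list[LabeledSlide]:
    """Generate ``n`` labelled patches for training/evaluation.

    With ``balanced=True`` the five artifact classes are cycled so each is
    guaranteed in ~20% of patches (well above the 5% floor); extra kinds
    and pigment confounders are added at random. Pure function of
    ``(n, patch_size, mpp, seed)``.
    """
    if n < 1:
        raise DomainError("n must be >= 1")
    out: list[LabeledSlide] = []
    for i in range(n):
        sub_seed = (seed * 100_003 + i) % (2**31)
        rng = np.random.default_rng(sub_seed)
        kinds: list[str] = []
        with_oof = False
        if balanced:
            forced = _BALANCE_CYCLE[i % len(_BALANCE_CYCLE)]
            if forced == "oof":
                with_oof = True
            else:
                kinds.append(forced)
        for k in ("fold", "dark_spot_foreign", "pen_marking", "air_bubble_edge"):
            if k not in kinds and rng.random() < 0.18:
                kinds.append(k)
        if not with_oof and rng.random() < 0.2:
            with_oof = True
        if rng.random() < 0.12:
            kinds.append("pigment")
        # OOF needs enough clean tissue; keep coverage generous
        tf = float(rng.uniform(0.55, 0.8))
        spec = random_slide_spec(
            sub_seed,
            size=(patch_size, patch_size),
            mpp=mpp,
            kinds=kinds,
            with_oof=with_oof,
            tissue_frac=tf,
        )
        try:
            out.append(compose_synthetic_slide(spec))
        except GenerationError:
            # heavy artifact load left too little clean tissue for OOF
            spec = replace(spec, oof=None)
            out.append(compose_synthetic_slide(spec))
    return out


def write_dataset(pairs: Sequence[LabeledSlide], out_dir: str | Path) -> Path:
    """Write image/mask PNG pairs plus a manifest CSV; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = out_dir / "manifest.csv"
    palette = ARTIFACT_SCHEME.palette_array().flatten().tolist()
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["patch_id", "image", "mask", "seed", "classes_present"])
        for i, pair in enumerate(pairs):
            img_name, mask_name = f"patch_{i:05d}.png", f"patch_{i:05d}_mask.png"
            Image.fromarray(pair.image.pixels).save(out_dir / img_name)
            pal_img = Image.fromarray(pair.gt.labels, mode="P")
            pal_img.putpalette(palette)
            pal_img.save(out_dir / mask_name)
            present = sorted(
                ARTIFACT_SCHEME.names[c] for c in np.unique(pair.gt.labels)
            )
            seed = pair.provenance.seed if pair.provenance else ""
            writer.writerow([i, img_name, mask_name, seed, ";".join(present)])
    return manifest
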