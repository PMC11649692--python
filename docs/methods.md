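# Methods

This note documents the models, conventions and design choices behind
`wsiqc`, in the spirit of a model-documentation page: what is computed, under
which assumptions, and what the synthetic experiments do and do not show.

## Coordinate and magnification conventions

All rasters carry a physical resolution in microns per pixel (MPP). Boxes
are `(x, y, w, h)`, 0-based, half-open, x right / y down, expressed at the
MPP of the raster they index. Magnification and MPP are linked linearly,
`mpp = 10 / power`, anchored at the two standard pairs 40x ≈ 0.25 MPP and
10x = 1.0 MPP; scanners with odd base resolutions are handled by
resampling, never by re-anchoring. Tissue detection runs at MPP 10
(~1x objective); the three artifact-model variants run at MPP 1.0 (10x),
10/7 ≈ 1.429 (7x) and 2.0 (5x).

Images are resampled by area averaging (box filter) when downsampling;
label masks always use nearest-neighbour so a resampled mask can never
contain a label absent from its source. Region reads from a pyramid pick
the nearest level at least as fine as the request and box-filter down;
a request at the base MPP is a bit-exact crop.

## Class schemes

The tissue scheme is `[background, tissue]`. The artifact scheme has seven
classes: `background, tissue_no_artifact, fold, dark_spot_foreign,
pen_marking, air_bubble_edge, out_of_focus`. Nine raw annotation classes
collapse onto it: air bubbles and slide edges merge into one class, as do
dark spots and foreign objects, because the pairs are visually
near-identical at working magnification. Index 0 is always background, and
the mask palette is a fixed table chosen for legibility (the exact colours
are a package choice).

## Synthetic slide simulator

The simulator exists so that training, evaluation and every test run
without external data. It emulates the *geometry and optics* of slide
artifacts, not the histology of any organ:

* **Tissue texture.** A low-frequency noise field thresholded at the
  `1 - tissue_frac` quantile defines the tissue support (so achieved
  coverage is essentially exact). Tissue colour blends eosin pink with
  hematoxylin purple along a second smooth field, plus a dark nuclear
  speckle and per-pixel intensity noise — the high-frequency texture that
  defocus blur later destroys. Background stays in [233, 255] per channel.
* **Artifacts.** Folds are darkened, duplicated bands along wavy strokes;
  air bubbles are washed-out ellipses with dark rims; dark spots/foreign
  objects are small dark blobs plus optional thread-like curves; pen
  markings are saturated opaque strokes; *pigment* is a melanin-like brown
  blob pattern that alters the image only — a deliberately unlabelled
  confounder mimicking the known pigment/air-bubble ambiguity in melanoma
  slides. `severity` (default 0.7) scales opacity/darkening linearly.
* **Ground-truth precedence.** When artifacts overlap, the label follows a
  fixed total order — `pen_marking > air_bubble_edge > fold >
  dark_spot_foreign > out_of_focus > tissue_no_artifact > background` —
  chosen so opaque artifacts occlude translucent ones; the result is
  independent of injection order. Pen and bubble labels may extend over
  background (artifacts do cross tissue borders); out-of-focus is only
  ever labelled where the previous label was clean tissue.
* **Synthetic out-of-focus.** A smoothed uniform-noise field is
  thresholded at the exact quantile that makes the selected region cover
  at least `min_frac` (default 0.30) of the slide in eligible (clean
  tissue) pixels; the image inside the region is blurred with one Gaussian
  kernel whose size is drawn uniformly from the odd sizes {3, 5, …, 17}.
  Kernel size maps to sigma by the common convolution-library convention
  `sigma = 0.3*((k-1)/2 - 1) + 0.8`; `k = 1` is the exact identity. The
  uniform kernel-size distribution is a neutral default; any distribution
  over 3–17 is consistent with the procedure. If the slide does not
  contain enough clean tissue to reach `min_frac`, generation fails
  loudly rather than under-delivering.
* **Determinism.** Every generator is a pure function of its seed; the
  same spec reproduces the bit-identical image and mask.

What passing tests on this simulator show: that the pipeline, training
loop, gating, metrics and statistics are correct, and that the feature set
separates the synthetic artifact appearances. What they do not show:
accuracy on real H&E slides, whose stain variability, scanner noise and
artifact morphology are far richer. The simulator makes no attempt at
photorealism or organ-specific appearance.

## Segmentation backend

Both modules are pixel-wise semantic segmentation models implemented as
multiscale pixel classification: each pixel is described by raw RGB,
Gaussian-smoothed RGB, local standard deviation of luminance, absolute
Laplacian-of-Gaussian of luminance (a focus cue that collapses under
defocus), and Sobel gradient magnitude; a small fully-connected softmax
network maps features to class probabilities. Two widths exist: `compact`
(scales 1/2/4 px, one hidden layer of 32 — the desk-scale default) and
`paper` (scales 0.7–8 px, two hidden layers of 64, for larger datasets).

Training samples up to `pixels_per_patch` (default 1500) random pixels per
patch, normalises features by the training mean/std (stored in the model
bundle), and minimises `0.7 * weighted cross-entropy + 0.3 * soft-Dice`
with minibatch Adam (default lr 3e-3, batch 1024, 25 epochs). Class
weights default to inverse-square-root frequency, capped at 10, so rare
artifact classes keep gradient; explicit per-class weights override this.
`epochs = 0` returns the input unchanged; single-threaded runs with a
fixed seed are bit-reproducible, and per-epoch history records training
loss and validation mean Dice. Inference is deterministic; labels are the
per-pixel argmax with ties resolved to the lower class index.

The receptive field of the feature bank (a few pixels) suits region-scale
artifacts at the working magnifications; it cannot use long-range shape
context the way a deep encoder–decoder can, which is the main accuracy
limitation on real data. The model-bundle interface (config, weights,
normalisation, history) is backend-agnostic.

## Pipeline

Tissue masks are produced by tiling the slide at MPP 10 into
patch-size boxes (edge boxes shifted to end flush; extents smaller than a
patch yield one clipped, white-padded tile), predicting, and stitching.
The artifact module tiles at the variant MPP, drops tiles whose resampled
tissue fraction is zero (or below `min_tissue_frac` if set), predicts the
rest, stitches with background fill, and finally forces every pixel
outside the tissue mask to background — the artifact mask *inherits*
background from the tissue module rather than re-deciding it. Overlapping
tiles (only possible with stride < patch) resolve last-written-wins in
row-major order. No morphological post-processing is applied by default;
the masks are raw pixel-wise output.

Per-slide summaries count every non-background pixel as tissue
(`area_mm2 = pixels * (mpp/1000)^2`) and report each artifact class as a
percentage of tissue; percentages including the artifact-free remainder
sum to 100 by construction, and a tissue-free slide yields NaN
percentages with an explicit `valid=False` flag. Masks export as paletted
PNG (bit-exact round trip), GeoJSON polygons (unions of per-row pixel-run
rectangles — rasterising them back reproduces the mask exactly), and a
JSON summary.

## Benchmark statistics

Group statistics are Tukey box-plot quantities: linear-interpolation
(type-7) quartiles, whiskers at the furthest datum within 1.5·IQR of the
quartiles, outliers strictly beyond. The quartile convention is fixed and
documented because the whisker and outlier sets depend on it. Institutes
are ranked ascending by mean burden. The scanner comparison takes slides
digitised on exactly two scanners, forms per-slide differences B − A, and
reports their mean with a 95% Student-t interval
`mean ± t_{0.975, n-1} * sd / sqrt(n)`; a paired-differences t interval
was chosen over a regression band as the simplest interval consistent
with paired data (a bootstrap percentile interval would be the natural
alternative and is easy to add). Swapping scanners negates the estimate
and mirrors the interval. Temporal grouping partitions records by year,
month, ISO week, or day; unparseable dates are rejected with a log entry.

## Downstream masking

Masking is realised as scoring-exclusion (with optional white fill):
artifact pixels enter a boolean ignore mask and downstream scores are
computed on the retained pixels only. Exclusion, not inpainting, because
masking prevents misclassification in corrupted areas but cannot recover
the structures they hide. Detection filtering tests only each detection's
centre point against the mask, matching point-like cell detections.
Sensitivity and specificity are one-vs-rest per class
(`TP/(TP+FN)`, `TN/(TN+FP)`).

## Problem sizes

The desk-scale experiments used throughout tests and examples are: tissue
model — 110 training / 30 held-out patches of 64 px at MPP 10; artifact
model — 230 training / 30 validation / 40 held-out patches of 96 px at
MPP 1.0 (~300 artifact patches in total); end-to-end runs on 768-px
synthetic slides; the OOF-coverage check uses 100 ROIs of 512 px. These
sizes were chosen so the full suite trains and evaluates in a few minutes
on one CPU while every class is represented with thousands of pixels.

## Known limitations

* The simulator's artifact appearances are stylised; per-class accuracies
  measured on it do not transfer to real slides.
* The pixel-classification backend has a small receptive field; real
  folds or bubbles with subtle colour change but distinctive shape would
  require a deep encoder–decoder and real training data.
* No stain normalisation, colour-profile management, immunohistochemistry
  support, or slide-level pass/fail scoring.
* Overlapping-window probability blending is not implemented; stitching
  is last-written-wins (with the default stride there are no overlaps).
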