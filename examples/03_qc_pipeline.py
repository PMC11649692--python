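"""Run the full two-stage QC pipeline on a simulated slide.

Trains desk-scale tissue and artifact models, simulates a 768-px slide
with artifacts, runs tissue detection at MPP 10 (~1x) gating artifact
detection at MPP 1 (10x), and prints the per-slide QC summary: tissue
area and the percentage of tissue occupied by each artifact class.
Outputs (paletted mask PNG, GeoJSON polygons, JSON summary, overlay)
are written to ``example_output/``.
"""
import numpy as np
from PIL import Image

from wsiqc import ARTIFACT_SCHEME, TISSUE_SCHEME, pyramid_from_array
from wsiqc.pipeline import (
    export_outputs,
    make_overlay,
    run_artifact_module,
    run_tissue_module,
    slide_summary,
)
from wsiqc.segmentation import ModelConfig, build_model, train_model
from wsiqc.slide_model import Raster, read_region
from wsiqc.synthetic import compose_synthetic_slide, gen_dataset, gen_tissue_texture, random_slide_spec

# --- train desk-scale models -------------------------------------------------
rng = np.random.default_rng(0)
tissue_data = [
    gen_tissue_texture((64, 64), 10.0, float(tf), seed=s)
    for s, tf in enumerate(rng.uniform(0.3, 0.8, 120))
]
tissue_bundle = train_model(
    build_model(ModelConfig(scheme=TISSUE_SCHEME, mpp=10.0, patch_size=64, epochs=10, seed=0)),
    tissue_data[:110],
    tissue_data[110:],
)
artifact_data = gen_dataset(180, patch_size=96, mpp=1.0, seed=11)
artifact_bundle = train_model(
    build_model(ModelConfig(scheme=ARTIFACT_SCHEME, mpp=1.0, patch_size=96, epochs=15, seed=0)),
    artifact_data[:160],
    artifact_data[160:],
)

# --- simulate a slide and run QC ---------------------------------------------
spec = random_slide_spec(
    42, size=(768, 768), kinds=["fold", "pen_marking", "air_bubble_edge"], with_oof=True, tissue_frac=0.7
)
slide = compose_synthetic_slide(spec)
pyramid = pyramid_from_array(slide.image.pixels, mpp=1.0)

tissue_mask = run_tissue_module(pyramid, tissue_bundle)
artifact_mask = run_artifact_module(pyramid, tissue_mask, artifact_bundle, variant="10x")
summary = slide_summary(artifact_mask, "synthetic_slide_42", variant="10x")

print(f"tissue area: {summary.tissue_area_mm2:.3f} mm^2")
for name, pct in summary.class_pct.items():
    print(f"  {name:<20s} {pct:6.2f} % of tissue")
print(f"  {'artifact-free':<20s} {summary.artifact_free_pct:6.2f} % of tissue")
print(f"any artifact: {summary.any_artifact_pct:.2f} % of tissue")

paths = export_outputs(artifact_mask, summary, "example_output")
w, h = pyramid.dims_at(1.0)
base = read_region(pyramid, 1.0, (0, 0, w, h))
overlay = make_overlay(base, artifact_mask, alpha=0.45)
Image.fromarray(overlay.pixels).save("example_output/synthetic_slide_42_overlay.png")
print("wrote:", ", ".join(str(p) for p in paths.values()))
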