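"""Simulate an H&E-like slide with artifacts and inspect its ground truth.

Builds a 512-px synthetic slide containing a fold, a pen marking, an air
bubble and a synthetic out-of-focus region, then prints how much of the
slide each ground-truth class occupies. The percentages are exact pixel
counts from the generator's label mask — this is the ground truth the
segmentation models are trained and scored against.
"""
import numpy as np

from wsiqc import ARTIFACT_SCHEME
from wsiqc.synthetic import compose_synthetic_slide, random_slide_spec

spec = random_slide_spec(
    seed=42,
    size=(512, 512),
    kinds=["fold", "pen_marking", "air_bubble_edge"],
    with_oof=True,
    tissue_frac=0.7,
)
slide = compose_synthetic_slide(spec)

print(f"slide {spec.size[0]}x{spec.size[1]} px at MPP {spec.mpp}, seed {spec.seed}")
print(f"OOF blur kernel size drawn: {slide.meta['oof_kernel']}")
total = slide.gt.labels.size
for c, name in enumerate(ARTIFACT_SCHEME.names):
    pct = 100.0 * (slide.gt.labels == c).sum() / total
    if pct:
        print(f"  {name:<20s} {pct:6.2f} % of slide area")
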