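"""Shared fixtures: synthetic datasets and desk-scale trained models.

The two model fixtures are session-scoped because training, while only
seconds at this scale, is the most expensive step; every test that needs
a trained model shares the same seeded, reproducible bundles.
"""
from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from wsiqc.segmentation import ModelConfig, build_model, train_model
from wsiqc.slide_model import ARTIFACT_SCHEME, TISSUE_SCHEME
from wsiqc.synthetic import (
    compose_synthetic_slide,
    gen_dataset,
    gen_tissue_texture,
    random_slide_spec,
)

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


def toy_pairs(n=16, size=32, seed=0):
    """Colour-separable toy task: each class is a distinct flat colour."""
    from wsiqc.slide_model import LabelMask, Raster
    from wsiqc.synthetic import LabeledSlide

    colours = ARTIFACT_SCHEME.palette_array()
    rng = np.random.default_rng(seed)
    pairs = []
    for i in range(n):
        cls = int(rng.integers(0, 7)) if n < 7 else i % 7
        labels = np.full((size, size), cls, dtype=np.uint8)
        pairs.append(
            LabeledSlide(
                image=Raster(colours[labels], 1.0),
                gt=LabelMask(labels, 1.0, ARTIFACT_SCHEME),
            )
        )
    return pairs


def toy_config(**kw):
    defaults = dict(
        scheme=ARTIFACT_SCHEME,
        mpp=1.0,
        patch_size=32,
        epochs=5,
        seed=0,
        pixels_per_patch=400,
    )
    defaults.update(kw)
    return ModelConfig(**defaults)


@pytest.fixture(scope="session")
def toy_bundle():
    """Model trained to saturation on the flat-colour toy task."""
    pairs = toy_pairs(20)
    return train_model(build_model(toy_config()), pairs[:16], pairs[16:])


@pytest.fixture(scope="session")
def artifact_dataset():
    """~300 labelled 96-px patches at MPP 1.0 with balanced artifact classes."""
    data = gen_dataset(300, patch_size=96, mpp=1.0, seed=11)
    return {"train": data[:230], "val": data[230:260], "test": data[260:]}


@pytest.fixture(scope="session")
def tissue_dataset():
    """Artifact-free texture patches at MPP 10 for the tissue model."""
    rng = np.random.default_rng(0)
    fracs = rng.uniform(0.3, 0.8, 150)
    data = [
        gen_tissue_texture((64, 64), 10.0, float(tf), seed=s)
        for s, tf in enumerate(fracs)
    ]
    return {"train": data[:110], "val": data[110:120], "test": data[120:]}


@pytest.fixture(scope="session")
def tissue_bundle(tissue_dataset):
    cfg = ModelConfig(scheme=TISSUE_SCHEME, mpp=10.0, patch_size=64, epochs=12, seed=0)
    return train_model(build_model(cfg), tissue_dataset["train"], tissue_dataset["val"])


@pytest.fixture(scope="session")
def artifact_bundle(artifact_dataset):
    cfg = ModelConfig(scheme=ARTIFACT_SCHEME, mpp=1.0, patch_size=96, epochs=20, seed=0)
    return train_model(build_model(cfg), artifact_dataset["train"], artifact_dataset["val"])


@pytest.fixture(scope="session")
def labeled_slide():
    """One 768-px synthetic slide with folds, pen, bubbles and OOF."""
    spec = random_slide_spec(
        42,
        size=(768, 768),
        kinds=["fold", "pen_marking", "air_bubble_edge"],
        with_oof=True,
        tissue_frac=0.7,
    )
    return compose_synthetic_slide(spec)
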