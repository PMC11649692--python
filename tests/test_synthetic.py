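"""Synthetic slide generator: determinism, ground-truth contracts, OOF."""
import numpy as np
import pytest
from scipy import ndimage

from wsiqc.errors import DomainError, GenerationError, MappingError
from wsiqc.slide_model import ARTIFACT_SCHEME
from wsiqc.synthetic import (
    ArtifactSpec,
    DEFAULT_KERNEL_SIZES,
    OofSpec,
    PRECEDENCE,
    SlideSpec,
    compose_synthetic_slide,
    gen_dataset,
    gen_tissue_texture,
    inject_artifact,
    inject_oof,
    random_slide_spec,
    write_dataset,
)

TISSUE = ARTIFACT_SCHEME.index("tissue_no_artifact")
OOF = ARTIFACT_SCHEME.index("out_of_focus")
FOLD = ARTIFACT_SCHEME.index("fold")
PEN = ARTIFACT_SCHEME.index("pen_marking")


class TestTissueTexture:
    def test_deterministic(self):
        a = gen_tissue_texture((128, 128), 1.0, 0.6, seed=7)
        b = gen_tissue_texture((128, 128), 1.0, 0.6, seed=7)
        np.testing.assert_array_equal(a.image.pixels, b.image.pixels)
        np.testing.assert_array_equal(a.gt.labels, b.gt.labels)

    @pytest.mark.parametrize("frac", [0.3, 0.6, 0.8])
    def test_tissue_fraction_near_target(self, frac):
        ls = gen_tissue_texture((256, 256), 1.0, frac, seed=1)
        achieved = (ls.gt.labels == TISSUE).mean()
        assert achieved == pytest.approx(frac, abs=0.1)

    def test_background_is_near_white(self):
        ls = gen_tissue_texture((128, 128), 1.0, 0.5, seed=2)
        bg = ls.image.pixels[ls.gt.labels == 0]
        assert bg.min() >= 200
        assert bg.mean(axis=1).min() >= 220

    def test_invalid_fraction(self):
        with pytest.raises(DomainError):
            gen_tissue_texture((128, 128), 1.0, 1.2, seed=0)


class TestInjectArtifact:
    def test_fold_labels_band_only(self):
        base = gen_tissue_texture((128, 128), 1.0, 0.7, seed=3)
        out = inject_artifact(base, ArtifactSpec(kind="fold", seed=9))
        changed = out.gt.labels != base.gt.labels
        assert changed.any()
        assert (out.gt.labels[changed] == FOLD).all()

    def test_pigment_is_a_confounder(self):
        base = gen_tissue_texture((128, 128), 1.0, 0.7, seed=3)
        out = inject_artifact(base, ArtifactSpec(kind="pigment", seed=9))
        assert (out.image.pixels != base.image.pixels).any()
        np.testing.assert_array_equal(out.gt.labels, base.gt.labels)

    def test_unknown_kind_rejected(self):
        with pytest.raises(MappingError):
            ArtifactSpec(kind="scratch", seed=1)

    def test_overlap_precedence_order_independent(self):
        # identical geometry either way; the overlap must always be pen
        base = gen_tissue_texture((96, 96), 1.0, 0.8, seed=4)
        geo = {"p0": (10.0, 48.0), "p1": (86.0, 48.0), "width": 10.0}
        fold = ArtifactSpec(kind="fold", geometry=geo, seed=5)
        pen = ArtifactSpec(kind="pen_marking", geometry={**geo, "colour": (25.0, 25.0, 25.0)}, seed=6)
        a = inject_artifact(inject_artifact(base, fold), pen)
        b = inject_artifact(inject_artifact(base, pen), fold)
        np.testing.assert_array_equal(a.gt.labels, b.gt.labels)
        overlap = (a.gt.labels == PEN) | (a.gt.labels == FOLD)
        assert PRECEDENCE["pen_marking"] > PRECEDENCE["fold"]
        assert (a.gt.labels[overlap & (b.gt.labels == PEN)] == PEN).all()


class TestInjectOof:
    def test_minimum_fraction_reached(self):
        base = gen_tissue_texture((256, 256), 1.0, 0.65, seed=5)
        out = inject_oof(base, OofSpec(min_frac=0.30, seed=6))
        assert (out.gt.labels == OOF).mean() >= 0.30

    def test_identity_kernel_leaves_image_unchanged(self):
        base = gen_tissue_texture((128, 128), 1.0, 0.65, seed=5)
        out = inject_oof(base, OofSpec(kernel_sizes=(1,), seed=6))
        np.testing.assert_array_equal(out.image.pixels, base.image.pixels)

    def test_blur_reduces_local_variance(self):
        base = gen_tissue_texture((256, 256), 1.0, 0.7, seed=7)
        out = inject_oof(base, OofSpec(kernel_sizes=(9,), seed=8))
        region = out.gt.labels == OOF

        def local_var(img):
            g = img.mean(axis=2)
            m = ndimage.uniform_filter(g, 5)
            m2 = ndimage.uniform_filter(g * g, 5)
            return m2 - m * m

        v_before = local_var(base.image.pixels.astype(np.float64))
        v_after = local_var(out.image.pixels.astype(np.float64))
        inner = ndimage.binary_erosion(region, iterations=5)
        assert v_after[inner].mean() < v_before[inner].mean()

    def test_oof_only_overwrites_clean_tissue(self):
        spec = random_slide_spec(9, size=(192, 192), kinds=["fold", "pen_marking"], tissue_frac=0.7)
        before = compose_synthetic_slide(spec)
        after = inject_oof(before, OofSpec(seed=10))
        newly = (after.gt.labels == OOF) & (before.gt.labels != OOF)
        assert (before.gt.labels[newly] == TISSUE).all()

    def test_kernel_size_from_allowed_set(self):
        base = gen_tissue_texture((128, 128), 1.0, 0.65, seed=5)
        out = inject_oof(base, OofSpec(seed=11))
        assert out.meta["oof_kernel"] in DEFAULT_KERNEL_SIZES

    def test_unattainable_fraction_raises(self):
        base = gen_tissue_texture((128, 128), 1.0, 0.1, seed=5)
        with pytest.raises(GenerationError):
            inject_oof(base, OofSpec(min_frac=0.5, seed=6))

    def test_even_kernel_rejected(self):
        with pytest.raises(DomainError):
            OofSpec(kernel_sizes=(4,))


class TestCompose:
    def test_clean_slide_has_only_background_and_tissue(self):
        ls = compose_synthetic_slide(SlideSpec(size=(128, 128), seed=1))
        assert set(np.unique(ls.gt.labels)) <= {0, TISSUE}

    def test_all_kinds_present(self):
        spec = random_slide_spec(
            13,
            size=(256, 256),
            kinds=["fold", "dark_spot_foreign", "pen_marking", "air_bubble_edge", "pigment"],
            with_oof=True,
            tissue_frac=0.7,
        )
        ls = compose_synthetic_slide(spec)
        assert set(np.unique(ls.gt.labels)) == set(range(7))

    def test_deterministic(self):
        spec = random_slide_spec(21, size=(128, 128), kinds=["fold"], with_oof=True)
        a = compose_synthetic_slide(spec)
        b = compose_synthetic_slide(spec)
        np.testing.assert_array_equal(a.image.pixels, b.image.pixels)
        np.testing.assert_array_equal(a.gt.labels, b.gt.labels)

    def test_recompose_idempotent_in_gt(self):
        spec = random_slide_spec(22, size=(128, 128), kinds=["fold", "pen_marking"])
        a = compose_synthetic_slide(spec)
        b = compose_synthetic_slide(spec)
        np.testing.assert_array_equal(a.gt.labels, b.gt.labels)


class TestGenDataset:
    def test_exact_count_and_dims(self):
        data = gen_dataset(10, patch_size=96, seed=1)
        assert len(data) == 10
        assert all(p.image.pixels.shape == (96, 96, 3) for p in data)

    def test_deterministic(self):
        a = gen_dataset(6, patch_size=96, seed=2)
        b = gen_dataset(6, patch_size=96, seed=2)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.gt.labels, y.gt.labels)

    def test_balanced_covers_all_classes(self):
        data = gen_dataset(60, patch_size=96, seed=3, balanced=True)
        seen = set()
        per_class_patches = {c: 0 for c in range(7)}
        for p in data:
            present = set(np.unique(p.gt.labels))
            seen |= present
            for c in present:
                per_class_patches[c] += 1
        assert seen == set(range(7))
        for c in range(2, 7):
            assert per_class_patches[c] >= 0.05 * len(data)

    def test_invalid_n(self):
        with pytest.raises(DomainError):
            gen_dataset(0)


class TestDatasetWriter:
    def test_png_round_trip(self, tmp_path):
        from PIL import Image

        data = gen_dataset(3, patch_size=96, seed=4)
        manifest = write_dataset(data, tmp_path)
        assert manifest.exists()
        mask = np.asarray(Image.open(tmp_path / "patch_00000_mask.png"))
        np.testing.assert_array_equal(mask, data[0].gt.labels)
        img = np.asarray(Image.open(tmp_path / "patch_00000.png").convert("RGB"))
        np.testing.assert_array_equal(img, data[0].image.pixels)
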