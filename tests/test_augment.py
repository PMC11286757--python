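"""Augmentation transform semantics (index-mapping oracles, involution and
identity properties) and the class-balancing expansion."""

import numpy as np
import pytest

from wbcnet.augment import (AugmentationSpec, balance_augment, flip_horizontal,
                            random_contrast, rotate_image, zoom_image)
from wbcnet.data import LabeledImageSet

FLIP_ONLY = AugmentationSpec(flip_enabled=True, rotation_deg=0.0,
                             zoom_scale=1.0, contrast_range=(1.0, 1.0))


def _img(rng, h=12, w=12):
    return rng.random((h, w, 3)).astype(np.float32)


class TestFlip:
    def test_index_mapping_oracle(self):
        """2x3 image, entries 1..6 row-major: out[i,j] = in[i, W-1-j]."""
        img = np.arange(1, 7, dtype=np.float32).reshape(2, 3)[:, :, None]
        img = np.repeat(img, 3, axis=2)
        out = flip_horizontal(img)
        want = np.zeros_like(img)
        for i in range(2):
            for j in range(3):
                want[i, j] = img[i, 3 - 1 - j]
        np.testing.assert_array_equal(out, want)

    def test_involution(self, rng):
        img = _img(rng)
        np.testing.assert_array_equal(flip_horizontal(flip_horizontal(img)),
                                      img)

    def test_constant_image_unchanged(self):
        img = np.full((5, 5, 3), 0.3, dtype=np.float32)
        np.testing.assert_array_equal(flip_horizontal(img), img)


class TestRotate:
    def test_zero_angle_is_identity(self, rng):
        img = _img(rng)
        np.testing.assert_array_equal(rotate_image(img, 0.0), img)

    def test_constant_interior_preserved(self):
        img = np.full((31, 31, 3), 0.6, dtype=np.float32)
        out = rotate_image(img, 10.0)
        np.testing.assert_allclose(out[10:21, 10:21], 0.6, atol=1e-6)

    def test_peak_lands_at_analytic_coordinates(self):
        """A bright pixel at offset (r, 0) below center moves to
        (r cos(t), -r sin(t)) under a clockwise rotation."""
        s = 41
        c = (s - 1) // 2
        r = 12
        img = np.zeros((s, s, 3), dtype=np.float32)
        img[c + r, c] = 1.0
        out = rotate_image(img, 10.0)
        pr, pc = np.unravel_index(out[:, :, 0].argmax(), (s, s))
        t = np.deg2rad(10.0)
        want = (c + r * np.cos(t), c - r * np.sin(t))
        assert abs(pr - want[0]) <= 1.0
        assert abs(pc - want[1]) <= 1.0

    def test_origin_anchor_differs_from_center(self, rng):
        img = _img(rng, 16, 16)
        a = rotate_image(img, 10.0, anchor="center")
        b = rotate_image(img, 10.0, anchor="origin")
        assert not np.array_equal(a, b)


class TestZoom:
    def test_origin_anchor_index_oracle(self):
        """Scale-2 top-left zoom duplicates each source pixel into a 2x2
        block: out[m, n] = in[floor(m/2), floor(n/2)]."""
        src = np.array([[0.1, 0.2], [0.3, 0.4]], dtype=np.float32)
        img = np.repeat(src[:, :, None], 3, axis=2)
        big = np.zeros((4, 4, 3), dtype=np.float32)
        big[:2, :2] = img
        out = zoom_image(big, 2.0, anchor="origin")
        for m in range(4):
            for n in range(4):
                np.testing.assert_array_equal(out[m, n], big[m // 2, n // 2])

    def test_unit_scale_is_identity(self, rng):
        img = _img(rng)
        np.testing.assert_array_equal(zoom_image(img, 1.0), img)
        np.testing.assert_array_equal(zoom_image(img, 1.0, anchor="origin"),
                                      img)

    def test_constant_image_unchanged(self):
        img = np.full((8, 8, 3), 0.42, dtype=np.float32)
        for anchor in ("origin", "center"):
            out = zoom_image(img, 2.0, anchor=anchor)
            np.testing.assert_allclose(out, 0.42, atol=1e-6)

    def test_rejects_nonpositive_scale(self, rng):
        with pytest.raises(ValueError, match="scale"):
            zoom_image(_img(rng), 0.0)


class _FixedRng:
    def __init__(self, value):
        self.value = value

    def uniform(self, lo, hi):
        return self.value


class TestContrast:
    def test_unit_factor_is_identity(self, rng):
        img = _img(rng)
        spec = AugmentationSpec(contrast_range=(1.0, 1.0))
        out = random_contrast(img, spec, np.random.default_rng(0))
        np.testing.assert_allclose(out, img, atol=1e-7)

    def test_two_pixel_closed_form(self):
        """{0.4, 0.6} at factor 2 -> {0.3, 0.7}: mean kept, deviations doubled."""
        img = np.array([[[0.4] * 3, [0.6] * 3]], dtype=np.float32)
        spec = AugmentationSpec(contrast_range=(1.0, 2.0))
        out = random_contrast(img, spec, _FixedRng(2.0))
        np.testing.assert_allclose(out[0, 0], 0.3, atol=1e-6)
        np.testing.assert_allclose(out[0, 1], 0.7, atol=1e-6)

    def test_output_clipped_to_unit_range(self, rng):
        img = _img(rng)
        spec = AugmentationSpec(contrast_range=(1.0, 5.0))
        for _ in range(10):
            out = random_contrast(img, spec, rng)
            assert out.min() >= 0.0 and out.max() <= 1.0


def _toy_set(rng, sizes=(3, 8, 5, 6)):
    images, labels = [], []
    for k, n in enumerate(sizes):
        for _ in range(n):
            images.append(rng.random((8, 8, 3)).astype(np.float32))
            labels.append(k)
    return LabeledImageSet(np.stack(images), np.array(labels))


class TestBalanceAugment:
    def test_exact_target_counts_and_originals_kept(self, rng):
        data = _toy_set(rng)
        out = balance_augment(data, 10, AugmentationSpec(seed=0))
        assert all(c == 10 for c in out.class_counts().values())
        hashes = {im.tobytes() for im in out.images}
        for im in data.images:
            assert im.tobytes() in hashes
        assert (np.asarray(out.provenance) == "original").sum() == len(data)

    def test_deterministic_under_seed(self, rng):
        data = _toy_set(rng)
        a = balance_augment(data, 10, AugmentationSpec(seed=5))
        b = balance_augment(data, 10, AugmentationSpec(seed=5))
        assert a.images.tobytes() == b.images.tobytes()

    def test_flip_group_exhausted_before_duplicates(self, rng):
        """With flips only and 3 originals per class, the 6 achievable
        images per class appear with no duplicates."""
        data = _toy_set(rng, sizes=(3, 3, 3, 3))
        out = balance_augment(data, 6, FLIP_ONLY)
        assert len(out) == 24
        assert len({im.tobytes() for im in out.images}) == 24

    def test_target_below_class_count_raises(self, rng):
        data = _toy_set(rng)
        with pytest.raises(ValueError, match="never discarded"):
            balance_augment(data, 7, AugmentationSpec())

    def test_labels_and_range_preserved(self, rng):
        data = _toy_set(rng)
        out = balance_augment(data, 12, AugmentationSpec(seed=1))
        assert out.images.dtype == np.float32
        assert out.images.min() >= 0.0 and out.images.max() <= 1.0

    def test_mixed_split_rejected(self, rng):
        data = _toy_set(rng)
        data.split = np.array(["train"] * 11 + ["test"] * 11)
        with pytest.raises(ValueError, match="single"):
            balance_augment(data, 10, AugmentationSpec())


def test_spec_invariants_enforced():
    with pytest.raises(ValueError):
        AugmentationSpec(zoom_scale=-1.0)
    with pytest.raises(ValueError):
        AugmentationSpec(contrast_range=(0.0, 1.2))
    with pytest.raises(ValueError):
        AugmentationSpec(contrast_range=(0.5, 0.9))
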