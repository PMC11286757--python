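"""Dataset loading, resizing and stratified splitting."""

import numpy as np
import pytest
from scipy.ndimage import map_coordinates

import imageio.v3 as iio

from wbcnet.data import (LabeledImageSet, load_image_dataset, resize_bilinear,
                         split_train_test)

CLASSES = ("eosinophil", "lymphocyte", "monocyte", "neutrophil")


def _write_tree(root, rng, per_class=5, size=(32, 32)):
    for cname in CLASSES:
        d = root / cname
        d.mkdir(parents=True)
        for i in range(per_class):
            arr = (rng.random((*size, 3)) * 255).astype(np.uint8)
            iio.imwrite(d / f"{cname}_{i}.png", arr)


class TestLoad:
    def test_counts_and_labels(self, tmp_path, rng):
        _write_tree(tmp_path, rng)
        ds = load_image_dataset(tmp_path, target_size=24)
        assert len(ds) == 20
        assert ds.class_counts() == {c: 5 for c in CLASSES}
        assert ds.images.shape == (20, 24, 24, 3)
        assert 0.0 <= ds.images.min() and ds.images.max() <= 1.0

    def test_grayscale_replicated_to_three_channels(self, tmp_path, rng):
        _write_tree(tmp_path, rng, per_class=1)
        gray = (rng.random((20, 20)) * 255).astype(np.uint8)
        iio.imwrite(tmp_path / CLASSES[0] / "gray.png", gray)
        ds = load_image_dataset(tmp_path, target_size=24)
        assert ds.images.shape[1:] == (24, 24, 3)
        assert len(ds) == 5

    def test_undecodable_file_skipped_with_warning(self, tmp_path, rng, caplog):
        _write_tree(tmp_path, rng, per_class=2)
        (tmp_path / CLASSES[0] / "broken.png").write_bytes(b"not a png")
        with caplog.at_level("WARNING"):
            ds = load_image_dataset(tmp_path, target_size=16)
        assert len(ds) == 8
        assert any("undecodable" in r.message for r in caplog.records)

    def test_empty_class_raises(self, tmp_path, rng):
        _write_tree(tmp_path, rng, per_class=2)
        (tmp_path / "basophil").mkdir()
        with pytest.raises(ValueError, match="basophil"):
            load_image_dataset(tmp_path, target_size=16)

    def test_directory_roundtrip(self, tmp_path, rng):
        imgs = rng.random((8, 16, 16, 3)).astype(np.float32)
        labels = np.tile(np.arange(4), 2)
        ds = LabeledImageSet(imgs, labels)
        ds.to_directory(tmp_path / "tree")
        back = load_image_dataset(tmp_path / "tree", target_size=16)
        assert back.class_counts() == ds.class_counts()
        # 8-bit quantisation on write is the only loss
        np.testing.assert_allclose(np.sort(back.images.ravel()),
                                   np.sort(ds.images.ravel()), atol=1 / 255)


class TestResize:
    def test_against_map_coordinates_oracle(self, rng):
        """Non-square 100x50 source to 36x36 vs an independent resampler
        evaluated at the same half-pixel sample points."""
        img = rng.random((100, 50, 3)).astype(np.float32)
        out = resize_bilinear(img, 36, 36)
        assert out.shape == (36, 36, 3)
        ry = np.clip((np.arange(36) + 0.5) * 100 / 36 - 0.5, 0, 99)
        rx = np.clip((np.arange(36) + 0.5) * 50 / 36 - 0.5, 0, 49)
        yy, xx = np.meshgrid(ry, rx, indexing="ij")
        for c in range(3):
            want = map_coordinates(img[:, :, c].astype(np.float64),
                                   [yy, xx], order=1, mode="nearest")
            np.testing.assert_allclose(out[:, :, c], want, atol=1e-5)

    def test_identity_when_size_matches(self, rng):
        img = rng.random((10, 10, 3)).astype(np.float32)
        np.testing.assert_array_equal(resize_bilinear(img, 10, 10), img)


class TestSplit:
    @pytest.mark.parametrize("n_per_class", [5, 10, 33, 100])
    def test_stratified_proportions(self, rng, n_per_class):
        imgs = rng.random((4 * n_per_class, 4, 4, 3)).astype(np.float32)
        labels = np.repeat(np.arange(4), n_per_class)
        ds = split_train_test(LabeledImageSet(imgs, labels), 0.8, seed=3)
        for k in range(4):
            tags = ds.split[ds.labels == k]
            assert (tags == "train").sum() == int(round(0.8 * n_per_class))
            assert (tags == "test").sum() == n_per_class - int(round(0.8 * n_per_class))

    def test_partition_property(self, rng):
        imgs = rng.random((40, 4, 4, 3)).astype(np.float32)
        labels = np.tile(np.arange(4), 10)
        ds = split_train_test(LabeledImageSet(imgs, labels), 0.8, seed=0)
        tr = ds.subset("train")
        te = ds.subset("test")
        assert len(tr) + len(te) == len(ds)
        tr_bytes = {im.tobytes() for im in tr.images}
        te_bytes = {im.tobytes() for im in te.images}
        assert not tr_bytes & te_bytes

    def test_deterministic_and_seed_sensitive(self, rng):
        imgs = rng.random((80, 4, 4, 3)).astype(np.float32)
        labels = np.tile(np.arange(4), 20)
        ds = LabeledImageSet(imgs, labels)
        a = split_train_test(ds, seed=1).split
        b = split_train_test(ds, seed=1).split
        c = split_train_test(ds, seed=2).split
        assert (a == b).all()
        assert not (a == c).all()
        # same per-class counts under any seed
        for k in range(4):
            assert (c[labels == k] == "train").sum() == \
                (a[labels == k] == "train").sum()

    def test_singleton_class_rejected(self, rng):
        imgs = rng.random((7, 4, 4, 3)).astype(np.float32)
        labels = np.array([0, 0, 1, 1, 2, 2, 3])
        with pytest.raises(ValueError, match="at least 2"):
            split_train_test(LabeledImageSet(imgs, labels))

    def test_val_carveout(self, rng):
        imgs = rng.random((80, 4, 4, 3)).astype(np.float32)
        labels = np.tile(np.arange(4), 20)
        ds = split_train_test(LabeledImageSet(imgs, labels), 0.8,
                              val_frac=0.1, seed=0)
        counts = {t: (ds.split == t).sum() for t in ("train", "val", "test")}
        assert counts["val"] == 8 and counts["test"] == 16
        assert sum(counts.values()) == 80


def test_label_validation():
    with pytest.raises(ValueError, match="class set"):
        LabeledImageSet(np.zeros((1, 4, 4, 3), np.float32), np.array([9]))
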