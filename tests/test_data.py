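"""Synthetic vein generator, ROI preprocessing, and dataset splits."""

import numpy as np
import pytest

from veinid.data import (RoiImage, SplitSpec, SyntheticVeinConfig,
                         generate_synthetic_dataset, labels_of, load_dataset,
                         preprocess_roi, save_dataset, split_dataset)


class TestGenerator:
    def test_counts_and_label_coverage(self):
        cfg = SyntheticVeinConfig(n_identities=10, images_per_identity=12,
                                  roi_size=(40, 120), seed=0)
        images = generate_synthetic_dataset(cfg)
        assert len(images) == 120
        labels = labels_of(images)
        values, counts = np.unique(labels, return_counts=True)
        assert list(values) == list(range(10))
        assert all(c == 12 for c in counts)

    def test_same_seed_is_bit_identical(self):
        cfg = SyntheticVeinConfig(n_identities=3, images_per_identity=4,
                                  roi_size=(40, 120), seed=5)
        a = generate_synthetic_dataset(cfg)
        b = generate_synthetic_dataset(cfg)
        for ia, ib in zip(a, b):
            assert np.array_equal(ia.pixels, ib.pixels)
            assert ia.identity_label == ib.identity_label

    def test_within_identity_more_similar_than_between(self):
        """Identity separability: mean within-class image correlation
        exceeds mean between-class correlation."""
        cfg = SyntheticVeinConfig(n_identities=20, images_per_identity=4,
                                  roi_size=(40, 120), seed=3)
        images = generate_synthetic_dataset(cfg)
        flat = np.stack([im.pixels.ravel() for im in images])
        flat = flat - flat.mean(axis=1, keepdims=True)
        flat /= np.linalg.norm(flat, axis=1, keepdims=True)
        corr = flat @ flat.T
        labels = labels_of(images)
        same = labels[:, None] == labels[None, :]
        off_diag = ~np.eye(len(images), dtype=bool)
        within = corr[same & off_diag].mean()
        between = corr[~same].mean()
        assert within > between

    def test_nearest_mean_classifier_beats_chance(self):
        cfg = SyntheticVeinConfig(n_identities=10, images_per_identity=6,
                                  roi_size=(40, 120), seed=11)
        images = generate_synthetic_dataset(cfg)
        tr, va, te = split_dataset(images, SplitSpec(ratios=(4, 1, 1), seed=0))
        labels_tr = labels_of(tr)
        means = np.stack([
            np.mean([im.pixels.ravel() for im in tr
                     if im.identity_label == c], axis=0)
            for c in range(10)])
        correct = sum(
            int(np.argmin(np.linalg.norm(means - im.pixels.ravel(), axis=1))
                == im.identity_label)
            for im in te)
        assert correct / len(te) > 0.3  # chance level is 0.1

    def test_degenerate_roi_rejected(self):
        with pytest.raises(ValueError):
            SyntheticVeinConfig(roi_size=(4, 300))

    def test_sessions_must_divide_images(self):
        with pytest.raises(ValueError):
            SyntheticVeinConfig(images_per_identity=7, n_sessions=2)


class TestPreprocessRoi:
    def test_fvusm_like_roi_is_centered_and_resized(self):
        pixels = np.ones((100, 300), dtype=np.float32) * 0.5
        out = preprocess_roi(RoiImage(pixels, 0, 0), target=112)
        assert out.shape == (1, 3, 112, 112)
        assert out.min() >= 0.0 and out.max() <= 1.0
        # content occupies the middle third of rows after square padding
        assert np.allclose(out[0, 0, 0, :], 0.0)    # top padding
        assert np.allclose(out[0, 0, -1, :], 0.0)   # bottom padding
        assert out[0, 0, 56, :].min() > 0.4         # center row has content
        # all three channels identical
        assert np.array_equal(out[0, 0], out[0, 1])
        assert np.array_equal(out[0, 0], out[0, 2])

    def test_square_input_padding_is_noop(self, rng):
        pixels = rng.random((64, 64)).astype(np.float32)
        out = preprocess_roi(pixels, target=64)
        assert np.abs(out[0, 0] - pixels).max() < 1e-6

    def test_all_zero_input_stays_zero(self):
        out = preprocess_roi(np.zeros((50, 150), dtype=np.float32))
        assert np.all(out == 0.0)

    def test_invalid_input_rejected(self):
        with pytest.raises(ValueError):
            preprocess_roi(np.zeros((0, 10)))


class TestSplitDataset:
    def test_fvusm_protocol_8_2_2(self, tiny_dataset):
        cfg = SyntheticVeinConfig(n_identities=4, images_per_identity=12,
                                  roi_size=(40, 120), seed=2)
        images = generate_synthetic_dataset(cfg)
        tr, va, te = split_dataset(images, SplitSpec(ratios=(4, 1, 1), seed=0))
        assert (len(tr), len(va), len(te)) == (32, 8, 8)
        for split, n in ((tr, 8), (va, 2), (te, 2)):
            counts = np.bincount(labels_of(split), minlength=4)
            assert all(c == n for c in counts)

    def test_plusvein_protocol_3_1_1_on_five_images(self):
        images = [RoiImage(np.full((10, 12), 0.5), c, 0)
                  for c in range(3) for _ in range(5)]
        tr, va, te = split_dataset(images, SplitSpec(ratios=(3, 1, 1), seed=1))
        assert (len(tr), len(va), len(te)) == (9, 3, 3)

    def test_splits_partition_the_input(self, tiny_dataset):
        tr, va, te = split_dataset(tiny_dataset,
                                   SplitSpec(ratios=(4, 1, 1), seed=9))
        assert len(tr) + len(va) + len(te) == len(tiny_dataset)
        seen = {id(im) for im in tr} | {id(im) for im in va} \
            | {id(im) for im in te}
        assert seen == {id(im) for im in tiny_dataset}

    def test_too_few_images_names_the_class(self):
        images = [RoiImage(np.full((10, 10), 0.5), 7, 0) for _ in range(3)]
        with pytest.raises(ValueError, match="class 7"):
            split_dataset(images, SplitSpec(ratios=(4, 1, 1), seed=0))

    def test_split_is_seed_deterministic(self, tiny_dataset):
        a = split_dataset(tiny_dataset, SplitSpec(seed=4))
        b = split_dataset(tiny_dataset, SplitSpec(seed=4))
        for sa, sb in zip(a, b):
            assert [id(x) for x in sa] == [id(x) for x in sb]


class TestDiskRoundTrip:
    def test_png_layout_and_manifest_roundtrip(self, tmp_path):
        cfg = SyntheticVeinConfig(n_identities=2, images_per_identity=4,
                                  roi_size=(32, 96), seed=13)
        images = generate_synthetic_dataset(cfg)
        save_dataset(images, tmp_path)
        assert (tmp_path / "identity_0000" / "session_0" / "img_000.png").exists()
        loaded = load_dataset(tmp_path)
        assert len(loaded) == len(images)
        for a, b in zip(images, loaded):
            assert a.identity_label == b.identity_label
            assert a.session_tag == b.session_tag
            # 8-bit quantization on disk
            assert np.abs(a.pixels - b.pixels).max() <= 0.5 / 255 + 1e-6
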