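"""Preprocessing: normalisation, labels, resizing, patch grids,
augmentation and the stratified split."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import segresdeit as sd
from segresdeit.data_pipeline import ImageMaskPair, SplitSpec


class TestNormalize:
    def test_minmax_endpoints(self):
        img = np.array([[[0], [128], [255]]], dtype=np.uint8)  # one channel
        out = sd.normalize_image(img)
        assert np.allclose(out.ravel(), [0.0, 128 / 255, 1.0])

    def test_constant_channel_maps_to_zeros(self):
        img = np.zeros((4, 4, 3), dtype=np.uint8)
        assert not sd.normalize_image(img).any()

    def test_random_image_hits_exact_extrema_per_channel(self, rng):
        img = rng.integers(0, 256, size=(16, 16, 3))
        out = sd.normalize_image(img)
        assert np.allclose(out.min(axis=(0, 1)), 0.0)
        assert np.allclose(out.max(axis=(0, 1)), 1.0)

    def test_idempotent(self, rng):
        img = rng.integers(0, 256, size=(8, 8, 3))
        once = sd.normalize_image(img)
        assert np.allclose(sd.normalize_image(once), once)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            sd.normalize_image(np.zeros((0, 4, 3)))


class TestDeriveLabel:
    def test_all_zero_is_negative(self):
        assert sd.derive_label(np.zeros((4, 4), dtype=np.uint8)) == 0

    def test_single_pixel_is_positive(self):
        m = np.zeros((4, 4), dtype=np.uint8)
        m[2, 1] = 1
        assert sd.derive_label(m) == 1

    def test_all_ones_is_positive(self):
        assert sd.derive_label(np.ones((3, 3), dtype=np.uint8)) == 1

    def test_non_binary_rejected(self):
        with pytest.raises(ValueError, match="binary|0 and 1"):
            sd.derive_label(np.array([[0, 2]]))


class TestResize:
    def _pair(self, h, w, rng):
        mask = (rng.random((h, w)) < 0.2).astype(np.uint8)
        img = rng.random((h, w, 3))
        return ImageMaskPair(img, mask, sd.derive_label(mask), "s")

    def test_downscale_to_study_size(self, rng):
        pair = self._pair(512, 512, rng)
        out = sd.resize_pair(pair, (256, 256))
        assert out.image.shape == (256, 256, 3) and out.mask.shape == (256, 256)
        out.validate()

    def test_identity_resize_bitwise_equal(self, rng):
        pair = self._pair(32, 32, rng)
        out = sd.resize_pair(pair, (32, 32))
        assert np.array_equal(out.image, pair.image)
        assert np.array_equal(out.mask, pair.mask)

    def test_checkerboard_mask_upscale_stays_binary(self):
        mask = np.indices((8, 8)).sum(axis=0) % 2
        pair = ImageMaskPair(np.random.rand(8, 8, 3), mask.astype(np.uint8), 1, "s")
        out = sd.resize_pair(pair, (16, 16))
        assert set(np.unique(out.mask)) <= {0, 1}

    def test_label_rederived_when_lesion_vanishes(self):
        mask = np.zeros((64, 64), dtype=np.uint8)
        mask[0, 0] = 1  # 1-pixel lesion can vanish under nearest-neighbour
        pair = ImageMaskPair(np.zeros((64, 64, 3)), mask, 1, "s")
        out = sd.resize_pair(pair, (4, 4))
        assert out.label == sd.derive_label(out.mask)


class TestPatchGrid:
    def test_single_patch(self):
        grid = sd.build_patch_grid((256, 256), 256, 256)
        assert grid.origins == [(0, 0)]

    def test_three_by_three_grid(self):
        grid = sd.build_patch_grid((256, 256), 128, 64)
        assert len(grid.origins) == 9
        rows = sorted({r for r, _ in grid.origins})
        assert rows == [0, 64, 128]

    def test_margin_clamping_and_full_coverage(self):
        grid = sd.build_patch_grid((250, 250), 128, 64)
        assert max(r for r, _ in grid.origins) == 122
        covered = np.zeros((250, 250), dtype=bool)
        for r, c in grid.origins:
            covered[r:r + 128, c:c + 128] = True
        assert covered.all()

    def test_oversized_patch_rejected(self):
        with pytest.raises(ValueError):
            sd.build_patch_grid((100, 100), 128, 64)

    @settings(max_examples=30, deadline=None)
    @given(
        h=st.integers(8, 60), w=st.integers(8, 60),
        patch=st.integers(2, 8), stride=st.integers(1, 8),
    )
    def test_every_pixel_covered(self, h, w, patch, stride):
        if patch > min(h, w) or stride > patch:
            return
        grid = sd.build_patch_grid((h, w), patch, stride)
        covered = np.zeros((h, w), dtype=bool)
        for r, c in grid.origins:
            assert r + patch <= h and c + patch <= w
            covered[r:r + patch, c:c + patch] = True
        assert covered.all()

    def test_extract_patches_rederives_labels(self, rng):
        mask = np.zeros((16, 16), dtype=np.uint8)
        mask[0, 0] = 1
        pair = ImageMaskPair(rng.random((16, 16, 3)), mask, 1, "s")
        patches = sd.extract_patches(pair, sd.build_patch_grid((16, 16), 8, 8))
        labels = [p.label for p in patches]
        assert labels == [1, 0, 0, 0]


class TestAugment:
    def _pair(self, rng, h=16, w=16):
        mask = np.zeros((h, w), dtype=np.uint8)
        mask[3:6, 4:8] = 1
        return ImageMaskPair(rng.random((h, w, 3)), mask, 1, "s")

    def test_identity_parameters_are_identity(self, rng):
        pair = self._pair(rng)
        # find a seed with neither flip drawn
        for seed in range(50):
            r = np.random.default_rng(seed)
            if r.random() >= 0.5 and r.random() >= 0.5:
                break
        out = sd.augment_pair(pair, seed, max_rotation_deg=0.0,
                              zoom_range=(1.0, 1.0), brightness_range=(1.0, 1.0))
        assert np.allclose(out.image, pair.image)
        assert np.array_equal(out.mask, pair.mask)

    def test_horizontal_flip_geometry(self):
        mask = np.zeros((8, 8), dtype=np.uint8)
        mask[2, 1] = 1
        pair = ImageMaskPair(np.zeros((8, 8, 3)), mask, 1, "s")
        for seed in range(100):
            r = np.random.default_rng(seed)
            if r.random() < 0.5 and r.random() >= 0.5:  # flip_h only
                break
        out = sd.augment_pair(pair, seed, max_rotation_deg=0.0,
                              zoom_range=(1.0, 1.0), brightness_range=(1.0, 1.0))
        assert out.mask[2, 8 - 1 - 1] == 1 and out.mask.sum() == 1

    def test_same_seed_reproducible(self, rng):
        pair = self._pair(rng)
        a = sd.augment_pair(pair, 123)
        b = sd.augment_pair(pair, 123)
        assert np.array_equal(a.image, b.image) and np.array_equal(a.mask, b.mask)

    def test_output_ranges_over_many_seeds(self, rng):
        pair = self._pair(rng, 24, 24)
        for seed in range(100):
            out = sd.augment_pair(pair, seed)
            assert out.image.min() >= 0.0 and out.image.max() <= 1.0
            assert set(np.unique(out.mask)) <= {0, 1}
            assert out.label == sd.derive_label(out.mask)

    def test_flips_preserve_label(self, rng):
        pair = self._pair(rng)
        for seed in range(30):
            out = sd.augment_pair(pair, seed, max_rotation_deg=0.0,
                                  zoom_range=(1.0, 1.0))
            assert out.label == pair.label


class TestStratifiedSplit:
    def test_study_sizes(self):
        labels = np.array([1] * 1500 + [0] * 727)
        tr, va = sd.stratified_split(labels, SplitSpec(train_fraction=0.8, seed=0))
        assert len(tr) == 1782 and len(va) == 445

    def test_single_class(self):
        tr, va = sd.stratified_split([1] * 10, SplitSpec(train_fraction=0.8, seed=1))
        assert len(tr) == 8 and len(va) == 2

    def test_per_class_fractions(self):
        labels = np.array([1] * 30 + [0] * 70)
        tr, va = sd.stratified_split(labels, SplitSpec(train_fraction=0.8, seed=2))
        assert (labels[tr] == 1).sum() == 24
        assert (labels[va] == 1).sum() == 6

    def test_disjoint_and_exhaustive(self, rng):
        labels = (rng.random(57) < 0.3).astype(int)
        tr, va = sd.stratified_split(labels, SplitSpec(train_fraction=0.8, seed=3))
        assert set(tr).isdisjoint(va)
        assert sorted(np.concatenate([tr, va])) == list(range(57))

    def test_reproducible_under_seed(self):
        labels = [0, 1] * 20
        a = sd.stratified_split(labels, SplitSpec(seed=7))
        b = sd.stratified_split(labels, SplitSpec(seed=7))
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_tiny_class_goes_to_train_with_warning(self):
        labels = [0] * 10 + [1]
        with pytest.warns(UserWarning, match="fewer than 2"):
            tr, va = sd.stratified_split(labels, SplitSpec(train_fraction=0.8, seed=0))
        assert 10 in tr

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            sd.stratified_split([], SplitSpec())
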