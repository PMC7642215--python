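"""Foreground extraction and patch tiling against independent oracles."""

import numpy as np
import pytest

from staincycle import (SlideImage, build_bags, extract_large_patches,
                        otsu_foreground, stitch_patches, tile_small_patches)
from staincycle.config import NORMAL_LABEL, TUMOR_LABEL
from staincycle.preprocess import to_grayscale
from staincycle.synthetic_slides import HE, GroundTruth


def _otsu_oracle(gray_u8):
    """Exhaustive 256-way search maximizing between-class variance."""
    hist = np.bincount(gray_u8.ravel(), minlength=256).astype(float)
    total = hist.sum()
    best_var, best_t = -1.0, 0
    levels = np.arange(256)
    for t in range(255):
        w0 = hist[:t + 1].sum()
        w1 = total - w0
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (hist[:t + 1] * levels[:t + 1]).sum() / w0
        mu1 = (hist[t + 1:] * levels[t + 1:]).sum() / w1
        var = w0 * w1 * (mu0 - mu1) ** 2
        if var > best_var:
            best_var, best_t = var, t
    return best_t, best_var


def _between_class_variance(gray_u8, t):
    return _otsu_oracle_at(gray_u8, t)


def _otsu_oracle_at(gray_u8, t):
    hist = np.bincount(gray_u8.ravel(), minlength=256).astype(float)
    total = hist.sum()
    levels = np.arange(256)
    w0 = hist[:t + 1].sum()
    w1 = total - w0
    if w0 == 0 or w1 == 0:
        return 0.0
    mu0 = (hist[:t + 1] * levels[:t + 1]).sum() / w0
    mu1 = (hist[t + 1:] * levels[t + 1:]).sum() / w1
    return w0 * w1 * (mu0 - mu1) ** 2


def _gray_image(gray2d):
    return SlideImage(pixels=np.repeat(gray2d[..., None], 3, axis=2).astype(np.uint8),
                      domain=HE)


class TestOtsu:
    def test_two_valued_image_split(self):
        gray = np.full((40, 40), 200, dtype=np.uint8)
        gray[:, :20] = 50
        img = _gray_image(gray)
        fg = otsu_foreground(img)
        t_oracle, var_oracle = _otsu_oracle(gray)
        assert _otsu_oracle_at(gray, int(fg.threshold_used)) == pytest.approx(var_oracle)
        assert np.array_equal(fg.mask.astype(bool), gray == 50)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_threshold_maximizes_between_class_variance(self, seed):
        """The chosen threshold attains the exhaustive-search maximum."""
        rng = np.random.default_rng(seed)
        gray = np.clip(np.concatenate([
            rng.normal(80, 20, size=500), rng.normal(190, 15, size=500)
        ]), 0, 255).astype(np.uint8).reshape(25, 40)
        fg = otsu_foreground(_gray_image(gray))
        _, var_oracle = _otsu_oracle(gray)
        assert _otsu_oracle_at(gray, int(fg.threshold_used)) == pytest.approx(
            var_oracle, rel=1e-12)

    def test_constant_image_all_background(self, caplog):
        img = _gray_image(np.full((32, 32), 255, dtype=np.uint8))
        with caplog.at_level("WARNING", logger="staincycle"):
            fg = otsu_foreground(img)
        assert fg.mask.sum() == 0

    def test_synthetic_slide_mask_covers_ground_truth(self, std_pair):
        he, ki, gt = std_pair
        for img in (he, ki):
            fg = otsu_foreground(img)
            coverage = fg.mask[gt.foreground_mask.astype(bool)].mean()
            assert coverage >= 0.99


class TestLargePatches:
    def _img(self, size, value=100):
        return _gray_image(np.full((size, size), value, dtype=np.uint8))

    def test_grid_origins(self):
        img = self._img(4480)
        fg_mask = np.ones((4480, 4480), dtype=np.uint8)
        from staincycle import ForegroundMask
        fg = ForegroundMask(mask=fg_mask, threshold_used=128)
        origins = extract_large_patches(img, fg, large_size=2240, min_fg_fraction=0.05)
        assert origins == [(0, 0), (0, 2240), (2240, 0), (2240, 2240)]

    def test_border_remainder_dropped(self):
        from staincycle import ForegroundMask
        img = self._img(4500)
        fg = ForegroundMask(mask=np.ones((4500, 4500), dtype=np.uint8),
                            threshold_used=128)
        origins = extract_large_patches(img, fg, large_size=2240)
        assert len(origins) == 4

    def test_all_background_yields_none(self):
        from staincycle import ForegroundMask
        img = self._img(256, value=250)
        fg = ForegroundMask(mask=np.zeros((256, 256), dtype=np.uint8),
                            threshold_used=128)
        assert extract_large_patches(img, fg, large_size=128) == []

    def test_image_smaller_than_patch(self):
        from staincycle import ForegroundMask
        img = self._img(100)
        fg = ForegroundMask(mask=np.ones((100, 100), dtype=np.uint8),
                            threshold_used=128)
        assert extract_large_patches(img, fg, large_size=128) == []


class TestSmallPatches:
    def test_full_scale_grid_is_100(self):
        region = np.zeros((2240, 2240, 3), dtype=np.uint8)
        patches = tile_small_patches(region, 224)
        assert len(patches) == 100

    def test_identity_tiling(self, rng):
        region = rng.integers(0, 256, size=(224, 224, 3), dtype=np.uint8)
        patches = tile_small_patches(region, 224)
        assert len(patches) == 1
        assert np.array_equal(patches[0].pixels, region)

    def test_border_rule(self, rng):
        region = rng.integers(0, 256, size=(300, 300, 3), dtype=np.uint8)
        patches = tile_small_patches(region, 224)
        assert len(patches) == 1 and patches[0].origin == (0, 0)

    def test_too_small_region(self):
        assert tile_small_patches(np.zeros((100, 100, 3), dtype=np.uint8), 224) == []

    def test_stitch_reassembles_bit_exactly(self, rng):
        region = rng.integers(0, 256, size=(96, 96, 3), dtype=np.uint8)
        patches = tile_small_patches(region, 32)
        assert len(patches) == 9
        assert np.array_equal(stitch_patches(patches, (96, 96)), region)


class TestBuildBags:
    def _slide(self, size=64):
        # half tissue-dark, half background-bright so Otsu keeps the patch
        pixels = np.full((size, size, 3), 100, dtype=np.uint8)
        pixels[size // 2:] = 250
        return SlideImage(pixels=pixels, domain=HE, slide_id="t")

    def _gt(self, size, centers, labels):
        return GroundTruth(cell_centers=centers, cell_labels=labels,
                           cell_positive=[False] * len(centers),
                           tumor_mask=np.zeros((size, size), dtype=np.uint8),
                           foreground_mask=np.ones((size, size), dtype=np.uint8))

    def test_one_tumor_cell_makes_tumor_bag(self):
        gt = self._gt(64, [(5, 5)] + [(i, 40) for i in range(10, 60, 5)],
                      [TUMOR_LABEL] + [NORMAL_LABEL] * 10)
        bags = build_bags(self._slide(), gt, large_size=64, small_size=32)
        assert len(bags) == 1 and bags[0].weak_label == TUMOR_LABEL

    def test_only_normal_cells_make_normal_bag(self):
        gt = self._gt(64, [(5, 5), (40, 40)], [NORMAL_LABEL, NORMAL_LABEL])
        bags = build_bags(self._slide(), gt, large_size=64, small_size=32)
        assert bags[0].weak_label == NORMAL_LABEL

    def test_no_tumor_region_means_all_normal(self):
        from staincycle import SyntheticSlideSpec, render_slide_pair
        spec = SyntheticSlideSpec(width=160, height=160, n_cells=30,
                                  tumor_region_fraction=0.0, seed=5)
        he, ki, gt = render_slide_pair(spec)
        bags = build_bags(he, gt, large_size=160, small_size=32)
        assert bags and all(b.weak_label == NORMAL_LABEL for b in bags)

    def test_missing_label_raises_with_origin(self):
        with pytest.raises(KeyError, match=r"\(0, 0\)"):
            build_bags(self._slide(), {}, large_size=64, small_size=32)

    def test_patch_count_conservation(self, std_pair):
        """Each retained bag carries the full small-patch grid."""
        he, ki, gt = std_pair
        bags = build_bags(he, gt, large_size=128, small_size=32)
        grid = (128 // 32) ** 2
        assert bags
        assert sum(len(b.instances) for b in bags) == grid * len(bags)
        for b in bags:
            for p in b.instances:
                assert p.pixels.shape == (32, 32, 3)
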