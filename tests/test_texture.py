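"""Texture panel: multi-Otsu, SFTA masks, fractal dimension, Gabor bank."""

import itertools

import numpy as np
import pytest
from skimage.filters import threshold_multiotsu

from stromatex import texture as tx
from stromatex.stains import density_to_gray, od_to_density, rgb_to_od
from stromatex.texture import (
    DegenerateImageError,
    GaborConfig,
    SftaConfig,
    box_counting_dimension,
    build_sfta_masks,
    channel_features,
    gabor_features,
    mask_border,
    multi_otsu_thresholds,
    sfta_features,
    tile_features,
)


def intraclass_variance(img: np.ndarray, thresholds) -> float:
    """Oracle objective: total within-class sum of squares of the
    partition t_{i-1} < g <= t_i."""
    v = img.ravel().astype(float)
    edges = [-np.inf, *thresholds, np.inf]
    total = 0.0
    for a, b in zip(edges[:-1], edges[1:]):
        sel = v[(v > a) & (v <= b)]
        if sel.size:
            total += float(((sel - sel.mean()) ** 2).sum())
    return total


def brute_force_box_count(border: np.ndarray, size: int) -> int:
    """Naive box counter: loop over the grid, test each box."""
    h, w = border.shape
    n = 0
    for i in range(0, h, size):
        for j in range(0, w, size):
            if border[i : i + size, j : j + size].any():
                n += 1
    return n


def brute_force_dimension(mask: np.ndarray) -> float:
    border = mask_border(mask)
    sizes = [2 ** k for k in range(1, 8) if 2 ** k <= min(border.shape) // 2]
    counts = [brute_force_box_count(border, s) for s in sizes]
    return float(np.polyfit(np.log(1.0 / np.array(sizes)), np.log(counts), 1)[0])


class TestMultiOtsu:
    def test_bimodal_single_threshold(self):
        img = np.concatenate([np.zeros(50), np.full(50, 255)]).reshape(10, 10).astype(np.uint8)
        (t,) = multi_otsu_thresholds(img, 1)
        assert 0 <= t < 255

    def test_two_thresholds_match_exhaustive_search(self):
        rng = np.random.default_rng(3)
        vals = rng.choice(np.arange(0, 256, 16), size=400)
        img = vals.reshape(20, 20).astype(np.uint8)
        got = multi_otsu_thresholds(img, 2)
        levels = sorted(set(vals.tolist()))
        best = min(
            itertools.combinations(levels[:-1], 2), key=lambda p: intraclass_variance(img, p)
        )
        assert intraclass_variance(img, got) == pytest.approx(intraclass_variance(img, best))

    def test_matches_skimage_multiotsu_partition(self):
        rng = np.random.default_rng(11)
        img = rng.integers(0, 256, (64, 64)).astype(np.uint8)
        sk = threshold_multiotsu(img, classes=3)
        mine = multi_otsu_thresholds(img, 2)
        assert intraclass_variance(img, mine) == pytest.approx(intraclass_variance(img, sk))

    def test_default_returns_eight_increasing_thresholds(self):
        rng = np.random.default_rng(0)
        img = rng.integers(0, 256, (100, 100)).astype(np.uint8)
        t = multi_otsu_thresholds(img, 8)
        assert t.shape == (8,)
        assert (np.diff(t) > 0).all()

    def test_constant_image_degenerate(self):
        with pytest.raises(DegenerateImageError):
            multi_otsu_thresholds(np.full((8, 8), 7, np.uint8), 1)


class TestSftaMasks:
    def test_default_config_yields_fifteen_masks(self):
        rng = np.random.default_rng(1)
        img = rng.integers(0, 256, (32, 32)).astype(np.uint8)
        masks = build_sfta_masks(img, multi_otsu_thresholds(img, 8))
        assert len(masks) == 15
        assert SftaConfig().n_masks == 15

    def test_single_threshold_single_mask(self):
        img = np.arange(64, dtype=np.uint8).reshape(8, 8)
        masks = build_sfta_masks(img, np.array([31.0]))
        assert len(masks) == 1
        assert np.array_equal(masks[0], img > 31)

    def test_band_masks_partition_pixels_above_first_threshold(self):
        rng = np.random.default_rng(2)
        img = rng.integers(0, 256, (16, 16)).astype(np.uint8)
        t = multi_otsu_thresholds(img, 8)
        masks = build_sfta_masks(img, t)
        bands, top_upper = masks[:7], masks[-1]
        # exhaustive per-pixel check: each pixel with g > t1 lies in
        # exactly one of (7 bands + top upper mask)
        membership = np.stack(bands + [top_upper]).sum(axis=0)
        assert np.array_equal(membership == 1, img > t[0])
        assert (membership <= 1).all()

    def test_empty_thresholds_rejected(self):
        with pytest.raises(ValueError):
            build_sfta_masks(np.zeros((4, 4), np.uint8), np.array([]))


class TestBoxCounting:
    def test_empty_mask_zero_by_convention(self):
        assert box_counting_dimension(np.zeros((64, 64), bool)) == 0.0

    def test_straight_line_near_one(self):
        mask = np.zeros((256, 256), bool)
        mask[128, :] = True
        d = box_counting_dimension(mask)
        assert 0.9 <= d <= 1.1
        assert d == pytest.approx(brute_force_dimension(mask))

    def test_dense_random_border_near_two(self):
        rng = np.random.default_rng(7)
        mask = rng.random((256, 256)) < 0.5
        d = box_counting_dimension(mask)
        assert 1.8 <= d <= 2.0
        assert d == pytest.approx(brute_force_dimension(mask))


class TestSftaFeatures:
    def test_forty_five_values(self, thin_tile):
        g = density_to_gray(od_to_density(rgb_to_od(thin_tile.rgb)).blue)
        assert sfta_features(g).shape == (45,)

    def test_constant_tile_all_zeros_with_warning(self):
        with pytest.warns(UserWarning, match="degenerate"):
            out = sfta_features(np.zeros((32, 32), np.uint8))
        assert out.shape == (45,)
        assert not out.any()

    def test_mask_areas_consistent_with_pixel_counts(self):
        rng = np.random.default_rng(4)
        img = rng.integers(0, 256, (50, 50)).astype(np.uint8)
        t = multi_otsu_thresholds(img, 8)
        feats = sfta_features(img)
        areas = feats[1::3]
        band_areas, upper_areas = areas[:7], areas[7:]
        # band areas + top upper area account for every pixel above t1
        assert band_areas.sum() + upper_areas[-1] == int((img > t[0]).sum())
        # upper-mask areas decrease with threshold
        assert (np.diff(upper_areas) <= 0).all()


class TestGabor:
    def test_sixty_values_default_bank(self):
        rng = np.random.default_rng(0)
        img = rng.integers(0, 256, (64, 64)).astype(np.uint8)
        out = gabor_features(img)
        assert out.shape == (60,)
        assert GaborConfig().n_filters == 30

    def test_constant_tile_zero_response(self):
        out = gabor_features(np.full((64, 64), 200, np.uint8))
        assert np.abs(out).max() < 1e-9 * 200

    def test_grating_maximizes_matching_filter(self):
        cfg = GaborConfig()
        yy, xx = np.mgrid[0:200, 0:200]
        th = np.deg2rad(30)
        grating = (127.5 + 127 * np.sin(2 * np.pi * (xx * np.cos(th) + yy * np.sin(th)) / 8.0)).astype(np.uint8)
        amp = gabor_features(grating, cfg)[30:]
        grid = [(lam, o) for lam in cfg.wavelengths for o in cfg.orientations_deg]
        assert grid[int(np.argmax(amp))] == (8.0, 30.0)


class TestPanelAssembly:
    def test_channel_and_tile_lengths(self, thin_tile):
        dens = od_to_density(rgb_to_od(thin_tile.rgb))
        blue = density_to_gray(dens.blue)
        red = density_to_gray(dens.red)
        ch = channel_features(blue)
        assert len(ch) == tx.FEATURES_PER_CHANNEL == 1 + 15 * 3 + 30 + 30
        full = tile_features(blue, red)
        assert len(full) == tx.FEATURES_PER_TILE
        assert sum(n.startswith("blue_") for n in full.index) == 106
        assert full.index.is_unique
        assert np.isfinite(full.to_numpy()).all()

    def test_identical_channels_give_identical_blocks(self):
        rng = np.random.default_rng(6)
        img = rng.integers(0, 256, (64, 64)).astype(np.uint8)
        full = tile_features(img, img)
        blue = full[[n for n in full.index if n.startswith("blue_")]].to_numpy()
        red = full[[n for n in full.index if n.startswith("red_")]].to_numpy()
        assert np.array_equal(blue, red)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError, match="dimensions"):
            tile_features(np.zeros((10, 10), np.uint8), np.zeros((12, 12), np.uint8))

    def test_feature_names_stable_golden(self):
        names = list(channel_features(np.arange(256, dtype=np.uint8).reshape(16, 16)).index)
        assert names[0] == "mean_intensity"
        assert names[1:4] == ["sfta_band1_fractal_dim", "sfta_band1_area", "sfta_band1_mean_int"]
        assert names[43:46] == ["sfta_upper8_fractal_dim", "sfta_upper8_area", "sfta_upper8_mean_int"]
        assert names[46] == "gabor_mse_w2_d0"
        assert names[76] == "gabor_amp_w2_d0"
        assert names[-1] == "gabor_amp_w32_d150"

    def test_rotation_by_90_degrees(self):
        """Mean intensity and SFTA areas/means are exactly invariant;
        Gabor responses permute orientations by +90 degrees."""
        rng = np.random.default_rng(8)
        img = rng.integers(0, 256, (128, 128)).astype(np.uint8)
        f0 = channel_features(img)
        f90 = channel_features(np.rot90(img))
        keep = ["mean_intensity"] + [
            n for n in f0.index if n.startswith("sfta_") and not n.endswith("fractal_dim")
        ]
        assert np.array_equal(f0[keep].to_numpy(), f90[keep].to_numpy())
        cfg = GaborConfig()
        perm = {0.0: 90.0, 30.0: 120.0, 60.0: 150.0, 90.0: 0.0, 120.0: 30.0, 150.0: 60.0}
        for stat in ("mse", "amp"):
            for lam in cfg.wavelengths:
                for o in cfg.orientations_deg:
                    assert f0[f"gabor_{stat}_w{lam:g}_d{o:g}"] == pytest.approx(
                        f90[f"gabor_{stat}_w{lam:g}_d{perm[o]:g}"], rel=1e-6
                    )
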