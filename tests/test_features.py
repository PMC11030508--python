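"""Tiling contract, texture/fractal/Fourier/autocorrelation features."""

import math

import numpy as np
import pytest
from skimage.draw import disk as draw_disk
from skimage.draw import ellipse as draw_ellipse

from oracles import gaussian_autocorr_1e_radius, glcm_contrast_enumerated
from organoidqpi.features import (
    FeatureConfig,
    autocorr_features,
    box_counting_dimension,
    elongated_pattern_score,
    extract_feature_table,
    fourier_features,
    fractal_features,
    texture_features,
    tile_features,
    tile_image,
)
from organoidqpi.phantoms import make_fractal_fixture


class TestTiling:
    def test_720um_image_gives_196_tiles(self):
        grid, tiles = tile_image(np.zeros((720, 720)), pixel_size=1.0)
        assert grid.n_tiles == 196 and len(tiles) == 196
        assert tiles[0].shape == (50, 50)

    def test_tile_equal_to_image_gives_one_tile(self):
        grid, tiles = tile_image(np.zeros((64, 64)), 1.0, tile_size_um=64)
        assert grid.n_tiles == 1

    def test_unit_conversion_preserves_tile_count(self):
        grid, tiles = tile_image(np.zeros((1440, 1440)), pixel_size=0.5)
        assert grid.n_tiles == 196
        assert tiles[0].shape == (100, 100)

    def test_too_fine_tiling_rejected(self):
        with pytest.raises(ValueError):
            tile_image(np.zeros((64, 64)), pixel_size=10.0)


class TestTexture:
    def test_constant_tile_degenerates_cleanly(self):
        f = texture_features(np.full((50, 50), 3.2))
        assert f["glcm_energy"] == 1.0
        assert f["glcm_contrast"] == 0.0
        assert f["glcm_entropy"] == 0.0

    def test_checkerboard_contrast_matches_enumeration_oracle(self):
        board = np.indices((20, 20)).sum(axis=0) % 2
        f = texture_features(board, levels=2, angles=(0,), quantized=True)
        expected = glcm_contrast_enumerated(board, offset=(0, 1))
        assert f["glcm_contrast"] == pytest.approx(expected, abs=1e-12)
        assert expected == 1.0  # every horizontal pair differs by ΔL = 1

    def test_energy_bounded_and_entropy_nonnegative(self, rng):
        f = texture_features(rng.standard_normal((50, 50)))
        assert 0 < f["glcm_energy"] <= 1
        assert f["glcm_entropy"] >= 0


class TestFractal:
    @pytest.mark.parametrize(
        "kind,expected",
        [
            ("filled_square", 2.0),
            ("line", 1.0),
            ("sierpinski_carpet", math.log(8) / math.log(3)),
        ],
    )
    def test_box_dimension_of_analytic_fixtures(self, kind, expected):
        img = make_fractal_fixture(kind, 243)
        assert box_counting_dimension(img) == pytest.approx(expected, abs=0.05)

    def test_empty_binarization_flags_and_zeroes(self):
        f = fractal_features(np.zeros((50, 50)), binary=np.zeros((50, 50), bool))
        assert f["fractal_empty"] == 1.0
        assert f["fractal_boxdim_global"] == 0.0

    def test_elongated_cells_score_higher_than_equal_area_disks(self):
        # aligned 2:1 ellipses (8 µm long) vs 8 µm disks, equal area fraction
        wins = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            te = np.zeros((50, 50), bool)
            td = np.zeros((50, 50), bool)
            for _ in range(8):
                r, c = rng.uniform(6, 44, 2)
                te[draw_ellipse(r, c, 2, 4, shape=te.shape)] = True
            for _ in range(4):
                r, c = rng.uniform(6, 44, 2)
                td[draw_disk((r, c), 4, shape=td.shape)] = True
            if elongated_pattern_score(te, 6.0) > elongated_pattern_score(td, 6.0):
                wins += 1
        assert wins >= 19

    def test_circle_pattern_prefers_in_band_disks(self):
        in_band = np.zeros((50, 50), bool)   # ~36 µm² disks (r ≈ 3.4)
        out_band = np.zeros((50, 50), bool)  # much larger disks
        for r, c in [(12, 12), (12, 38), (38, 12), (38, 38)]:
            in_band[draw_disk((r, c), 3.4, shape=in_band.shape)] = True
            out_band[draw_disk((r, c), 8, shape=out_band.shape)] = True
        fi = fractal_features(np.where(in_band, 1.0, 0.0), 1.0)
        fo = fractal_features(np.where(out_band, 1.0, 0.0), 1.0)
        assert fi["circle_pattern_34_38um2"] > fo["circle_pattern_34_38um2"]


class TestFourier:
    def test_stripes_localize_in_frequency_and_orientation(self):
        xx = np.indices((50, 50))[1]
        f = fourier_features(np.sin(2 * np.pi * xx / 10.0), 1.0)
        assert f["fourier_peak_freq_um1"] == pytest.approx(0.1, abs=0.01)
        # stripe normal is horizontal: orientation 0° (mod 180°)
        ang = min(f["fourier_orientation_deg"], 180 - f["fourier_orientation_deg"])
        assert ang <= 5.0
        powers = {k: v for k, v in f.items() if k.startswith("fourier_power")}
        # the 10 µm period lands in the 9–17 µm band; window sidelobes leak a
        # little into the adjacent band but the in-band power dominates
        assert max(powers, key=powers.get) == "fourier_power_9_17um"
        assert powers["fourier_power_9_17um"] > 0.75 * sum(powers.values())

    def test_parseval_band_partition(self, rng):
        tile = rng.standard_normal((50, 50))
        f = fourier_features(tile, 1.0)
        win = np.outer(np.hanning(50), np.hanning(50))
        x = (tile - tile.mean()) * win
        total = sum(v for k, v in f.items() if k.startswith("fourier_power"))
        assert total == pytest.approx(np.mean(x**2), rel=1e-6)

    def test_white_noise_is_nearly_isotropic(self):
        vals = [
            fourier_features(
                np.random.default_rng(s).standard_normal((50, 50)), 1.0
            )["fourier_anisotropy"]
            for s in range(20)
        ]
        assert np.mean(vals) <= 0.1


class TestAutocorr:
    def test_gaussian_blob_correlation_length(self):
        sigma = 5.0
        yy, xx = np.indices((128, 128))
        tile = np.exp(-((yy - 64) ** 2 + (xx - 64) ** 2) / (2 * sigma**2))
        f = autocorr_features(tile, 1.0)
        expected = gaussian_autocorr_1e_radius(sigma)
        assert f["autocorr_length_um"] == pytest.approx(expected, rel=0.15)

    def test_isotropic_noise_low_anisotropy(self):
        vals = [
            autocorr_features(
                np.random.default_rng(s).standard_normal((50, 50)), 1.0
            )["autocorr_anisotropy"]
            for s in range(20)
        ]
        assert np.mean(vals) <= 0.1

    def test_constant_tile_degenerates_to_zero(self):
        f = autocorr_features(np.full((50, 50), 2.0), 1.0)
        assert f["autocorr_length_um"] == 0.0


class TestAssembly:
    def test_feature_table_shape_and_metadata(self, rng):
        imgs = [rng.standard_normal((150, 150))]
        table = extract_feature_table(imgs, [{"group": "c"}], pixel_size=1.0)
        assert len(table) == 9  # 3×3 full 50 px tiles
        assert "group" in table.columns and "glcm_contrast" in table.columns

    def test_identical_images_give_identical_blocks(self, rng):
        img = rng.standard_normal((100, 100))
        table = extract_feature_table([img, img.copy()], None, 1.0)
        featcols = [c for c in table.columns if c != "image_index"]
        a = table[table.image_index == 0][featcols].reset_index(drop=True)
        b = table[table.image_index == 1][featcols].reset_index(drop=True)
        assert a.equals(b)

    def test_all_features_finite_on_phantom(self, small_phantom):
        table = extract_feature_table([small_phantom.ri_map], None, 1.0)
        num = table.select_dtypes(float)
        assert np.isfinite(num.to_numpy()).all()

    def test_feature_determinism_bitwise(self, rng):
        tile = rng.standard_normal((50, 50))
        a = tile_features(tile, 1.0)
        b = tile_features(tile.copy(), 1.0)
        assert a == b

    def test_rotation_invariant_features_stable_under_90_degrees(self, small_phantom):
        tile = small_phantom.ri_map[100:150, 100:150]
        a = tile_features(tile, 1.0)
        b = tile_features(np.rot90(tile), 1.0)
        for key in ("fractal_boxdim_global", "circle_pattern_34_38um2",
                    "autocorr_length_um"):
            assert b[key] == pytest.approx(a[key], rel=0.02, abs=1e-9)

    def test_family_switches_respected(self, rng):
        tile_img = rng.standard_normal((100, 100))
        table = extract_feature_table(
            [tile_img], None, 1.0, FeatureConfig(families=("fractal",))
        )
        assert not any(c.startswith("glcm") for c in table.columns)
        assert any(c.startswith("fractal") for c in table.columns)
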