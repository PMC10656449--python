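"""Macro-pixel analysis: segmentation, arc/scatter/point classification,
orientation vectors, apertures, mosaic reconstruction."""

import numpy as np
import pytest

from collagenfft import anisotropy as an, phantom, spectral_core as sc
from collagenfft.afm_io import AFMImage
from collagenfft.errors import (
    ApertureUndefinedError,
    NoOrientationError,
    ParameterError,
    ResolutionError,
)

from conftest import BAND, PIXEL_NM, axial_diff, small_phantom_spec


def psd_of(image: AFMImage) -> sc.PowerSpectrum2D:
    return sc.psd(sc.fft2d(image))


class TestSegmentation:
    def test_512px_gives_16_tiles(self):
        img = AFMImage(pixels=np.zeros((512, 512)), width_um=5.0, height_um=5.0)
        grid = an.segment_macropixels(img, tile_px=128)
        assert (grid.n_rows, grid.n_cols, len(grid.tiles)) == (4, 4, 16)
        assert grid.remainder_px == (0, 0)
        # tiles inherit pixel size and exactly cover the region
        _, _, t0 = grid.tiles[0]
        assert t0.pixel_size_nm == pytest.approx(img.pixel_size_nm)

    def test_single_tile_image(self):
        img = AFMImage(pixels=np.zeros((128, 128)), width_um=1.25, height_um=1.25)
        grid = an.segment_macropixels(img, tile_px=128)
        assert len(grid.tiles) == 1

    def test_remainder_dropped_and_reported(self):
        img = AFMImage(pixels=np.zeros((600, 600)), width_um=6.0, height_um=6.0)
        grid = an.segment_macropixels(img, tile_px=128)
        assert len(grid.tiles) == 16
        assert grid.remainder_px == (88, 88)

    def test_small_tile_rejected(self):
        img = AFMImage(pixels=np.zeros((512, 512)), width_um=5.0, height_um=5.0)
        with pytest.raises(ResolutionError):
            an.segment_macropixels(img, tile_px=64)

    def test_image_smaller_than_tile_rejected(self):
        img = AFMImage(pixels=np.zeros((100, 100)), width_um=1.0, height_um=1.0)
        with pytest.raises(ParameterError):
            an.segment_macropixels(img, tile_px=128)

    def test_tiles_partition_pixels(self):
        rng = np.random.default_rng(0)
        img = AFMImage(pixels=rng.normal(size=(256, 256)), width_um=2.5, height_um=2.5)
        grid = an.segment_macropixels(img, tile_px=128)
        rebuilt = np.block(
            [[grid.tiles[i * 2 + j][2].pixels for j in range(2)] for i in range(2)]
        )
        assert np.array_equal(rebuilt, img.pixels)


class TestClassifyTile:
    def test_aligned_phantom_tile_is_oriented(self):
        img, _ = phantom.render_phantom(small_phantom_spec([25.0], px=128, n_fibrils=14, seed=5))
        tc = an.classify_tile(img, BAND)
        assert tc.label in ("arc", "point_set")
        assert axial_diff(tc.orientation_deg, 25.0) <= 2.0
        assert 0.0 <= tc.concentration <= 1.0

    def test_noise_tiles_are_scatter_or_empty(self, make_noise_tile):
        """≥90% of 50 isotropic-noise tiles classified scatter/empty."""
        good = sum(
            an.classify_tile(make_noise_tile(seed), BAND).label in ("scatter", "empty")
            for seed in range(50)
        )
        assert good >= 45

    def test_blank_tile_is_empty(self):
        img = AFMImage(pixels=np.zeros((128, 128)), width_um=1.25, height_um=1.25)
        assert an.classify_tile(img, BAND).label == "empty"

    def test_perfectly_aligned_gives_single_discrete_point(self):
        img, _ = phantom.render_phantom(
            small_phantom_spec([40.0], px=128, n_fibrils=14, seed=6, noise=0.02)
        )
        tc = an.classify_tile(img, BAND)
        assert tc.label == "point_set"
        assert len(tc.point_angles_deg) == 1
        assert axial_diff(tc.point_angles_deg[0], 40.0) <= 2.0

    def test_small_tile_rejected(self):
        img = AFMImage(pixels=np.zeros((64, 64)), width_um=0.625, height_um=0.625)
        with pytest.raises(ResolutionError):
            an.classify_tile(img, BAND)


class TestDiscretePoints:
    @pytest.mark.parametrize(
        "preset_name, expected",
        [("two_group_20", 2), ("four_group_0_30_45_60", 4), ("uniform_aligned", 1)],
    )
    def test_point_counts_on_presets(self, render_preset, preset_name, expected):
        img, _ = render_preset(preset_name)
        pts = an.detect_discrete_points(psd_of(img), BAND)
        assert len(pts) == expected

    def test_two_group_separation_20_degrees(self, render_preset):
        img, _ = render_preset("two_group_20")
        pts = an.detect_discrete_points(psd_of(img), BAND)
        sep = axial_diff(pts[0], pts[1])
        assert sep == pytest.approx(20.0, abs=2.0)

    def test_zero_psd_no_points(self):
        p = sc.PowerSpectrum2D(power=np.zeros((128, 128)), source_px=(128, 128), pixel_size_nm=PIXEL_NM)
        assert an.detect_discrete_points(p, BAND) == []

    def test_point_count_fidelity_over_18_seeds(self):
        """k ∈ {1..4} groups with ≥10° pairwise separation: exact count
        recovered in at least 17/18 seeded runs."""
        group_sets = {1: [30.0], 2: [30.0, 50.0], 3: [20.0, 45.0, 70.0], 4: [10.0, 35.0, 60.0, 85.0]}
        hits = 0
        for seed in range(18):
            k = seed % 4 + 1
            spec = small_phantom_spec(group_sets[k], n_fibrils=max(12, 60 // k), seed=seed)
            img, _ = phantom.render_phantom(spec)
            hits += len(an.detect_discrete_points(psd_of(img), BAND)) == k
        assert hits >= 17

    @pytest.mark.parametrize("sep", [10, 20, 30, 40, 50, 60, 70, 80])
    def test_separation_fidelity(self, sep):
        """Measured angle between two points tracks the generative separation."""
        spec = small_phantom_spec([20.0, 20.0 + sep], seed=sep)
        img, _ = phantom.render_phantom(spec)
        pts = an.detect_discrete_points(psd_of(img), BAND)
        assert len(pts) == 2
        assert axial_diff(pts[0], pts[1]) == pytest.approx(sep, abs=2.0)


class TestOrientation:
    def test_orientation_recovery_mae_below_2_degrees(self):
        """Mean absolute orientation error over generative angles 0°..170°."""
        errs = []
        for ang in range(0, 180, 10):
            spec = small_phantom_spec([float(ang)], px=128, n_fibrils=14, seed=42)
            img, _ = phantom.render_phantom(spec)
            tc = an.classify_tile(img, BAND)
            assert tc.label in ("arc", "point_set")
            errs.append(axial_diff(tc.orientation_deg, ang))
        assert float(np.mean(errs)) <= 2.0

    def test_axial_doubling_convention(self):
        """A 180°-rotated image has the same orientation estimate: fibril
        direction lives on [0°, 180°)."""
        spec = small_phantom_spec([73.0], px=128, n_fibrils=14, seed=8)
        img, _ = phantom.render_phantom(spec)
        flipped = AFMImage(
            pixels=np.rot90(img.pixels, 2), width_um=img.width_um, height_um=img.height_um
        )
        t1 = an.classify_tile(img, BAND)
        t2 = an.classify_tile(flipped, BAND)
        assert axial_diff(t1.orientation_deg, t2.orientation_deg) <= 0.5

    def test_orientation_vector_contract(self):
        arc = an.TileClassification(row=0, col=0, label="arc", orientation_deg=37.0)
        assert an.orientation_vector(arc) == 37.0
        scatter = an.TileClassification(row=0, col=0, label="scatter")
        with pytest.raises(NoOrientationError):
            an.orientation_vector(scatter)

    def test_single_point_orientation_matches_point(self):
        img, _ = phantom.render_phantom(
            small_phantom_spec([40.0], px=128, n_fibrils=14, seed=6, noise=0.02)
        )
        tc = an.classify_tile(img, BAND)
        assert tc.label == "point_set"
        assert axial_diff(tc.orientation_deg, tc.point_angles_deg[0]) <= 0.5


class TestArcAperture:
    def test_four_group_span_60_degrees(self, render_preset):
        img, _ = render_preset("four_group_0_30_45_60")
        ap = an.arc_aperture(psd_of(img), BAND)
        assert ap == pytest.approx(60.0, abs=10.0)

    def test_single_orientation_is_point_like(self, render_preset):
        img, _ = render_preset("uniform_aligned")
        assert an.arc_aperture(psd_of(img), BAND) <= 10.0

    def test_undefined_for_isotropic_noise(self, make_noise_tile):
        with pytest.raises(ApertureUndefinedError):
            an.arc_aperture(psd_of(make_noise_tile(3)), BAND)

    def test_invalid_energy_fraction(self, render_preset):
        img, _ = render_preset("uniform_aligned")
        with pytest.raises(ParameterError):
            an.arc_aperture(psd_of(img), BAND, energy_fraction=1.5)


class TestMosaic:
    def test_aligned_phantom_mosaic(self, render_preset):
        img, _ = render_preset("wildtype")
        grid = an.segment_macropixels(img, 128)
        mosaic, tiles, summary = an.build_mosaic(grid, BAND)
        oriented = sum(t.label in ("arc", "point_set") for t in tiles)
        assert oriented >= 14
        assert summary["orientation_dispersion_deg"] < 5.0
        assert axial_diff(summary["mean_orientation_deg"], 25.0) <= 2.0
        assert mosaic.shape == (512, 512)

    def test_eds_phantom_majority_scatter(self, render_preset):
        img, _ = render_preset("eds_like")
        grid = an.segment_macropixels(img, 128)
        _, tiles, summary = an.build_mosaic(grid, BAND)
        assert summary["label_fractions"]["scatter"] > 0.5

    def test_blank_grid_all_empty(self):
        img = AFMImage(pixels=np.zeros((512, 512)), width_um=5.0, height_um=5.0)
        grid = an.segment_macropixels(img, 128)
        _, tiles, summary = an.build_mosaic(grid, BAND)
        assert all(t.label == "empty" for t in tiles)
        assert summary["label_fractions"]["empty"] == 1.0
        assert summary["mean_orientation_deg"] is None
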