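"""Color calibration, pixel classification, tiling and median aggregation."""

import dataclasses

import numpy as np
import pytest

from fibroquant import (
    CalibrationError,
    ClassMap,
    ColorModel,
    NoTissueError,
    SectionImage,
    SectionSpec,
    StageError,
    calibrate_colors,
    classify_pixels,
    default_color_model,
    generate_section,
    quantify_image,
    quantify_section,
    run_quantification,
    tile_side_for_area,
    train_color_model,
    write_section_image,
)
from fibroquant.evg_quant import (
    CLASS_NAMES,
    COLLAGEN,
    CYTOPLASM,
    DEFAULT_PALETTE,
    ELASTIN,
    GLASS,
    rgb_to_working,
)


def _uniform_image(rgb, shape=(32, 32), resolution=0.46):
    px = np.tile(np.asarray(rgb, np.uint8), (*shape, 1))
    return SectionImage(pixels=px, resolution_um_per_px=resolution)


# ---------------------------------------------------------------------------
# Calibration
# ---------------------------------------------------------------------------


class TestCalibrateColors:
    def test_already_calibrated_is_identity_within_one_level(self, color_model):
        sec = generate_section(SectionSpec(color_noise_sd=0.0, seed=1))
        out = calibrate_colors(sec.image, color_model)
        assert np.max(np.abs(out.pixels.astype(int) - sec.image.pixels.astype(int))) <= 1

    def test_known_gain_recovered(self, color_model):
        sec = generate_section(SectionSpec(color_noise_sd=0.0, seed=2))
        dimmed = SectionImage(
            pixels=np.round(sec.image.pixels * 0.9).astype(np.uint8),
            resolution_um_per_px=sec.image.resolution_um_per_px,
        )
        out = calibrate_colors(dimmed, color_model)
        assert np.max(np.abs(out.pixels.astype(int) - sec.image.pixels.astype(int))) <= 1

    def test_no_background_raises(self, color_model):
        dark = _uniform_image((40, 40, 40))
        with pytest.raises(CalibrationError):
            calibrate_colors(dark, color_model)


# ---------------------------------------------------------------------------
# Color model training
# ---------------------------------------------------------------------------


class TestTrainColorModel:
    def test_constant_swatches_give_exact_means_and_ridge_covariance(self):
        swatches = {
            name: np.tile(np.asarray(DEFAULT_PALETTE[name], float), (60, 1))
            for name in CLASS_NAMES
        }
        model = train_color_model(swatches, ridge=2.0)
        for code, name in enumerate(CLASS_NAMES):
            np.testing.assert_allclose(
                model.means[code], rgb_to_working(np.asarray(DEFAULT_PALETTE[name], float))
            )
            np.testing.assert_allclose(model.covariances[code], 2.0 * np.eye(3))

    def test_gaussian_swatches_recover_means_within_3se(self, rng):
        true = {n: np.asarray(DEFAULT_PALETTE[n], float) for n in CLASS_NAMES}
        sd, n = 6.0, 4000
        swatches = {n_: rng.normal(true[n_], sd, size=(n, 3)) for n_ in CLASS_NAMES}
        model = train_color_model(swatches)
        se = sd / np.sqrt(n) * np.abs(rgb_to_working(np.ones(3)))  # loose per-channel SE
        for code, name in enumerate(CLASS_NAMES):
            err = np.abs(model.means[code] - rgb_to_working(true[name]))
            assert np.all(err < 3 * np.maximum(se, sd / np.sqrt(n) * 3))

    def test_missing_class_listed(self):
        swatches = {n: np.zeros((60, 3)) for n in CLASS_NAMES if n != "elastin"}
        with pytest.raises(ValueError, match="elastin"):
            train_color_model(swatches)

    def test_too_few_pixels_rejected(self):
        swatches = {n: np.zeros((10, 3)) for n in CLASS_NAMES}
        with pytest.raises(ValueError, match="50"):
            train_color_model(swatches)

    def test_palette_self_consistency(self):
        # a model trained on palette swatches classifies each palette color
        # back to its own class
        rng = np.random.default_rng(0)
        swatches = {
            n: rng.normal(DEFAULT_PALETTE[n], 5.0, size=(500, 3)) for n in CLASS_NAMES
        }
        model = train_color_model(swatches)
        for code, name in enumerate(CLASS_NAMES):
            img = _uniform_image(DEFAULT_PALETTE[name], shape=(4, 4))
            assert (classify_pixels(img, model).labels == code).all()


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------


from tests_oracles import brute_force_labels as _brute_force_labels


class TestClassifyPixels:
    def test_uniform_glass_image_all_glass(self, color_model):
        img = _uniform_image(DEFAULT_PALETTE["glass"])
        assert (classify_pixels(img, color_model).labels == GLASS).all()

    def test_two_region_mean_colors_match_regions_exactly(self, color_model):
        px = np.empty((20, 40, 3), np.uint8)
        px[:, :20] = DEFAULT_PALETTE["collagen"]
        px[:, 20:] = DEFAULT_PALETTE["elastin"]
        labels = classify_pixels(SectionImage(px, 0.46), color_model).labels
        assert (labels[:, :20] == COLLAGEN).all()
        assert (labels[:, 20:] == ELASTIN).all()

    def test_matches_brute_force_oracle_on_random_image(self, rng):
        img = SectionImage(rng.integers(0, 256, size=(64, 64, 3), dtype=np.uint8), 0.46)
        # anisotropic random model so the Mahalanobis metric actually matters
        means = rgb_to_working(rng.uniform(30, 230, size=(5, 3)))
        covs = np.empty((5, 3, 3))
        for k in range(5):
            a = rng.normal(size=(3, 3))
            covs[k] = a @ a.T + 5.0 * np.eye(3)
        model = ColorModel(means=means, covariances=covs)
        np.testing.assert_array_equal(
            classify_pixels(img, model).labels, _brute_force_labels(img, model)
        )

    def test_exact_tie_never_called_fiber(self, color_model):
        # collapse collagen and elastin onto the same distribution: every
        # pixel of that color ties, and the tie must resolve to the lower,
        # non-elastin code
        means = color_model.means.copy()
        means[ELASTIN] = means[COLLAGEN]
        model = ColorModel(means=means, covariances=color_model.covariances)
        rgb = DEFAULT_PALETTE["collagen"]
        labels = classify_pixels(_uniform_image(rgb), model).labels
        assert (labels == COLLAGEN).all()

    def test_zero_noise_round_trip_reproduces_label_map(self, color_model):
        sec = generate_section(
            SectionSpec(width_px=128, height_px=128, color_noise_sd=0.0, seed=5,
                        vessel_lumen_count=1)
        )
        calibrated = calibrate_colors(sec.image, color_model)
        np.testing.assert_array_equal(
            classify_pixels(calibrated, color_model).labels, sec.labels
        )

    def test_accuracy_at_noise_sd8(self, color_model):
        sec = generate_section(SectionSpec(width_px=200, height_px=200, seed=6))
        calibrated = calibrate_colors(sec.image, color_model)
        acc = (classify_pixels(calibrated, color_model).labels == sec.labels).mean()
        assert acc >= 0.99


# ---------------------------------------------------------------------------
# Tiling geometry and quantification
# ---------------------------------------------------------------------------


class TestTileSide:
    @pytest.mark.parametrize(
        "resolution,area,expected", [(0.46, 1.0, 2173), (1.0, 1.0, 1000), (0.92, 1.0, 1086)]
    )
    def test_known_values(self, resolution, area, expected):
        assert tile_side_for_area(resolution, area) == expected

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            tile_side_for_area(0.0)
        with pytest.raises(ValueError):
            tile_side_for_area(0.46, -1.0)


def _class_map_from_tiles(tile_cpas, side=10, epa_percents=None):
    """Build a ClassMap whose tiles have prescribed collagen (and elastin) %."""
    n = len(tile_cpas)
    labels = np.full((side, side * n), CYTOPLASM, np.uint8)
    for i, cpa in enumerate(tile_cpas):
        n_col = round(cpa / 100 * side * side)
        block = labels[:, i * side : (i + 1) * side].ravel()
        block[:n_col] = COLLAGEN
        if epa_percents is not None:
            n_ela = round(epa_percents[i] / 100 * side * side)
            block[n_col : n_col + n_ela] = ELASTIN
        labels[:, i * side : (i + 1) * side] = block.reshape(side, side)
    return ClassMap(labels=labels)


class TestQuantifySection:
    def test_median_over_odd_tile_count(self):
        cm = _class_map_from_tiles([2, 4, 6])
        res = quantify_section(cm, tile_side_px=10)
        assert res.median_cpa == pytest.approx(4.0)
        assert res.n_tiles_included == 3

    def test_even_tile_count_takes_mean_of_middle_two(self):
        cm = _class_map_from_tiles([0, 0, 0, 0], epa_percents=[1, 2, 3, 10])
        res = quantify_section(cm, tile_side_px=10)
        assert res.median_epa == pytest.approx(2.5)

    def test_glass_tile_excluded_and_median_unchanged(self):
        cm = _class_map_from_tiles([2, 4, 6])
        labels = cm.labels.copy()
        labels[:, 20:30] = GLASS  # vessel lumen swallows the third tile
        res_with = quantify_section(ClassMap(labels), tile_side_px=10)
        assert res_with.n_tiles_included == 2
        assert res_with.median_cpa == pytest.approx(3.0)  # median of {2, 4}

    def test_all_glass_raises_no_tissue(self):
        cm = ClassMap(labels=np.zeros((20, 20), np.uint8))
        with pytest.raises(NoTissueError):
            quantify_section(cm, tile_side_px=10)

    def test_counts_conserved_and_tissue_percentages_sum_to_100(self, rng):
        labels = rng.integers(0, 5, size=(37, 53)).astype(np.uint8)  # partial edge tiles
        res = quantify_section(ClassMap(labels), tile_side_px=10)
        total = sum(t.tile_pixels for t in res.tiles)
        assert total == labels.size
        for t in res.tiles:
            if t.tissue_pixels:
                pct = [100.0 * t.class_counts[c] / t.tissue_pixels for c in (1, 2, 3, 4)]
                assert sum(pct) == pytest.approx(100.0, rel=1e-9)

    def test_partial_edge_tiles_kept(self):
        labels = np.full((15, 25), CYTOPLASM, np.uint8)
        res = quantify_section(ClassMap(labels), tile_side_px=10)
        assert len(res.tiles) == 2 * 3
        assert res.n_tiles_included == 6


class TestEndToEnd:
    @pytest.mark.parametrize(
        "cpa,epa,noise,tol",
        [(14.1, 2.5, 0.0, 0.3), (6.5, 4.8, 8.0, 0.5)],
    )
    def test_truth_recovery_through_file_round_trip(self, tmp_path, cpa, epa, noise, tol):
        sec = generate_section(
            SectionSpec(
                width_px=256,
                height_px=256,
                true_collagen_fraction=cpa / 100,
                true_elastin_fraction=epa / 100,
                color_noise_sd=noise,
                seed=23,
            )
        )
        path = tmp_path / "case.png"
        write_section_image(sec.image, path)
        res = run_quantification(path)
        assert res.median_cpa == pytest.approx(cpa, abs=tol)
        assert res.median_epa == pytest.approx(epa, abs=tol)

    def test_all_glass_image_raises_staged_no_tissue(self, tmp_path):
        px = np.tile(np.asarray(DEFAULT_PALETTE["glass"], np.uint8), (96, 96, 1))
        path = tmp_path / "blank.png"
        write_section_image(SectionImage(px, 0.46), path)
        with pytest.raises(StageError) as exc:
            run_quantification(path)
        assert exc.value.stage == "quantify"
        assert isinstance(exc.value.cause, NoTissueError)

    def test_median_cpa_monotone_in_true_collagen(self, color_model):
        base = SectionSpec(width_px=160, height_px=160, color_noise_sd=0.0, seed=31)
        medians = []
        for f in (0.05, 0.10, 0.15, 0.20, 0.30):
            sec = generate_section(dataclasses.replace(base, true_collagen_fraction=f))
            res, _ = quantify_image(sec.image, color_model)
            medians.append(res.median_cpa)
        assert all(b >= a for a, b in zip(medians, medians[1:]))
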