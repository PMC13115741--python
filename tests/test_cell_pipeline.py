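import math

import numpy as np
import pytest
from skimage.draw import disk

from gliaquant.cell_pipeline import (
    CellROI,
    apply_mask_minimum,
    chain_code_perimeter,
    extract_square_roi,
    filter_objects_by_size,
    measure_cell,
    run_pipeline,
)
from gliaquant.imaging_io import (
    AnnotationSet,
    IntensityImage,
    Polyline,
    SegmentationMask,
    read_measurements,
)
from gliaquant.pixel_classifier import train_classifier

SQRT2 = math.sqrt(2)


class TestROIExtraction:
    def test_centered_crop_indexing(self):
        img = IntensityImage(np.arange(10000.0).reshape(100, 100))
        roi = CellROI("c", center=(50, 50), side=20)
        crop = extract_square_roi(img, roi)
        np.testing.assert_array_equal(crop.pixels, img.pixels[40:60, 40:60])
        assert crop.pixel_size_um == img.pixel_size_um

    def test_out_of_bounds_is_an_error_not_padding(self):
        img = IntensityImage(np.zeros((100, 100)))
        with pytest.raises(ValueError, match="bounds"):
            extract_square_roi(img, CellROI("c", center=(5, 5), side=20))

    def test_crop_of_constant_is_constant(self):
        img = IntensityImage(np.full((50, 50), 3.25))
        crop = extract_square_roi(img, CellROI("c", center=(25, 25), side=16))
        assert (crop.pixels == 3.25).all() and crop.shape == (16, 16)

    def test_minimum_side(self):
        with pytest.raises(ValueError, match="side"):
            CellROI("c", center=(5, 5), side=4)


class TestSizeFilter:
    def test_small_component_removed(self):
        m = np.zeros((20, 20), bool)
        m[1:2, 1:6] = True  # 5 px
        m[10:15, 5:15] = True  # 50 px
        out = filter_objects_by_size(SegmentationMask(m), 10)
        assert out.area_px == 50

    def test_min_area_zero_is_identity(self):
        rng = np.random.default_rng(0)
        m = SegmentationMask(rng.random((30, 30)) < 0.4)
        np.testing.assert_array_equal(
            filter_objects_by_size(m, 0).pixels, m.pixels
        )

    def test_diagonal_pair_connectivity(self):
        m = np.zeros((6, 6), bool)
        m[2, 2] = m[3, 3] = True
        assert filter_objects_by_size(SegmentationMask(m), 2, connectivity=8).area_px == 2
        assert filter_objects_by_size(SegmentationMask(m), 2, connectivity=4).area_px == 0

    def test_output_subset_and_monotone_in_threshold(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            m = SegmentationMask(rng.random((25, 25)) < 0.35)
            prev = m.pixels.sum()
            for thr in (0, 2, 5, 10, 20):
                out = filter_objects_by_size(m, thr)
                assert not (out.pixels & ~m.pixels).any()  # subset
                assert out.pixels.sum() <= prev
                prev = out.pixels.sum()

    def test_um2_units(self):
        m = np.zeros((10, 10), bool)
        m[2:5, 2:5] = True  # 9 px = 0.81 um^2 at 0.3 um/px
        kept = filter_objects_by_size(
            SegmentationMask(m), 0.8, units="um2", pixel_size_um=0.3
        )
        removed = filter_objects_by_size(
            SegmentationMask(m), 0.9, units="um2", pixel_size_um=0.3
        )
        assert kept.area_px == 9 and removed.area_px == 0


class TestMaskMinimum:
    def test_worked_example(self):
        roi = IntensityImage(np.array([[10.0, 200.0], [50.0, 0.0]]))
        mask = SegmentationMask(np.array([[True, False], [True, True]]))
        out = apply_mask_minimum(roi, mask)
        np.testing.assert_array_equal(out.pixels, [[10, 0], [50, 0]])

    def test_all_true_and_all_false(self):
        roi = IntensityImage(np.arange(16.0).reshape(4, 4))
        ones = SegmentationMask(np.ones((4, 4), bool))
        zeros = SegmentationMask(np.zeros((4, 4), bool))
        np.testing.assert_array_equal(apply_mask_minimum(roi, ones).pixels, roi.pixels)
        assert not apply_mask_minimum(roi, zeros).pixels.any()

    def test_idempotent(self):
        rng = np.random.default_rng(2)
        roi = IntensityImage(rng.random((12, 12)) * 100)
        mask = SegmentationMask(rng.random((12, 12)) < 0.5)
        once = apply_mask_minimum(roi, mask)
        twice = apply_mask_minimum(once, mask)
        np.testing.assert_array_equal(once.pixels, twice.pixels)

    def test_commutes_with_crop(self):
        rng = np.random.default_rng(3)
        img = IntensityImage(rng.random((40, 40)) * 50)
        mask = SegmentationMask(rng.random((40, 40)) < 0.5)
        roi = CellROI("c", center=(20, 20), side=16)
        a = extract_square_roi(apply_mask_minimum(img, mask), roi)
        from gliaquant.cell_pipeline import extract_square_mask

        b = apply_mask_minimum(
            extract_square_roi(img, roi), extract_square_mask(mask, roi)
        )
        np.testing.assert_array_equal(a.pixels, b.pixels)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError, match="shape"):
            apply_mask_minimum(
                IntensityImage(np.zeros((4, 4))),
                SegmentationMask(np.zeros((5, 5), bool)),
            )


class TestChainCodePerimeter:
    @pytest.mark.parametrize(
        "builder,expected",
        [
            # solid 10x10 square: 36 straight steps through boundary centers
            (lambda m: m.__setitem__((slice(5, 15), slice(5, 15)), True), 36.0),
            # 3x7 rectangle: 2*(2+6)
            (lambda m: m.__setitem__((slice(2, 5), slice(2, 9)), True), 16.0),
        ],
    )
    def test_known_rectangles(self, builder, expected):
        m = np.zeros((20, 20), bool)
        builder(m)
        assert chain_code_perimeter(SegmentationMask(m)) == expected

    def test_diagonal_pair_and_single_pixel(self):
        m = np.zeros((6, 6), bool)
        m[2, 2] = m[3, 3] = True
        assert chain_code_perimeter(SegmentationMask(m)) == pytest.approx(2 * SQRT2)
        s = np.zeros((5, 5), bool)
        s[2, 2] = True
        assert chain_code_perimeter(SegmentationMask(s)) == 4.0

    def test_hole_boundary_included(self):
        m = np.zeros((20, 20), bool)
        m[5:15, 5:15] = True
        m[8:12, 8:12] = False  # 4x4 hole -> its own 12-step boundary
        assert chain_code_perimeter(SegmentationMask(m)) == 36.0 + 12.0

    def test_multiple_components_sum(self):
        m = np.zeros((30, 30), bool)
        m[2:12, 2:12] = True
        m[20:23, 20:27] = True
        assert chain_code_perimeter(SegmentationMask(m)) == 36.0 + 16.0


class TestMorphometry:
    def test_square_oracle(self):
        img = IntensityImage(np.full((20, 20), 50.0), 0.3)
        m = np.zeros((20, 20), bool)
        m[5:15, 5:15] = True
        rec = measure_cell(img, SegmentationMask(m), cell_id="sq")
        assert rec.mean_intensity == 50.0
        assert rec.area_um2 == pytest.approx(9.0)
        assert rec.perimeter_um == pytest.approx(10.8)
        assert rec.circularity == pytest.approx(4 * math.pi * 9.0 / 10.8**2, abs=1e-12)
        assert rec.circularity == pytest.approx(0.970, abs=1e-3)
        assert rec.area_to_perimeter_um == pytest.approx(9.0 / 10.8, abs=1e-15)
        assert rec.n_objects == 1

    def test_disk_circularity_near_isoperimetric_limit(self):
        m = np.zeros((80, 80), bool)
        rr, cc = disk((40, 40), 30)
        m[rr, cc] = True
        rec = measure_cell(
            IntensityImage(np.ones((80, 80)), 0.3), SegmentationMask(m), "disk"
        )
        assert 0.90 <= rec.circularity <= 1.05

    def test_mean_intensity_over_mask_only(self):
        img = np.full((10, 10), 5.0)
        img[0:2, 0:2] = 100.0
        m = np.zeros((10, 10), bool)
        m[0:2, 0:2] = True
        rec = measure_cell(IntensityImage(img), SegmentationMask(m), "c")
        assert rec.mean_intensity == 100.0  # zeros outside mask don't dilute

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="no object to measure"):
            measure_cell(
                IntensityImage(np.ones((5, 5))),
                SegmentationMask(np.zeros((5, 5), bool)),
                "c",
            )


def _three_square_scene():
    """Noiseless scene with three bright 12x12 'cells' on dark background."""
    img = np.full((96, 96), 20.0)
    centers = [(20, 20), (48, 70), (75, 30)]
    for cx, cy in centers:
        img[cy - 6 : cy + 6, cx - 6 : cx + 6] = 200.0
    image = IntensityImage(img, 0.3)
    ann = AnnotationSet(
        96,
        96,
        (
            # foreground through the cell, background right alongside it
            Polyline("foreground", [[15, 20], [25, 20]]),
            Polyline("background", [[8, 28], [36, 28]]),
        ),
    )
    rois = [
        CellROI(f"cell{i}", center=c, side=30, animal_id="a0", condition="scar")
        for i, c in enumerate(centers)
    ]
    return image, ann, rois


class TestRunPipeline:
    def test_three_cells_measured_close_to_ground_truth(self, tmp_path):
        image, ann, rois = _three_square_scene()
        model = train_classifier([(image, ann)])
        result = run_pipeline(image, rois, model, out_dir=tmp_path)
        assert len(result.records) == 3 and not result.failures
        truth_area = 144 * 0.09
        for rec in result.records:
            assert abs(rec.area_um2 - truth_area) / truth_area < 0.15
        table = read_measurements(tmp_path / "measurements.csv")
        assert len(table) == 3

    def test_empty_roi_list(self, tmp_path):
        image, ann, _ = _three_square_scene()
        model = train_classifier([(image, ann)])
        result = run_pipeline(image, [], model, out_dir=tmp_path)
        assert result.records == []
        csv = (tmp_path / "measurements.csv").read_text().strip().splitlines()
        assert len(csv) == 1

    def test_background_roi_reported_failed_others_unaffected(self):
        image, ann, rois = _three_square_scene()
        model = train_classifier([(image, ann)])
        bg_roi = CellROI("bg", center=(70, 75), side=16)
        result = run_pipeline(image, rois + [bg_roi], model, min_area_px=30)
        assert len(result.records) == 3
        assert [f.cell_id for f in result.failures] == ["bg"]
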