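"""Image pipeline stages: stretch, segmentation, filters, measurement."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from comphet import image_quant as iq
from comphet import synthetic_data as sd


def _seg_from_areas(areas):
    """A SegmentationResult with synthetic objects of the given areas."""
    objects = [
        iq.SegObject(label=i + 1, area=float(a), centroid_x=0.0, centroid_y=0.0, bbox=(0, 0, 1, 1))
        for i, a in enumerate(areas)
    ]
    # a label map in which each object owns one strip of pixels
    label_map = np.zeros((1, len(areas)), dtype=np.int32)
    label_map[0, :] = np.arange(1, len(areas) + 1)
    return iq.SegmentationResult(label_map=label_map, objects=objects)


class TestContrastStretch:
    def test_uniform_values_map_to_unit_interval(self):
        img = np.arange(100).reshape(10, 10)
        out = iq.contrast_stretch(img)
        # p98 of 0..99 is 97.02 under linear interpolation; 98 clips to 1.0
        assert out.flat[98] == 1.0
        assert out.flat[1] == 0.0
        assert out.min() == 0.0 and out.max() == 1.0

    def test_constant_image_warns_and_zeroes(self):
        with pytest.warns(UserWarning, match="degenerate"):
            out = iq.contrast_stretch(np.full((20, 20), 7))
        assert np.all(out == 0)

    @given(a=st.floats(0.5, 20.0), b=st.floats(-50.0, 50.0))
    def test_affine_invariance(self, a, b):
        rng = np.random.default_rng(0)
        img = rng.integers(0, 1000, (30, 30)).astype(float)
        np.testing.assert_allclose(
            iq.contrast_stretch(img), iq.contrast_stretch(a * img + b), atol=1e-9
        )


class TestCentralRoiFilter:
    def test_center_retained_corner_excluded(self):
        seg = iq.SegmentationResult(
            label_map=np.zeros((100, 100), dtype=np.int32),
            objects=[
                iq.SegObject(1, 10.0, 50.0, 50.0, (0, 0, 1, 1)),  # exact center
                iq.SegObject(2, 10.0, 0.0, 0.0, (0, 0, 1, 1)),  # corner
            ],
        )
        out = iq.central_roi_filter(seg, 100, 100)
        assert [o.label for o in out.objects] == [1]

    def test_uniform_centroids_retain_pi_over_4(self):
        # geometric oracle: circle radius 0.5*side over a unit square
        rng = np.random.default_rng(42)
        n = 1000
        xs, ys = rng.uniform(0, 100, n), rng.uniform(0, 100, n)
        seg = iq.SegmentationResult(
            label_map=np.zeros((100, 100), dtype=np.int32),
            objects=[
                iq.SegObject(i + 1, 1.0, float(x), float(y), (0, 0, 1, 1))
                for i, (x, y) in enumerate(zip(xs, ys))
            ],
        )
        out = iq.central_roi_filter(seg, 100, 100, fraction=0.5)
        frac = len(out.objects) / n
        assert frac == pytest.approx(np.pi / 4, abs=3 * np.sqrt(0.785 * 0.215 / n))


class TestFilterSmallObjects:
    def test_floor_rule_1000_objects(self):
        seg = _seg_from_areas(np.arange(1, 1001, dtype=float))
        out = iq.filter_small_objects(seg, 0.03)
        assert out.n_objects == 970
        assert min(o.area for o in out.objects) == 31.0

    def test_rounding_edge_removes_none(self):
        seg = _seg_from_areas(np.arange(1, 11, dtype=float))
        out = iq.filter_small_objects(seg, 0.03)  # floor(0.3) = 0
        assert out.n_objects == 10

    def test_equal_areas_tie_break_by_label(self):
        seg = _seg_from_areas(np.full(100, 5.0))
        out = iq.filter_small_objects(seg, 0.03)
        assert out.n_objects == 97
        assert [o.label for o in out.objects] == list(range(4, 101))

    def test_conservation_and_order(self):
        rng = np.random.default_rng(1)
        areas = rng.uniform(1, 100, 57)
        seg = _seg_from_areas(areas)
        out = iq.filter_small_objects(seg, 0.1)
        n_removed = seg.n_objects - out.n_objects
        assert n_removed == int(np.floor(0.1 * 57))
        removed = set(seg.labels()) - set(out.labels())
        max_removed = max(areas[l - 1] for l in removed)
        assert max_removed <= min(o.area for o in out.objects)
        # removed labels vanish from the label map too
        assert not np.isin(out.label_map, list(removed)).any()


class TestSegmentation:
    def test_fifty_disks_recovered(self, rendered_field):
        img, mask, gt = rendered_field
        seg = iq.segment_cells(iq.contrast_stretch(img))
        match = sd.match_to_ground_truth(mask, seg)
        assert match["n_detected"] == 50
        assert match["n_spurious"] == 0

    def test_two_disks_areas(self):
        # field small enough that cell pixels exceed the 2% stretch tail
        geom = sd.FieldGeometry(n_cells=2, width=96, height=96, cell_radius_mean=7, cell_radius_sd=0)
        img, mask, gt = sd.render_field(geom, [400.0, 600.0], sd.NoiseModel(False, 0.0), seed=5)
        seg = iq.segment_cells(iq.contrast_stretch(img))
        assert seg.n_objects == 2
        for o in seg.objects:
            assert o.area == pytest.approx(np.pi * 7**2, rel=0.15)

    def test_blank_field_empty(self):
        with pytest.warns(UserWarning):
            stretched = iq.contrast_stretch(np.full((64, 64), 100))
        seg = iq.segment_cells(stretched)
        assert seg.n_objects == 0

    def test_unknown_method_lists_registered(self):
        with pytest.raises(ValueError, match="classical"):
            iq.segment_cells(np.zeros((32, 32)), method="nope")

    def test_adapter_seam(self):
        def oracle_segmenter(stretched):
            lm = np.zeros(stretched.shape, dtype=np.int32)
            lm[2:6, 2:6] = 1
            return lm

        iq.register_segmenter("oracle", oracle_segmenter)
        seg = iq.segment_cells(np.zeros((32, 32)), method="oracle")
        assert seg.n_objects == 1 and seg.objects[0].area == 16


class TestMeasurement:
    def test_constant_image(self):
        seg = iq.segment_cells(np.zeros((16, 16)))  # empty
        lm = np.zeros((16, 16), dtype=np.int32)
        lm[2:5, 2:5] = 1
        lm[10:12, 10:12] = 2
        seg = iq.SegmentationResult(lm, iq._objects_from_labels(lm))
        means = iq.measure_intensities(np.full((16, 16), 7.0), seg)
        assert means == {1: 7.0, 2: 7.0}

    def test_disk_on_background(self):
        img = np.full((32, 32), 10.0)
        lm = np.zeros((32, 32), dtype=np.int32)
        lm[8:16, 8:16] = 1
        img[lm == 1] = 100.0
        seg = iq.SegmentationResult(lm, iq._objects_from_labels(lm))
        assert iq.measure_intensities(img, seg)[1] == 100.0

    def test_shape_mismatch_errors(self):
        lm = np.zeros((8, 8), dtype=np.int32)
        seg = iq.SegmentationResult(lm, [])
        with pytest.raises(ValueError, match="shape"):
            iq.measure_intensities(np.zeros((9, 9)), seg)

    def test_measurement_purity_under_stretch_change(self, rendered_field):
        """Means on the raw image do not depend on the stretch percentiles."""
        img, _, _ = rendered_field
        seg = iq.segment_cells(iq.contrast_stretch(img, 2, 98))
        m1 = iq.measure_intensities(img, seg)
        m2 = iq.measure_intensities(img, seg)  # same masks, raw unchanged
        assert m1 == m2


class TestNormalizePerImage:
    def _records(self, intensities):
        return [
            iq.CellRecord("img", i + 1, 10.0, 0.0, 0.0, float(v))
            for i, v in enumerate(intensities)
        ]

    def test_linear_scaling(self):
        out = iq.normalize_per_image(self._records([10, 20, 30]))
        assert [r.relative_intensity for r in out] == [0.0, 50.0, 100.0]

    def test_single_cell_warns_zero(self):
        with pytest.warns(UserWarning):
            out = iq.normalize_per_image(self._records([42]))
        assert out[0].relative_intensity == 0.0

    def test_affine_shift_invariance(self):
        a = iq.normalize_per_image(self._records([10, 25, 30, 70]))
        b = iq.normalize_per_image(self._records([110, 125, 130, 170]))
        np.testing.assert_allclose(
            [r.relative_intensity for r in a], [r.relative_intensity for r in b]
        )

    def test_empty_input_empty_output(self):
        assert iq.normalize_per_image([]) == []


class TestQuantifyImage:
    def test_composition_counts(self, rendered_field):
        img, mask, gt = rendered_field
        records = iq.quantify_image(img, source_id="f0")
        # 50 truth cells; floor(3% of segmented) removed, ROI may drop edge cells
        assert 30 <= len(records) <= 50
        assert all(0 <= r.relative_intensity <= 100 for r in records)

    def test_intensity_rank_recovery(self, rendered_field):
        img, mask, gt = rendered_field
        seg = iq.segment_cells(iq.contrast_stretch(img))
        match = sd.match_to_ground_truth(mask, seg)
        means = iq.measure_intensities(img, seg)
        truth = {c.label: c.intensity for c in gt.cells}
        t = [truth[g] for g, _ in match["pairs"]]
        m = [means[p] for _, p in match["pairs"]]
        assert stats.spearmanr(t, m).statistic >= 0.95

    def test_gradient_background_tolerated(self, mixture):
        """A tilted background widens identical-truth intensities by at most
        the gradient span relative to a flat-background field."""
        spreads = {}
        for grad in (0.0, 0.05):
            geom = sd.FieldGeometry(n_cells=40, background_gradient=grad)
            img, _, _ = sd.render_field(
                geom, np.full(40, 500.0), sd.NoiseModel(), seed=7
            )
            raw = np.array(
                [r.mean_raw_intensity for r in iq.quantify_image(img)]
            )
            assert raw.size >= 30
            spreads[grad] = raw.max() - raw.min()
        assert spreads[0.05] <= spreads[0.0] + 0.05 * 384 + 5

    def test_blank_image_empty_records(self):
        with pytest.warns(UserWarning):
            records = iq.quantify_image(np.full((64, 64), 100, dtype=np.uint16))
        assert records == []
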