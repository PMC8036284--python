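"""The four feature measurements and their ordinal binning."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pculfdg import (
    BinningConfig,
    PipelineConfig,
    bin_to_scales,
    build_contour_tree,
    extract_raw_features,
    max_contour_size,
    max_shift,
    nesting_degree,
    read_feature_table,
    shape_change,
)
from pculfdg.contours import SliceImage, normalize
from pculfdg.features import RawFeatures, bin_cohort, tercile_thresholds

from conftest import gaussian_image


def tree(img, levels=8):
    return build_contour_tree(img, levels=levels)


def pixel_image(pixels, value=0.9, shape=(16, 16)):
    v = np.zeros(shape)
    for p in pixels:
        v[p] = value
    return SliceImage(v)


class TestNestingDegree:
    def test_empty_trees_give_zero(self):
        flat = tree(SliceImage(np.zeros((10, 10))))
        assert nesting_degree([flat, flat]) == 0

    def test_highest_slice_wins(self):
        shallow = tree(gaussian_image(sigma=6.0, peak=0.30))  # 2 bands
        deep = tree(gaussian_image(sigma=6.0, peak=0.60))  # 4 bands
        assert nesting_degree([shallow, deep, shallow]) == 4

    def test_chain_of_four_components(self):
        assert tree(gaussian_image(sigma=6.0, peak=0.55)).depth() == 4


class TestShapeChange:
    def test_identical_slices_give_zero(self):
        t = tree(gaussian_image(sigma=5.0))
        assert shape_change([t, t, t]) == 0.0

    def test_centroid_aligned_disjoint_masks_give_one(self):
        a = tree(pixel_image([(5, 5), (6, 6)]))
        b = tree(pixel_image([(5, 6), (6, 5)]))
        assert shape_change([a, b]) == 1.0

    def test_single_usable_slice_is_undefined(self):
        t = tree(gaussian_image(sigma=5.0))
        flat = tree(SliceImage(np.zeros((10, 10))))
        assert shape_change([t, flat]) is None

    def test_circle_to_ellipse_matches_pixel_count_oracle(self):
        """Equal-area circle vs 2:1 ellipse: the measured value equals the
        brute-force rasterised overlap of the outer masks."""
        r = np.arange(60)[:, None] - 30.0
        c = np.arange(60)[None, :] - 30.0
        circle = SliceImage((r**2 + c**2 <= 12.0**2) * 0.9)
        ellipse = SliceImage(((r / np.sqrt(2)) ** 2 + (c * np.sqrt(2) / 2) ** 2 <= 72.0) * 0.9)
        ta, tb = tree(circle), tree(ellipse)
        got = shape_change([ta, tb])

        ma = ta.outer_component_of_max().mask
        mb = tb.outer_component_of_max().mask
        pa = {(r, c) for r, c in zip(*np.nonzero(ma))}
        ar, ac = np.nonzero(ma)[0].mean(), np.nonzero(ma)[1].mean()
        br, bc = np.nonzero(mb)[0].mean(), np.nonzero(mb)[1].mean()
        dr, dc = round(ar - br), round(ac - bc)
        pb = {(r + dr, c + dc) for r, c in zip(*np.nonzero(mb))}
        oracle = 1.0 - len(pa & pb) / len(pa | pb)
        assert got == pytest.approx(oracle, abs=1e-12)


class TestMaxShift:
    def test_static_phantom_has_negligible_shift(self, static_phantom):
        raw = extract_raw_features(static_phantom, PipelineConfig())
        assert raw.max_shift == pytest.approx(0.0, abs=0.1)

    def test_known_drift_against_equivalent_radius(self):
        """8 mm jump with a ~10 mm outer radius gives a shift near 0.8."""
        sigma = 10.0 / np.sqrt(2 * np.log(8))  # outer contour radius 10 mm
        a = tree(gaussian_image(shape=(64, 64), center=(32.0, 26.0), sigma=sigma))
        b = tree(gaussian_image(shape=(64, 64), center=(32.0, 34.0), sigma=sigma))
        assert max_shift([a, b]) == pytest.approx(0.8, rel=0.15)

    def test_alternating_dominance_matches_argmax_oracle(self):
        """Two foci 12 mm apart with alternating dominance: the shift
        equals the exhaustive per-slice argmax displacement (within a
        pixel) over the equivalent radius."""
        def two_focus(amp_left, amp_right):
            img = gaussian_image(shape=(60, 60), center=(30.0, 24.0), sigma=4.0, peak=amp_left)
            img.values += gaussian_image(
                shape=(60, 60), center=(30.0, 36.0), sigma=4.0, peak=amp_right
            ).values
            return normalize(img)

        images = [two_focus(1.0, 0.7), two_focus(0.7, 1.0), two_focus(1.0, 0.7)]
        trees = [tree(im) for im in images]
        got = max_shift(trees)

        argmaxes = [
            np.unravel_index(int(np.argmax(im.values)), im.values.shape)
            for im in images
        ]
        disp = max(
            np.hypot(p[0] - q[0], p[1] - q[1])
            for p, q in zip(argmaxes, argmaxes[1:])
        )
        area = max(t.outer_component_of_max().area_mm2 for t in trees)
        radius = np.sqrt(area / np.pi)
        assert disp == pytest.approx(12.0, abs=1.5)
        assert got == pytest.approx(disp / radius, abs=2.0 / radius)


class TestMaxContourSize:
    def test_peak_inside_plateau_reports_plateau_area(self):
        v = np.zeros((20, 20))
        v[5:15, 5:15] = 0.9  # 100-pixel plateau
        v[10, 10] = 1.0
        assert max_contour_size([tree(SliceImage(v))]) == 100.0

    def test_empty_trees_give_zero(self):
        assert max_contour_size([tree(SliceImage(np.zeros((10, 10))))]) == 0.0

    def test_gaussian_innermost_area_matches_bruteforce(self):
        img = gaussian_image(sigma=4.0)
        t = tree(img, levels=8)
        brute = int(np.sum(img.values >= 7 / 8))
        assert max_contour_size([t]) == brute


class TestBinning:
    @pytest.mark.parametrize(
        "depth, score", [(0, 1), (1, 1), (2, 2), (3, 3), (4, 4), (7, 4)]
    )
    def test_nesting_scale(self, depth, score):
        raw = RawFeatures(depth, 0.0, 0.0, 10.0)
        rec = bin_to_scales(raw, BinningConfig(v4_mode="fixed"))
        assert rec.v1 == score

    def test_zero_shape_change_scores_one(self):
        rec = bin_to_scales(RawFeatures(1, 0.0, 0.0, 1.0), BinningConfig(v4_mode="fixed"))
        assert rec.v2 == 1

    def test_undefined_measurements_score_one_with_warning(self):
        raw = RawFeatures(2, None, None, 5.0)
        with pytest.warns(UserWarning, match="undefined"):
            rec = bin_to_scales(raw, BinningConfig(v4_mode="fixed"))
        assert (rec.v2, rec.v3) == (1, 1)

    @given(
        a=st.floats(min_value=0, max_value=1),
        b=st.floats(min_value=0, max_value=1),
    )
    @settings(max_examples=60, deadline=None)
    def test_binning_is_monotone(self, a, b):
        lo, hi = sorted([a, b])
        cfg = BinningConfig(v4_mode="fixed")
        ra = bin_to_scales(RawFeatures(1, lo, lo, 1.0), cfg)
        rb = bin_to_scales(RawFeatures(1, hi, hi, 1.0), cfg)
        assert ra.v2 <= rb.v2 and ra.v3 <= rb.v3

    def test_cohort_terciles_split_small_medium_large(self):
        raws = {
            f"n{i}": RawFeatures(1, 0.0, 0.0, float(area))
            for i, area in enumerate([5, 6, 7, 50, 55, 60, 200, 210, 220])
        }
        records = bin_cohort(raws)
        v4 = [r.v4 for r in records]
        assert v4 == [1, 1, 1, 2, 2, 2, 3, 3, 3]

    def test_tercile_thresholds_need_data(self):
        with pytest.raises(ValueError):
            tercile_thresholds([])


class TestFeatureTable:
    def test_round_trip_valid_rows(self, tmp_path):
        path = tmp_path / "f.csv"
        path.write_text(
            "nodule_id,v1,v2,v3,v4,label\nn1,4,3,3,2,malignant\nn2,1,1,2,1,benign\n"
        )
        records = read_feature_table(path)
        assert [r.values for r in records] == [(4, 3, 3, 2), (1, 1, 2, 1)]
        assert records[0].label == "malignant"

    def test_out_of_scale_row_reports_line_number(self, tmp_path):
        path = tmp_path / "f.csv"
        path.write_text("nodule_id,v1,v2,v3,v4\nn1,5,1,1,1\n")
        with pytest.raises(ValueError, match="line 2"):
            read_feature_table(path)

    def test_empty_file_gives_empty_list(self, tmp_path):
        path = tmp_path / "f.csv"
        path.write_text("")
        assert read_feature_table(path) == []


class TestTranslationInvariance:
    def test_common_shift_leaves_both_motion_features_unchanged(self, drift_phantom):
        """Rigid in-plane displacement of every slice (respiratory-motion
        surrogate) moves the whole structure without distorting it: shape
        change and max shift are unaffected."""
        cfg = PipelineConfig()
        base = extract_raw_features(drift_phantom, cfg)

        shifted_activity = np.roll(drift_phantom.activity, (4, 6), axis=(1, 2))
        from pculfdg import PETSeries

        shifted = PETSeries(
            activity=shifted_activity,
            in_plane_spacing_mm=drift_phantom.in_plane_spacing_mm,
            slice_thickness_mm=drift_phantom.slice_thickness_mm,
            injected_activity_mCi=drift_phantom.injected_activity_mCi,
            body_weight_kg=drift_phantom.body_weight_kg,
        )
        moved = extract_raw_features(shifted, cfg)
        assert moved.shape_change == pytest.approx(base.shape_change, abs=0.02)
        assert moved.max_shift == pytest.approx(base.max_shift, abs=0.05)
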