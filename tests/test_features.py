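"""Descriptors, ellipse fitting and sliding-window variances."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from falldetect.features import (
    FEATURE_NAMES,
    FrameDescriptor,
    WindowConfig,
    aspect_ratio,
    build_feature_vectors,
    compute_descriptors,
    ellipse_ratio,
    fit_ellipse,
    geometric_center,
    motion_magnitude,
    person_angle,
    temporal_variance,
    upper_half_area,
)
from falldetect.foreground import SegmentationParams, extract_person_blob, segment_sequence
from falldetect.synthetic import ScenarioSpec, rasterize_ellipse, simulate_sequence

LOOSE = SegmentationParams(min_person_size=1)


def blob_from_mask(mask):
    return extract_person_blob(mask, LOOSE)


def rect_blob(w, h, shape=(100, 100), at=(20, 20)):
    mask = np.zeros(shape, dtype=bool)
    mask[at[0] : at[0] + h, at[1] : at[1] + w] = True
    return blob_from_mask(mask)


class TestFitEllipse:
    def test_vertical_rectangle(self):
        fit = fit_ellipse(rect_blob(20, 60))
        assert fit.theta == pytest.approx(90.0)
        assert fit.major_len / fit.minor_len == pytest.approx(3.0, rel=0.01)

    def test_disk_is_isotropic_with_vertical_convention(self):
        mask = rasterize_ellipse((80, 80), (40, 40), 25, 25, 0.0)
        fit = fit_ellipse(blob_from_mask(mask))
        assert fit.theta == 90.0
        assert fit.major_len / fit.minor_len == pytest.approx(1.0, rel=0.01)

    @pytest.mark.parametrize("angle", [10.0, 30.0, 55.0, 80.0])
    @pytest.mark.parametrize("ratio", [1.5, 2.67, 4.0])
    def test_recovers_rasterizer_parameters(self, angle, ratio):
        b = 15.0
        mask = rasterize_ellipse((220, 220), (110, 110), b * ratio, b, angle)
        fit = fit_ellipse(blob_from_mask(mask))
        assert fit.theta == pytest.approx(angle, abs=2.0)
        assert fit.major_len / fit.minor_len == pytest.approx(ratio, rel=0.05)

    def test_degenerate_blob_clamps_minor_axis(self):
        mask = np.zeros((30, 30), dtype=bool)
        mask[10, 5:25] = True  # collinear pixels
        fit = fit_ellipse(blob_from_mask(mask))
        assert fit.minor_len == 1.0
        assert fit.theta == pytest.approx(0.0)

    def test_too_small_blob_raises(self):
        mask = np.zeros((10, 10), dtype=bool)
        mask[2, 2:5] = True
        with pytest.raises(ValueError):
            fit_ellipse(blob_from_mask(mask))


class TestAngleAndRatio:
    def test_person_angle_vertical_and_horizontal(self):
        assert person_angle(fit_ellipse(rect_blob(10, 40))) == pytest.approx(90.0)
        assert person_angle(fit_ellipse(rect_blob(40, 10))) == pytest.approx(0.0)

    def test_oriented_ratio_flips_under_rotation(self):
        standing = fit_ellipse(
            blob_from_mask(rasterize_ellipse((100, 100), (50, 50), 30, 10, 90.0))
        )
        lying = fit_ellipse(
            blob_from_mask(rasterize_ellipse((100, 100), (50, 50), 30, 10, 0.0))
        )
        er_stand = ellipse_ratio(standing)
        er_lie = ellipse_ratio(lying)
        assert er_stand == pytest.approx(3.0, rel=0.05)
        assert er_lie == pytest.approx(1 / 3, rel=0.05)
        assert er_lie == pytest.approx(1.0 / er_stand, rel=0.01)

    def test_disk_ratio_is_one(self):
        fit = fit_ellipse(
            blob_from_mask(rasterize_ellipse((80, 80), (40, 40), 22, 22, 0.0))
        )
        assert ellipse_ratio(fit) == pytest.approx(1.0, rel=0.01)

    def test_strict_ratio_always_at_least_one(self):
        lying = fit_ellipse(
            blob_from_mask(rasterize_ellipse((100, 100), (50, 50), 30, 10, 0.0))
        )
        assert ellipse_ratio(lying, oriented=False) >= 1.0

    def test_aspect_ratio_reciprocal_under_rotation(self):
        assert aspect_ratio(rect_blob(12, 48)) == pytest.approx(
            1.0 / aspect_ratio(rect_blob(48, 12))
        )


class TestUpperHalfArea:
    def test_solid_rectangle_splits_evenly(self):
        assert upper_half_area(rect_blob(20, 40)) == 20 * 20

    def test_odd_height_upper_half_gets_extra_row(self):
        assert upper_half_area(rect_blob(10, 41)) == 10 * 21

    def test_top_heavy_shape_exceeds_half(self):
        mask = np.zeros((60, 60), dtype=bool)
        mask[10:20, 10:40] = True  # wide top bar
        mask[20:40, 22:28] = True  # narrow stem
        blob = blob_from_mask(mask)
        assert upper_half_area(blob) > blob.area / 2

    def test_matches_row_by_row_bruteforce(self):
        rng = np.random.default_rng(6)
        from scipy import ndimage as ndi

        mask = ndi.binary_dilation(rng.random((40, 40)) > 0.9, iterations=2)
        blob = blob_from_mask(mask)
        x, y, w, h = blob.bbox
        count = 0
        for row in range(y, y + math.ceil(h / 2)):
            for col in range(x, x + w):
                count += bool(blob.mask[row, col])
        assert upper_half_area(blob) == count


class TestGeometricCenter:
    def test_single_pixel_blob(self):
        mask = np.zeros((10, 10), dtype=bool)
        mask[4, 7] = True
        assert geometric_center(blob_from_mask(mask)) == (7.0, 4.0)

    def test_centered_square(self):
        blob = rect_blob(21, 21, at=(30, 30))
        assert geometric_center(blob) == (40.0, 40.0)

    def test_matches_boundary_trace_bruteforce(self):
        rng = np.random.default_rng(7)
        from scipy import ndimage as ndi

        mask = ndi.binary_dilation(rng.random((30, 30)) > 0.9, iterations=2)
        blob = blob_from_mask(mask)
        pts = []
        H, W = blob.mask.shape
        for yy in range(H):
            for xx in range(W):
                if not blob.mask[yy, xx]:
                    continue
                nbrs = [
                    (yy + dy, xx + dx) for dy, dx in ((1, 0), (-1, 0), (0, 1), (0, -1))
                ]
                if any(
                    not (0 <= ny < H and 0 <= nx < W) or not blob.mask[ny, nx]
                    for ny, nx in nbrs
                ):
                    pts.append((xx, yy))
        ex = np.mean([p[0] for p in pts])
        ey = np.mean([p[1] for p in pts])
        assert geometric_center(blob) == pytest.approx((ex, ey))


class TestMotion:
    def test_three_four_five(self):
        assert motion_magnitude((0, 0), (3, 4)) == 5.0

    def test_zero_displacement(self):
        assert motion_magnitude((2.5, 7.0), (2.5, 7.0)) == 0.0

    @given(
        st.tuples(
            st.floats(-1e3, 1e3), st.floats(-1e3, 1e3),
            st.floats(-1e3, 1e3), st.floats(-1e3, 1e3),
        )
    )
    def test_matches_hypot(self, p):
        x0, y0, x1, y1 = p
        assert motion_magnitude((x0, y0), (x1, y1)) == pytest.approx(
            math.hypot(x1 - x0, y1 - y0), abs=1e-12
        )


class TestTemporalVariance:
    def test_constant_series_is_exactly_zero(self):
        assert temporal_variance([0.1] * 30, 30) == 0.0

    def test_arithmetic_series_closed_form(self):
        assert temporal_variance(np.arange(1, 31), 30) == pytest.approx(
            (30**2 - 1) / 12, abs=1e-9
        )

    def test_uses_only_trailing_window(self):
        series = [100.0] * 10 + [1.0, 2.0, 3.0]
        assert temporal_variance(series, 3) == pytest.approx(2.0 / 3.0)

    def test_short_series_raises(self):
        with pytest.raises(ValueError):
            temporal_variance([1.0, 2.0], 5)

    @given(
        st.lists(st.floats(-1e4, 1e4), min_size=5, max_size=40),
        st.floats(-100, 100),
        st.floats(0.1, 10),
    )
    def test_shift_invariance_and_quadratic_scaling(self, values, shift, scale):
        k = min(5, len(values))
        base = temporal_variance(values, k)
        shifted = temporal_variance(np.asarray(values) + shift, k)
        scaled = temporal_variance(np.asarray(values) * scale, k)
        assert base >= 0
        assert shifted == pytest.approx(base, rel=1e-6, abs=1e-6)
        assert scaled == pytest.approx(base * scale**2, rel=1e-6, abs=1e-9)


def make_descriptors(n, **overrides):
    out = []
    for i in range(n):
        d = FrameDescriptor(
            frame_index=i, ar=1.0, pa=90.0, er=2.0, sd=100.0,
            gcx=50.0, gcy=40.0, mv=0.0, valid=True, mv_defined=i > 0,
        )
        for key, series in overrides.items():
            setattr(d, key, series[i])
        out.append(d)
    return out


class TestBuildFeatureVectors:
    def test_identical_descriptors_give_one_zero_vector(self):
        vecs = build_feature_vectors(make_descriptors(30), WindowConfig(k=30))
        assert len(vecs) == 1
        assert vecs[0].frame_index == 29
        assert np.all(vecs[0].as_array() == 0.0)

    def test_window_count_arithmetic(self):
        vecs = build_feature_vectors(make_descriptors(31), WindowConfig(k=30))
        assert [v.frame_index for v in vecs] == [29, 30]

    def test_too_few_frames_raises(self):
        with pytest.raises(ValueError):
            build_feature_vectors(make_descriptors(10), WindowConfig(k=30))

    def test_skip_policy_drops_windows_with_invalid_frames(self):
        descs = make_descriptors(40)
        descs[35].valid = False
        vecs = build_feature_vectors(descs, WindowConfig(k=30, invalid_policy="skip"))
        # windows ending at 35..39 all contain frame 35
        assert [v.frame_index for v in vecs] == list(range(29, 35))

    def test_interpolate_policy_fills_short_gaps(self):
        descs = make_descriptors(40, ar=[1.0 + 0.1 * i for i in range(40)])
        for i in (34, 35):
            descs[i].valid = False
        vecs = build_feature_vectors(
            descs, WindowConfig(k=30, invalid_policy="interpolate")
        )
        assert [v.frame_index for v in vecs] == list(range(29, 40))

    def test_fall_windows_have_larger_variance_than_walking(self, fall_sequence):
        seq, gt = fall_sequence
        blobs = segment_sequence(seq.frames, SegmentationParams(), seq.background)
        descs = compute_descriptors(blobs)
        vecs = build_feature_vectors(descs, WindowConfig(k=30))
        onset = gt.action_onset
        during = [v for v in vecs if onset <= v.frame_index < onset + 15]
        steady = [v for v in vecs if v.frame_index < onset - 5]
        assert during and steady
        for name in ("var_ar", "var_pa"):
            assert max(getattr(v, name) for v in during) > max(
                getattr(v, name) for v in steady
            )

    def test_every_variance_peaks_near_fall_onset(self, fall_sequence):
        seq, gt = fall_sequence
        blobs = segment_sequence(seq.frames, SegmentationParams(), seq.background)
        vecs = build_feature_vectors(compute_descriptors(blobs), WindowConfig(k=30))
        onset = gt.action_onset
        for name in FEATURE_NAMES:
            series = np.array([getattr(v, name) for v in vecs])
            peak_frame = vecs[int(np.argmax(series))].frame_index
            assert abs(peak_frame - onset) <= 30, name


class TestScaleCovariance:
    def test_doubling_dimensions(self):
        small = blob_from_mask(rasterize_ellipse((100, 100), (50, 60), 20, 7, 60.0))
        large = blob_from_mask(rasterize_ellipse((200, 200), (100, 120), 40, 14, 60.0))
        assert upper_half_area(large) == pytest.approx(
            4 * upper_half_area(small), rel=0.05
        )
        gs, gl = geometric_center(small), geometric_center(large)
        assert gl[0] == pytest.approx(2 * gs[0], rel=0.02)
        assert gl[1] == pytest.approx(2 * gs[1], rel=0.02)
        assert motion_magnitude((0, 0), (6, 8)) * 2 == motion_magnitude((0, 0), (12, 16))
        fs, fl = fit_ellipse(small), fit_ellipse(large)
        assert aspect_ratio(large) == pytest.approx(aspect_ratio(small), rel=0.05)
        assert fl.theta == pytest.approx(fs.theta, abs=1.0)
        assert ellipse_ratio(fl) == pytest.approx(ellipse_ratio(fs), rel=0.05)
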