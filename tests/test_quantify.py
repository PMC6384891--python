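"""Intensity normalization, ROI cropping, SD statistic, and histogram QC."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from mshts.quantify import (
    Micrograph,
    NormalizationError,
    QCThresholds,
    ROISpec,
    compute_sd,
    extract_center_roi,
    normalize_intensity,
    percent_sd_trace,
    qc_image,
    read_micrograph,
    well_sd,
)
from mshts.simulate import KineticModel, kinetic_load, render_micrograph


def _micro(arr, bit_depth=8):
    return Micrograph(pixels=np.asarray(arr), bit_depth=bit_depth)


class TestNormalizeIntensity:
    def test_hand_computed_scaling(self):
        # mean 25, target 127.5 -> scale 5.1
        img = normalize_intensity(_micro([[10, 20], [30, 40]]), 0.5)
        np.testing.assert_array_equal(img.pixels, [[51, 102], [153, 204]])

    def test_uniform_image_moves_to_target(self):
        img = normalize_intensity(_micro(np.full((8, 8), 26, dtype=np.uint8)), 0.5)
        assert img.pixels.mean() == pytest.approx(0.5 * 255, abs=1)

    def test_already_at_target_unchanged(self):
        base = np.full((8, 8), 128, dtype=np.uint8)
        img = normalize_intensity(_micro(base), 128 / 255)
        np.testing.assert_array_equal(img.pixels, base)

    def test_all_zero_image_raises(self):
        with pytest.raises(NormalizationError):
            normalize_intensity(_micro(np.zeros((4, 4), dtype=np.uint8)))

    def test_clipping_is_flagged(self):
        arr = np.full((10, 10), 10, dtype=np.uint8)
        arr[0] = 250  # dim field with bright outliers: scaling to mean 50% clips them
        img = normalize_intensity(_micro(arr), 0.5)
        assert img.meta["norm_clipped_fraction"] > 0.005


class TestExtractCenterROI:
    def test_even_margins(self):
        arr = np.arange(36).reshape(6, 6)
        roi = extract_center_roi(_micro(arr), ROISpec(2))
        np.testing.assert_array_equal(roi.pixels, arr[2:4, 2:4])

    def test_identity_when_size_matches(self):
        arr = np.arange(16).reshape(4, 4)
        roi = extract_center_roi(_micro(arr), ROISpec(4))
        np.testing.assert_array_equal(roi.pixels, arr)

    def test_standard_offset_in_large_frame(self):
        img = _micro(np.zeros((1000, 1000), dtype=np.uint8))
        img.pixels[284, 284] = 7  # floor((1000-432)/2) = 284
        roi = extract_center_roi(img, ROISpec(432))
        assert roi.pixels.shape == (432, 432)
        assert roi.pixels[0, 0] == 7

    def test_odd_margin_uses_floor_offset(self):
        arr = np.arange(25).reshape(5, 5)
        roi = extract_center_roi(_micro(arr), ROISpec(2))
        np.testing.assert_array_equal(roi.pixels, arr[1:3, 1:3])

    def test_oversized_roi_rejected(self):
        with pytest.raises(ValueError):
            extract_center_roi(_micro(np.zeros((4, 4), dtype=np.uint8)), ROISpec(5))


class TestComputeSD:
    def test_constant_raster_is_zero(self):
        assert compute_sd(_micro(np.full((4, 4), 9, dtype=np.uint8))) == 0.0

    def test_direct_formula(self):
        assert compute_sd(np.array([1, 2, 3, 4])) == pytest.approx(np.sqrt(1.25))

    def test_shift_invariance_and_scale_equivariance(self):
        arr = np.array([[3, 9], [7, 1]], dtype=np.float64)
        assert compute_sd(arr + 17) == pytest.approx(compute_sd(arr))
        assert compute_sd(arr * 3) == pytest.approx(3 * compute_sd(arr))

    @given(
        hnp.arrays(
            dtype=np.float64,
            shape=hnp.array_shapes(min_dims=2, max_dims=2, min_side=2, max_side=12),
            elements=st.floats(0, 255),
        )
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_matches_two_pass_oracle(self, arr):
        mean = arr.sum() / arr.size
        oracle = np.sqrt(((arr - mean) ** 2).sum() / arr.size)
        assert compute_sd(arr) == pytest.approx(oracle, rel=1e-9, abs=1e-12)


class TestQC:
    def test_saturated_frame_fails_bright(self):
        arr = np.full((50, 50), 255, dtype=np.uint8)
        arr[0, :25] = 10
        assert qc_image(_micro(arr)).verdict == "fail_bright"

    def test_dark_frame_fails_dark(self):
        arr = np.zeros((50, 50), dtype=np.uint8)
        arr[0, 0] = 3
        assert qc_image(_micro(arr)).verdict == "fail_dark"

    def test_gaussian_histogram_passes(self, rng):
        arr = np.clip(rng.normal(128, 20, (100, 100)), 0, 255).astype(np.uint8)
        report = qc_image(_micro(arr))
        assert report.verdict == "pass"
        assert abs(report.skewness) < 0.5

    def test_heavy_tail_fails_nonnormal(self, rng):
        arr = np.clip(rng.normal(100, 5, (100, 100)), 0, 255)
        arr[:10, :10] = 250  # bright speckle block -> skew/kurtosis blow-up
        assert qc_image(_micro(arr.astype(np.uint8))).verdict == "fail_nonnormal"


class TestWellSD:
    def test_simulated_low_load_passes_qc(self, small_params):
        img, _ = render_micrograph(0.0, small_params, seed=1)
        res = well_sd(img, ROISpec(100))
        assert res.qc.verdict == "pass"
        assert res.sd_value > 0

    def test_24h_exceeds_0h_on_simulated_pair(self, small_params):
        img0, _ = render_micrograph(0.0, small_params, seed=2, timepoint=0.0)
        img24, _ = render_micrograph(0.7, small_params, seed=3)
        roi = ROISpec(100)
        assert well_sd(img24, roi).sd_value > well_sd(img0, roi).sd_value

    def test_saturated_input_flagged_but_sd_reported(self):
        arr = np.full((64, 64), 65535, dtype=np.uint16)
        arr[:4] = 30000
        res = well_sd(Micrograph(pixels=arr, bit_depth=16), ROISpec(32))
        assert res.qc.verdict == "fail_bright"
        assert res.sd_value >= 0

    def test_exposure_scaling_invariance(self, small_params):
        # normalization absorbs exposure/gain differences (clip-free scaling)
        rendered, _ = render_micrograph(0.5, small_params, seed=7)
        base = np.rint(rendered.pixels.astype(np.float64) / 2.2).astype(np.uint16)
        img = Micrograph(pixels=base, bit_depth=16)
        roi = ROISpec(100)
        baseline = well_sd(img, roi).sd_value
        for k in (0.5, 0.8, 1.25, 2.0):
            scaled = np.rint(img.pixels.astype(np.float64) * k)
            assert scaled.max() <= img.full_scale, "scaling must stay clip-free"
            res = well_sd(Micrograph(pixels=scaled.astype(np.uint16)), roi)
            assert res.sd_value == pytest.approx(baseline, rel=0.01)

    def test_roi_size_insensitivity_on_simulated_frames(self):
        img, _ = render_micrograph(0.6, seed=13)  # full 432x432 frame
        sds = [well_sd(img, ROISpec(size)).sd_value for size in (216, 324, 432)]
        assert max(sds) / min(sds) < 1.10


class TestPercentSDTrace:
    def test_proportionality(self):
        np.testing.assert_allclose(percent_sd_trace([2, 4, 8]), [25, 50, 100])

    def test_constant_series_is_all_100(self):
        np.testing.assert_allclose(percent_sd_trace([3.3, 3.3]), [100, 100])

    def test_all_zero_series_rejected(self):
        with pytest.raises(ValueError):
            percent_sd_trace([0.0, 0.0])

    def test_tau_reaches_half_max_before_lagged_amyloid(self):
        tau = KineticModel(lag_time=0.0, rate=0.5)
        abeta = KineticModel(lag_time=4.0, rate=0.5)
        t = np.linspace(0, 24, 97)
        trace_tau = percent_sd_trace([kinetic_load(float(x), tau) + 1e-9 for x in t])
        trace_ab = percent_sd_trace([kinetic_load(float(x), abeta) + 1e-9 for x in t])
        t50_tau = t[np.argmax(trace_tau >= 50)]
        t50_ab = t[np.argmax(trace_ab >= 50)]
        assert t50_tau < t50_ab


def test_rgb_tiff_reduced_to_luminance(tmp_path):
    import tifffile

    rgb = np.zeros((16, 16, 3), dtype=np.uint8)
    rgb[..., 0] = 30
    rgb[..., 1] = 60
    rgb[..., 2] = 90
    path = tmp_path / "img.tif"
    tifffile.imwrite(path, rgb)
    micro = read_micrograph(path)
    assert micro.pixels.shape == (16, 16)
    assert micro.pixels[0, 0] == 60
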