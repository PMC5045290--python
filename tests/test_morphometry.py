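"""Feret length, silhouette segmentation, kymographs and tip angles."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import hypoquant as hq
from hypoquant.morphometry import (
    feret_diameter,
    growth_trace,
    line_kymograph,
    segment_mask,
    tip_angle,
)
from hypoquant.series import ImageSeries
from hypoquant.synthdata import render_rod


class TestFeret:
    def test_single_pixel_is_unit_square_diagonal(self):
        mask = np.zeros((5, 5), bool)
        mask[2, 2] = True
        assert feret_diameter(mask) == pytest.approx(np.sqrt(2))

    def test_axis_aligned_rectangle_is_pythagorean(self):
        mask = np.zeros((10, 10), bool)
        mask[3:6, 2:6] = True  # 3 x 4 pixels -> 3-4-5 triangle of corners
        assert feret_diameter(mask) == pytest.approx(5.0)

    @given(seed=st.integers(0, 30))
    def test_matches_bruteforce_oracle_on_random_blobs(self, seed):
        from conftest import feret_bruteforce, random_blob

        mask = random_blob(np.random.default_rng(seed), n_target=100)
        assert feret_diameter(mask) == pytest.approx(feret_bruteforce(mask))

    def test_rotation_by_90_degrees_changes_little(self, blob_factory):
        mask = blob_factory(np.random.default_rng(40), n_target=200)
        d0 = feret_diameter(mask)
        d90 = feret_diameter(np.rot90(mask))
        assert abs(d90 - d0) / d0 < 0.01

    def test_translation_invariance(self, blob_factory):
        mask = blob_factory(np.random.default_rng(41), n_target=80)
        shifted = np.zeros((64, 64), bool)
        shifted[17:49, 9:41] = mask  # translate by (dy=17, dx=9)
        assert feret_diameter(shifted) == feret_diameter(mask)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            feret_diameter(np.zeros((4, 4), bool))


class TestSegmentMask:
    def test_recovers_rod_support_noiselessly(self):
        rod = render_rod((64, 64), (32, 32), 40, 8, 30.0)
        frame = np.where(rod, 200.0, 10.0)
        result = segment_mask(frame, threshold="auto")
        assert np.array_equal(result.mask, rod)

    def test_selection_point_picks_smaller_blob(self):
        frame = np.full((40, 40), 5.0)
        frame[5:25, 5:15] = 100.0   # large blob
        frame[30:34, 30:34] = 100.0  # small blob
        result = segment_mask(frame, threshold=50.0, selection_point=(31, 31))
        assert result.component_policy == "seeded"
        assert result.mask.sum() == 16

    def test_largest_policy_without_seed(self):
        frame = np.full((40, 40), 5.0)
        frame[5:25, 5:15] = 100.0
        frame[30:34, 30:34] = 100.0
        result = segment_mask(frame, threshold=50.0)
        assert result.mask.sum() == 200

    def test_uniform_frame_auto_threshold_rejected(self):
        with pytest.raises(ValueError, match="uniform"):
            segment_mask(np.full((8, 8), 7.0), threshold="auto")

    def test_no_foreground_rejected(self):
        with pytest.raises(ValueError, match="foreground"):
            segment_mask(np.full((8, 8), 7.0), threshold=50.0)


class TestGrowthTrace:
    def test_static_rod_stays_at_100(self):
        cfg = hq.GrowthSeriesConfig(
            growth_rate_pct_per_hr=0.0, length_noise_sd_px=0.0,
            angle_jitter_deg=0.0, n_frames=6,
        )
        series, _ = hq.generate_elongation_series(cfg)
        masks = [segment_mask(series.data[t, 0], "auto")
                 for t in range(series.n_frames)]
        trace = growth_trace(series, masks)
        assert np.allclose(trace.length_pct, 100.0)

    def test_first_point_is_exactly_100(self):
        series, _ = hq.generate_elongation_series(hq.GrowthSeriesConfig(seed=8))
        masks = [segment_mask(series.data[t, 0], "auto")
                 for t in range(series.n_frames)]
        trace = growth_trace(series, masks)
        assert trace.length_pct[0] == 100.0

    def test_tracks_true_length_within_1p5_px(self, noiseless_growth):
        series, truth = noiseless_growth
        masks = [segment_mask(series.data[t, 0], "auto")
                 for t in range(series.n_frames)]
        trace = growth_trace(series, masks)
        assert np.abs(trace.length_px - truth.true_length_series).max() <= 1.5

    def test_percentage_is_calibration_free(self, noiseless_growth):
        series, _ = noiseless_growth
        masks = [segment_mask(series.data[t, 0], "auto")
                 for t in range(series.n_frames)]
        a = growth_trace(series, masks, px_per_mm=50.0)
        b = growth_trace(series, masks, px_per_mm=500.0)
        assert np.array_equal(a.length_pct, b.length_pct)
        assert np.allclose(a.length_mm, 10.0 * b.length_mm)


class TestLineKymograph:
    def _static_series(self):
        rng = np.random.default_rng(3)
        frame = rng.uniform(0, 50, (32, 32))
        return ImageSeries(np.stack([frame] * 4)[:, None])

    def test_static_series_gives_identical_columns(self):
        series = self._static_series()
        kymo = line_kymograph(series, np.array([[2.0, 5.0], [29.0, 20.0]]))
        assert np.allclose(kymo, kymo[:, [0]])

    def test_width_averaging_identity_on_uniform_transverse_profile(self):
        frames = np.tile(np.linspace(0, 10, 32)[None, None, :, None], (3, 1, 1, 32))
        series = ImageSeries(frames)
        line = np.array([[10.0, 4.0], [10.0, 28.0]])  # vertical line
        k1 = line_kymograph(series, line, width_px=1)
        k3 = line_kymograph(series, line, width_px=3)
        assert np.allclose(k1, k3)

    def test_zero_length_polyline_rejected(self):
        series = self._static_series()
        with pytest.raises(ValueError, match="zero length"):
            line_kymograph(series, np.array([[4.0, 4.0], [4.0, 4.0]]))

    def test_advancing_tip_slope_matches_speed(self):
        # rod tip advancing 3 px/frame along the sampling line
        h = w = 64
        frames = []
        for t in range(6):
            m = render_rod((h, w), (20 + 1.5 * t, 32.0), 30 + 3 * t, 7, 0.0)
            frames.append(np.where(m, 100.0, 0.0))
        series = ImageSeries(np.stack(frames)[:, None])
        kymo = line_kymograph(series, np.array([[2.0, 32.0], [61.0, 32.0]]))
        edges = [np.max(np.nonzero(kymo[:, t] > 50.0)[0]) for t in range(6)]
        slope = np.polyfit(np.arange(6), edges, 1)[0]
        assert slope == pytest.approx(3.0, abs=0.3)


class TestTipAngle:
    def test_vertical_rod_is_90(self):
        rod = render_rod((64, 64), (32, 32), 40, 7, 90.0)
        assert tip_angle(rod) == pytest.approx(90.0, abs=1.0)

    def test_horizontal_rod_is_0(self):
        rod = render_rod((64, 64), (32, 32), 40, 7, 0.0)
        assert tip_angle(rod) == pytest.approx(0.0, abs=1.0)

    @pytest.mark.parametrize("angle", range(-80, 81, 20))
    def test_recovers_rendered_angle_within_2_degrees(self, angle):
        length, width = 120.0, 7.0
        center = (80.0, 80.0)
        rod = render_rod((160, 160), center, length, width, float(angle))
        a = np.radians(angle)
        base = (center[0] - length / 2 * np.cos(a),
                center[1] + length / 2 * np.sin(a))
        assert tip_angle(rod, base_point=base) == pytest.approx(
            float(angle), abs=2.0
        )

    def test_closed_curve_rejected(self):
        mask = np.zeros((32, 32), bool)
        mask[8:24, 8:24] = True
        mask[12:20, 12:20] = False  # annulus -> closed skeleton
        with pytest.raises(ValueError, match="free end"):
            tip_angle(mask)
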