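"""Generator contracts: closed-form brightness, schedules, determinism."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import hypoquant as hq
from hypoquant.synthdata import (
    generate_bending_series,
    generate_luminescence_trace,
    luminescence_stack,
    ph_schedule,
    quench_fraction,
    render_rod,
)


class TestQuenchModel:
    def test_midpoint_is_half(self):
        assert quench_fraction(6.0, pka=6.0) == pytest.approx(0.5)

    @given(
        ph_lo=st.floats(3.0, 8.0),
        delta=st.floats(0.01, 3.0),
        pka=st.floats(4.0, 8.0),
    )
    def test_strictly_increasing_in_ph(self, ph_lo, delta, pka):
        assert quench_fraction(ph_lo + delta, pka) > quench_fraction(ph_lo, pka)

    def test_closed_form_brightness_values(self):
        # B(6.4) and B(5.4) at pKa 6.0, evaluated analytically
        assert quench_fraction(6.4, 6.0) == pytest.approx(0.7153, abs=1e-4)
        assert quench_fraction(5.4, 6.0) == pytest.approx(0.2008, abs=1e-4)


class TestPHSeries:
    def test_frame_median_matches_closed_form(self):
        cfg = hq.PHSeriesConfig(
            pka=6.0, ph_initial=6.4, ph_final=5.4, onset_min=20.0,
            tau_min=5.0, noise_sd=0.0, n_frames=13,
        )
        series, _ = hq.generate_ph_series(cfg)
        mask = hq.wall_mask(series, 100.0)
        summary = hq.frame_summary(hq.pixel_ratios(series, mask))
        assert summary["median"][0] == pytest.approx(0.7153, abs=1e-4)
        # 40 min past onset = 8 time constants: at the plateau value
        assert summary["median"].iloc[-1] == pytest.approx(0.2008, abs=1e-3)

    def test_constant_ph_gives_constant_median(self):
        cfg = hq.PHSeriesConfig(ph_initial=6.0, ph_final=6.0, noise_sd=0.0)
        series, _ = hq.generate_ph_series(cfg)
        mask = hq.wall_mask(series, 100.0)
        medians = hq.frame_summary(hq.pixel_ratios(series, mask))["median"]
        assert np.allclose(medians, medians[0])

    def test_schedule_flat_before_onset_then_decays(self):
        cfg = hq.PHSeriesConfig()
        t = np.array([0.0, 10.0, 19.9, 20.0, 50.0, 1e6])
        ph = ph_schedule(t, cfg)
        assert np.all(ph[:3] == cfg.ph_initial)
        assert ph[3] == cfg.ph_initial  # continuous at onset
        assert cfg.ph_final < ph[4] < cfg.ph_initial
        assert ph[5] == pytest.approx(cfg.ph_final)

    def test_seed_determinism(self):
        a, _ = hq.generate_ph_series(hq.PHSeriesConfig(seed=7))
        b, _ = hq.generate_ph_series(hq.PHSeriesConfig(seed=7))
        assert np.array_equal(a.data, b.data)

    def test_reference_channel_is_ph_independent(self, noiseless_ph):
        series, _ = noiseless_ph
        assert np.array_equal(series.ref[0], series.ref[-1])

    @pytest.mark.parametrize(
        "patch,field",
        [
            ({"ph_final": 7.0}, "ph_final"),
            ({"onset_min": 1e6}, "onset_min"),
            ({"noise_sd": -1.0}, "noise_sd"),
            ({"wall_width_px": 99}, "wall_width_px"),
        ],
    )
    def test_validation_names_offending_field(self, patch, field):
        cfg = hq.PHSeriesConfig(**patch)
        with pytest.raises(ValueError, match=field):
            hq.generate_ph_series(cfg)

    def test_lattice_matches_ground_truth_support(self, noiseless_ph):
        series, truth = noiseless_ph
        mask = hq.wall_mask(series, 100.0)
        for t in range(series.n_frames):
            assert np.array_equal(mask.masks[t], truth.wall_mask)

    def test_flank_zstack_halves_differ_in_ph(self):
        cfg = hq.PHSeriesConfig(noise_sd=0.0)
        stack, truth = hq.synthdata.generate_flank_zstack(
            cfg, ph_upper=6.2, ph_lower=5.6, n_slices=3
        )
        h = cfg.image_height_px
        assert np.all(truth.ph_map_series[:, : h // 2] == 6.2)
        assert np.all(truth.ph_map_series[:, h // 2:] == 5.6)
        assert stack.n_frames == 3


class TestElongationSeries:
    def test_zero_rate_gives_constant_truth(self):
        cfg = hq.GrowthSeriesConfig(growth_rate_pct_per_hr=0.0)
        _, truth = hq.generate_elongation_series(cfg)
        assert np.all(truth.true_length_series == cfg.initial_length_px)

    def test_final_length_closed_form(self):
        # 30 %/h from 200 px with onset at 20 min over a 120-min series
        cfg = hq.GrowthSeriesConfig(
            initial_length_px=200.0, growth_rate_pct_per_hr=30.0,
            onset_min=20.0, n_frames=25, time_step_min=5.0,
        )
        _, truth = hq.generate_elongation_series(cfg)
        assert truth.true_length_series[-1] == pytest.approx(300.0)

    def test_flat_during_lag_phase(self):
        cfg = hq.GrowthSeriesConfig()
        _, truth = hq.generate_elongation_series(cfg)
        times = cfg.t_start_min + cfg.time_step_min * np.arange(cfg.n_frames)
        lag = times <= cfg.onset_min
        assert np.all(truth.true_length_series[lag] == cfg.initial_length_px)

    def test_seed_determinism(self):
        a, _ = hq.generate_elongation_series(hq.GrowthSeriesConfig(seed=3))
        b, _ = hq.generate_elongation_series(hq.GrowthSeriesConfig(seed=3))
        assert np.array_equal(a.data, b.data)

    def test_rod_exceeding_frame_is_rejected(self):
        cfg = hq.GrowthSeriesConfig(initial_length_px=360.0)
        with pytest.raises(ValueError, match="frame bounds"):
            hq.generate_elongation_series(cfg)

    def test_capsule_supports_expected_extent(self):
        rod = render_rod((64, 64), (32.0, 32.0), 40.0, 8.0, 0.0)
        xs = np.nonzero(rod)[1]
        assert xs.max() - xs.min() + 1 == pytest.approx(40, abs=1)


class TestLuminescence:
    def test_zero_amplitude_is_flat(self):
        trace, _ = generate_luminescence_trace(amplitude=0.0, noise_sd=0.0)
        assert np.allclose(trace.value, trace.value[0])

    def test_continuity_at_onset(self):
        trace, _ = generate_luminescence_trace(
            baseline=50.0, onset_min=20.0, noise_sd=0.0, time_step_min=5.0
        )
        assert trace.value[trace.time_min == 20.0] == pytest.approx(50.0)

    def test_onset_recovered_from_noiseless_trace(self):
        trace, truth = generate_luminescence_trace(noise_sd=0.0)
        est = hq.detect_onset(trace, direction="increase")
        assert est.detected
        assert abs(est.t_break_min - truth.true_onset_min) <= 5.0

    def test_stack_roi_mean_equals_trace(self):
        trace, _ = generate_luminescence_trace(noise_sd=0.0)
        stack = luminescence_stack(trace, shape=(32, 32))
        roi = np.array([[2, 2], [30, 2], [30, 30], [2, 30]])
        extracted = hq.extract_roi_trace(stack, roi)
        assert np.allclose(extracted.value, trace.value)


class TestBending:
    def test_zero_rate_keeps_start_angle(self):
        _, truth = generate_bending_series(30.0, 90.0, 0.0, n_frames=4)
        assert np.all(truth.true_angle_series_deg == 30.0)

    def test_linear_schedule_with_saturation(self):
        _, truth = generate_bending_series(
            0.0, 90.0, 90.0, n_frames=5, time_step_min=30.0
        )
        assert truth.true_angle_series_deg[1] == pytest.approx(45.0)
        assert truth.true_angle_series_deg[-1] == 90.0  # saturated

    def test_tip_angle_recovers_trajectory(self):
        series, truth = generate_bending_series(
            0.0, 90.0, 45.0, n_frames=7, time_step_min=20.0
        )
        for t in range(series.n_frames):
            est = hq.tip_angle(series.data[t, 0] > 0.5)
            assert est == pytest.approx(truth.true_angle_series_deg[t], abs=2.0)

    def test_angle_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="start_angle_deg"):
            generate_bending_series(200.0, 90.0, 10.0)


class TestDriftInjection:
    def test_reproducible_and_logged(self, noiseless_ph):
        series, _ = noiseless_ph
        d1, log1 = hq.synthdata.inject_drift(series, step_sd_px=2.0, seed=5)
        d2, log2 = hq.synthdata.inject_drift(series, step_sd_px=2.0, seed=5)
        assert np.array_equal(d1.data, d2.data)
        assert np.array_equal(log1, log2)
        assert np.all(log1[0] == 0)
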