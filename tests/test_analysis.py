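"""Traces, gating, failure events, sine fitting and validation stats."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from resptrack import (
    FailureCriteria,
    GateConfig,
    MotionModelParams,
    Trace,
    detect_failures,
    displacement_from_baseline,
    error_statistics,
    fit_modified_sine,
    gate_signal,
    modified_sine_displacement,
    multi_marker_discrepancy,
)


def make_trace(disp, fps=30.0, axis="AP", marker_id=0):
    disp = np.asarray(disp, dtype=float)
    t = np.arange(len(disp)) / fps
    return Trace(marker_id, t, {axis: disp})


def model_trace(params, duration_s, fps=30.0, axis="AP", marker_id=0, noise_sd=0.0, seed=0):
    n = int(round(duration_s * fps))
    t = np.arange(n) / fps
    d = modified_sine_displacement(t, params)
    if noise_sd > 0:
        d = d + np.random.default_rng(seed).normal(0.0, noise_sd, n)
    return Trace(marker_id, t, {axis: d})


class TestBaseline:
    def test_constant_trace_becomes_zero(self):
        tr = displacement_from_baseline(make_trace(np.full(50, 2.5)))
        np.testing.assert_allclose(tr.displacement_mm["AP"], 0.0, atol=1e-12)

    def test_step_after_baseline_window(self):
        d = np.concatenate([[0.0], np.full(49, 3.0)])
        tr = displacement_from_baseline(make_trace(d), baseline=(0, 1))
        assert tr.displacement_mm["AP"][-1] == pytest.approx(3.0)

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError):
            displacement_from_baseline(make_trace(np.zeros(10)), baseline=(5, 5))


class TestGating:
    def test_below_threshold_no_alerts(self):
        tr = make_trace(4.0 * np.sin(np.linspace(0, 6, 200)))
        alert = gate_signal(tr, GateConfig({"AP": 5.0}))
        assert not alert.any()

    def test_single_excursion_single_alert(self):
        d = np.zeros(100)
        d[40] = 6.0
        alert = gate_signal(make_trace(d), GateConfig({"AP": 5.0}))
        assert alert.sum() == 1 and alert[40]

    def test_latching_keeps_alert_on(self):
        d = np.zeros(100)
        d[40] = 6.0
        alert = gate_signal(make_trace(d), GateConfig({"AP": 5.0}, latching=True))
        assert alert[40:].all() and not alert[:40].any()

    def test_alert_fraction_matches_closed_form_crossing_times(self):
        # a = 20 mm, threshold 5 mm: within each cycle the displacement
        # exceeds the threshold from sin(theta) = 1/4 on the rise to the
        # mirrored point on the fall, plus the inhale pause
        params = MotionModelParams(15.0, 20.0, 0.4)
        fps = 30.0
        tr = model_trace(params, duration_s=params.period_s * 5, fps=fps)
        alert = gate_signal(tr, GateConfig({"AP": 5.0}))
        r, T, p = params.rise_s, params.period_s, params.pause_s
        t_cross = r * np.arcsin(5.0 / 20.0) / (np.pi / 2.0)
        expected_fraction = (2.0 * (r - t_cross) + p) / T
        n_cycles = 5
        # two threshold crossings per cycle, each quantized by at most one sample
        assert abs(alert.sum() - expected_fraction * len(alert)) <= 2 * n_cycles

    def test_alert_count_monotone_in_threshold(self):
        params = MotionModelParams(20.0, 15.0, 0.3)
        tr = model_trace(params, duration_s=9.0)
        counts = [
            gate_signal(tr, GateConfig({"AP": thr})).sum()
            for thr in np.linspace(0.5, 16.0, 25)
        ]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_missing_axis_threshold_rejected(self):
        with pytest.raises(ValueError):
            gate_signal(make_trace(np.zeros(10)), GateConfig({"SI": 5.0}))


class TestFitModifiedSine:
    def test_noiseless_self_fit_is_exact(self):
        params = MotionModelParams(30.0, 25.0, 0.33)
        tr = model_trace(params, duration_s=6.0)
        fit = fit_modified_sine(tr, init=params)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-9)
        assert fit.rmse_mm <= 1e-9

    @pytest.mark.parametrize("f_bpm", [10.0, 20.0, 30.0])
    @pytest.mark.parametrize("a_mm", [2.0, 50.0])
    @pytest.mark.parametrize("pause", [0.0, 0.33])
    def test_parameter_recovery_within_one_percent(self, f_bpm, a_mm, pause):
        params = MotionModelParams(f_bpm, a_mm, pause)
        tr = model_trace(params, duration_s=3.2 * params.period_s, fps=25.0)
        fit = fit_modified_sine(tr)
        assert fit.params.frequency_bpm == pytest.approx(f_bpm, rel=0.01)
        assert fit.params.amplitude_mm == pytest.approx(a_mm, rel=0.01)

    def test_too_short_trace_rejected(self):
        params = MotionModelParams(10.0, 10.0, 0.0)
        tr = model_trace(params, duration_s=5.0)
        with pytest.raises(ValueError, match="two breathing cycles"):
            fit_modified_sine(tr, init=params)


class TestErrorStatistics:
    def test_identical_traces_all_zero(self):
        tr = make_trace(np.sin(np.linspace(0, 10, 300)))
        stats = error_statistics(tr, tr)["AP"]
        assert stats.mean == 0.0 and stats.sd == 0.0
        assert stats.min == 0.0 and stats.max == 0.0

    def test_constant_offset(self):
        base = np.sin(np.linspace(0, 10, 300))
        stats = error_statistics(make_trace(base + 0.2), make_trace(base))["AP"]
        assert stats.mean == pytest.approx(0.2)
        assert stats.sd == pytest.approx(0.0, abs=1e-12)

    def test_white_noise_sd_recovered(self):
        rng = np.random.default_rng(11)
        sigma = 0.13
        base = np.zeros(900)
        noisy = base + rng.normal(0.0, sigma, 900)
        stats = error_statistics(make_trace(noisy), make_trace(base))["AP"]
        assert stats.sd == pytest.approx(sigma, rel=0.15)

    def test_timestamp_mismatch_rejected(self):
        a = make_trace(np.zeros(10), fps=30.0)
        b = make_trace(np.zeros(10), fps=25.0)
        with pytest.raises(ValueError):
            error_statistics(a, b)


class TestMultiMarkerDiscrepancy:
    def test_identical_traces_zero(self):
        tr = make_trace(np.sin(np.linspace(0, 10, 100)))
        per_frame, peak = multi_marker_discrepancy([tr, tr], "AP")
        assert peak == 0.0

    def test_constant_offset_pair(self):
        base = np.sin(np.linspace(0, 10, 100))
        a, b = make_trace(base), make_trace(base + 4.0, marker_id=1)
        per_frame, peak = multi_marker_discrepancy([a, b], "AP")
        np.testing.assert_allclose(per_frame, 4.0, atol=1e-12)
        assert peak == pytest.approx(4.0)

    def test_amplitude_spread_matches_closed_form(self):
        # three markers breathing in phase with amplitudes 10/12/14 mm:
        # the spread peaks at max(a) - min(a) = 4 mm at full inhale
        t = np.arange(300) / 30.0
        params = MotionModelParams(20.0, 1.0, 0.3)
        unit = modified_sine_displacement(t, params)
        traces = [
            Trace(i, t, {"SI": a * unit}) for i, a in enumerate([10.0, 12.0, 14.0])
        ]
        _, peak = multi_marker_discrepancy(traces, "SI")
        assert peak == pytest.approx(4.0, abs=1e-9)

    def test_permutation_invariant(self):
        rng = np.random.default_rng(2)
        t = np.arange(50) / 30.0
        traces = [Trace(i, t, {"AP": rng.normal(size=50)}) for i in range(3)]
        _, p1 = multi_marker_discrepancy(traces, "AP")
        _, p2 = multi_marker_discrepancy(traces[::-1], "AP")
        assert p1 == p2

    def test_fewer_than_two_traces_rejected(self):
        with pytest.raises(ValueError):
            multi_marker_discrepancy([make_trace(np.zeros(5))], "AP")


class TestDetectFailures:
    criteria = FailureCriteria()

    def test_perfect_trace_no_events(self):
        tr = make_trace(np.sin(np.linspace(0, 10, 200)))
        assert detect_failures(tr, tr, self.criteria) == []

    def test_gradual_drift_gives_one_drift_event(self):
        truth = make_trace(np.zeros(200))
        drift = np.concatenate([np.zeros(50), np.linspace(0.0, 1.2, 100), np.full(50, 1.2)])
        events = detect_failures(make_trace(drift), truth, self.criteria)
        drift_events = [e for e in events if e.kind == "drift"]
        step_events = [e for e in events if e.kind == "step"]
        assert len(drift_events) == 1
        assert step_events == []
        # event begins at the first frame the running drift crosses 1 mm
        first_cross = int(np.argmax(drift > 1.0))
        assert drift_events[0].frame_start == first_cross

    def test_single_frame_deviation_gives_one_step_event(self):
        truth = make_trace(np.zeros(100))
        d = np.zeros(100)
        d[40] = 0.6
        events = detect_failures(make_trace(d), truth, self.criteria)
        assert len(events) == 1
        assert events[0].kind == "step"
        assert events[0].magnitude_mm == pytest.approx(0.6)

    def test_live_mode_flags_speed_envelope_violation(self):
        d = np.zeros(100)
        d[60:] = 30.0  # a 30 mm jump in one frame at 30 fps = 900 mm/s
        events = detect_failures(make_trace(d), None, self.criteria, max_speed_mm_s=120.0)
        assert len(events) == 1
        assert events[0].kind == "jump"
        assert events[0].frame_start == 60


@settings(max_examples=30, deadline=None, derandomize=True)
@given(thr_lo=st.floats(0.5, 10.0), delta=st.floats(0.1, 10.0), seed=st.integers(0, 100))
def test_gate_alert_count_never_increases_with_threshold(thr_lo, delta, seed):
    rng = np.random.default_rng(seed)
    tr = make_trace(rng.normal(0.0, 5.0, 200))
    lo = gate_signal(tr, GateConfig({"AP": thr_lo})).sum()
    hi = gate_signal(tr, GateConfig({"AP": thr_lo + delta})).sum()
    assert hi <= lo
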