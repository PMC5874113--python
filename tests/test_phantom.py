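"""Motion law, rendering and ground-truth bookkeeping of the phantom."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from resptrack import (
    MarkerSpec,
    MotionModelParams,
    PhantomScene,
    SegmentedMotion,
    modified_sine_displacement,
    peak_speed,
    quantize_motion,
    render_sequence,
)


def params(f=30.0, a=50.0, p=0.33, **kw):
    return MotionModelParams(frequency_bpm=f, amplitude_mm=a, pause_s=p, **kw)


class TestMotionLaw:
    def test_cycle_starts_at_baseline(self):
        assert modified_sine_displacement(0.0, params()) == 0.0

    def test_full_inhale_at_end_of_rise(self):
        p = params()
        assert modified_sine_displacement(p.rise_s, p) == pytest.approx(50.0)

    def test_quarter_sine_midpoint(self):
        p = params()
        assert modified_sine_displacement(p.rise_s / 2.0, p) == pytest.approx(
            50.0 * np.sin(np.radians(45.0))
        )

    def test_rejects_negative_time(self):
        with pytest.raises(ValueError):
            modified_sine_displacement(-0.1, params())

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(frequency_bpm=0.0, amplitude_mm=10.0),
            dict(frequency_bpm=30.0, amplitude_mm=-1.0),
            dict(frequency_bpm=30.0, amplitude_mm=10.0, pause_s=-0.1),
            # pause so long the period cannot contain two of them
            dict(frequency_bpm=60.0, amplitude_mm=10.0, pause_s=0.6),
        ],
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            MotionModelParams(**kwargs)

    def test_exact_periodicity(self):
        p = params()
        t = np.linspace(0.0, p.period_s, 501)
        np.testing.assert_allclose(
            modified_sine_displacement(t, p),
            modified_sine_displacement(t + 3 * p.period_s, p),
            rtol=0,
            atol=1e-12,
        )

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        f=st.floats(5.0, 60.0),
        a=st.floats(0.0, 60.0),
        frac=st.floats(0.0, 0.2),
        t=st.floats(0.0, 600.0),
    )
    def test_displacement_bounded_by_amplitude(self, f, a, frac, t):
        p = MotionModelParams(f, a, pause_s=frac * 60.0 / f)
        d = modified_sine_displacement(t, p)
        assert -1e-9 <= d <= a + 1e-9

    def test_continuity_on_dense_grid(self):
        p = params()
        t = np.linspace(0.0, 2 * p.period_s, 20001)
        d = modified_sine_displacement(t, p)
        dt = t[1] - t[0]
        max_slope = p.amplitude_mm * np.pi / (2.0 * p.rise_s)
        assert np.max(np.abs(np.diff(d))) <= max_slope * dt * 1.01

    def test_numeric_peak_slope_matches_closed_form(self):
        # no pauses: the quarter-sine peak speed is a*pi/(2r)
        p = params(p=0.0)
        t = np.linspace(0.0, p.period_s, 200001)
        slope = np.max(np.abs(np.diff(modified_sine_displacement(t, p)))) / (t[1] - t[0])
        assert slope == pytest.approx(p.amplitude_mm * np.pi / (2 * p.rise_s), rel=1e-4)

    def test_peak_slope_within_design_envelope(self):
        p = params()
        t = np.linspace(0.0, p.period_s, 100001)
        slope = np.max(np.abs(np.diff(modified_sine_displacement(t, p)))) / (t[1] - t[0])
        envelope = peak_speed(p) * (np.pi / 2.0) / (1.0 - 2.0 * p.pause_s / p.period_s)
        assert slope <= envelope * 1.001

    def test_rests_at_baseline_after_configured_cycles(self):
        p = params(n_cycles=2)
        assert modified_sine_displacement(2 * p.period_s + 0.5, p) == 0.0


class TestPeakSpeed:
    def test_design_worst_case_is_5_cm_per_s(self):
        assert peak_speed(params(f=30.0, a=50.0)) == pytest.approx(50.0)

    def test_zero_amplitude(self):
        assert peak_speed(params(a=0.0)) == 0.0

    def test_linear_in_frequency_and_amplitude(self):
        assert peak_speed(params(f=15.0, a=20.0, p=0.0)) == pytest.approx(10.0)


class TestQuantize:
    def test_zero_step_is_identity(self):
        assert quantize_motion(1.2345, 0.0) == 1.2345

    def test_nearest_multiple(self):
        assert quantize_motion(1.07, 0.5) == pytest.approx(1.0)

    def test_error_bounded_by_half_step_on_grid(self):
        vals = np.linspace(0.0, 50.0, 5001)
        step = 0.17
        err = np.abs(quantize_motion(vals, step) - vals)
        assert np.max(err) <= step / 2 + 1e-12

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(d=st.floats(-100, 100), s=st.floats(1e-3, 5.0))
    def test_quantization_error_property(self, d, s):
        assert abs(quantize_motion(d, s) - d) <= s / 2 + 1e-9


def _tiny_scene(noise_sd=0.0, shape="disc", amplitude=5.0):
    return PhantomScene(
        markers=[MarkerSpec(centre_mm=(8.0, 28.0), size_mm=6.0, shape=shape)],
        pixel_scale_px_per_mm=4.0,
        image_size_px=(64, 128),
        noise_sd=noise_sd,
    )


class TestRenderer:
    def test_zero_amplitude_frames_identical_and_truth_constant(self):
        scene = _tiny_scene()
        frames, truth = render_sequence(
            scene, params(a=0.0, p=0.0), fps=10.0, duration_s=1.0, seed=0
        )
        for f in frames[1:]:
            np.testing.assert_array_equal(f.pixels, frames[0].pixels)
        assert np.all(truth.displacement_mm[0] == 0.0)

    def test_40s_at_30fps_gives_1200_frames_and_rows(self):
        scene = _tiny_scene()
        frames, truth = render_sequence(
            scene, params(f=30.0, a=5.0, p=0.33), fps=30.0, duration_s=40.0, seed=0
        )
        assert len(frames) == 1200
        assert truth.n_frames == 1200

    def test_fixed_seed_reproducible_bitwise(self):
        scene = _tiny_scene(noise_sd=0.02)
        f1, _ = render_sequence(scene, params(a=5.0), fps=10.0, duration_s=1.0, seed=3)
        f2, _ = render_sequence(scene, params(a=5.0), fps=10.0, duration_s=1.0, seed=3)
        for a, b in zip(f1, f2):
            assert a.pixels.tobytes() == b.pixels.tobytes()

    def test_different_seeds_differ(self):
        scene = _tiny_scene(noise_sd=0.02)
        f1, _ = render_sequence(scene, params(a=5.0), fps=10.0, duration_s=0.5, seed=3)
        f2, _ = render_sequence(scene, params(a=5.0), fps=10.0, duration_s=0.5, seed=4)
        assert not np.array_equal(f1[0].pixels, f2[0].pixels)

    def test_disc_centroid_matches_ground_truth(self):
        # intensity-weighted centroid over the noiseless rendered disc is
        # an independent oracle for the recorded sub-pixel centre
        scene = _tiny_scene()
        frames, truth = render_sequence(
            scene, params(a=5.0), fps=7.0, duration_s=1.0, seed=0
        )
        for k, frame in enumerate(frames):
            w = frame.pixels - scene.background
            w = np.clip(w, 0.0, None)
            ys, xs = np.mgrid[: frame.height, : frame.width]
            cx = (w * xs).sum() / w.sum()
            cy = (w * ys).sum() / w.sum()
            assert abs(cx - truth.centres_px[0][k, 0]) < 0.05
            assert abs(cy - truth.centres_px[0][k, 1]) < 0.05

    def test_marker_leaving_fov_is_an_error(self):
        scene = _tiny_scene()
        with pytest.raises(ValueError, match="field of view"):
            render_sequence(scene, params(a=40.0), fps=10.0, duration_s=1.0, seed=0)

    def test_stepper_quantization_recorded_in_truth(self):
        scene = _tiny_scene()
        _, truth = render_sequence(
            scene, params(a=5.0), fps=10.0, duration_s=1.0, seed=0, step_size_mm=0.5
        )
        d = truth.displacement_mm[0]
        np.testing.assert_allclose(d, np.round(d / 0.5) * 0.5, atol=1e-12)


class TestSegmentedMotion:
    def test_concatenated_segments_are_continuous(self):
        seg = SegmentedMotion(
            [(params(f=12.0, a=20.0, p=0.2), 2), (params(f=25.0, a=5.0, p=0.2), 4)]
        )
        t = np.linspace(0.0, seg.duration_s - 1e-9, 20001)
        d = seg.displacement(t)
        dt = t[1] - t[0]
        max_slope = max(
            p.amplitude_mm * np.pi / (2 * p.rise_s) for p, _ in seg.segments
        )
        assert np.max(np.abs(np.diff(d))) <= max_slope * dt * 1.05
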