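"""End-to-end phantom validation scenarios.

These helpers wire the whole chain together — render a phantom video,
detect markers on the first frame, select Shi-Tomasi features, track
them with pyramidal Lucas-Kanade, convert to millimetres, and score the
result against the frame-exact ground truth.  The *reference scenario*
is the benchmark breathing pattern used throughout: 30 breaths per
minute with 330 ms respiratory pauses, 25 mm amplitude at 10 px/mm,
30 fps, with mild sensor noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .analysis import (
    Trace,
    ValidationReport,
    detect_failures,
    error_statistics,
    fit_modified_sine,
    multi_marker_discrepancy,
    trace_from_tracking,
    truth_trace,
)
from .calibration import CameraModel, LATERAL_AXIS_MAP
from .detection import (
    DetectionConfig,
    FeatureConfig,
    detect_markers,
    select_features,
)
from .phantom import (
    GroundTruthTrajectory,
    MarkerSpec,
    MotionModelParams,
    PhantomScene,
    SegmentedMotion,
    iter_rendered,
)
from .tracking import FailureCriteria, TrackerConfig, TrackingResult, track_sequence

__all__ = [
    "PhantomRun",
    "reference_scene",
    "reference_params",
    "variable_breathing_motion",
    "run_phantom_validation",
    "camera_for_scene",
]


def reference_params(
    bpm: float = 30.0, amplitude_mm: float = 25.0, pause_s: float = 0.33
) -> MotionModelParams:
    """The benchmark breathing pattern: 30 bpm with 330 ms pauses."""
    return MotionModelParams(
        frequency_bpm=bpm, amplitude_mm=amplitude_mm, pause_s=pause_s
    )


def reference_scene(
    amplitude_mm: float = 25.0,
    pixel_scale_px_per_mm: float = 10.0,
    noise_sd: float = 0.01,
    marker_size_mm: float = 10.0,
    motion_axis: str = "y",
    n_markers: int = 1,
    marker_gap_mm: float = 15.0,
    amplitude_scales: tuple[float, ...] | None = None,
) -> PhantomScene:
    """A desk-scale scene sized so the motion stays in the field of view.

    The image dimensions are derived from the amplitude, marker size and
    pixel scale with a safety margin, mimicking a camera framed on the
    region the markers sweep.
    """
    s = pixel_scale_px_per_mm
    size = marker_size_mm
    margin_mm = 4.0
    travel = amplitude_mm + size + 2 * margin_mm
    across = n_markers * size + (n_markers - 1) * marker_gap_mm + 2 * margin_mm
    if motion_axis == "y":
        w_px = int(np.ceil(across * s / 16.0)) * 16
        h_px = int(np.ceil(travel * s / 16.0)) * 16
    else:
        w_px = int(np.ceil(travel * s / 16.0)) * 16
        h_px = int(np.ceil(across * s / 16.0)) * 16
    markers = []
    for i in range(n_markers):
        along0 = margin_mm + size / 2.0  # rest position near the baseline edge
        acr = margin_mm + size / 2.0 + i * (size + marker_gap_mm)
        if motion_axis == "y":
            centre = (acr, h_px / s - along0)
        else:
            centre = (along0, acr)
        scale = 1.0 if amplitude_scales is None else amplitude_scales[i]
        markers.append(
            MarkerSpec(centre_mm=centre, size_mm=size, amplitude_scale=scale)
        )
    return PhantomScene(
        markers=markers,
        pixel_scale_px_per_mm=s,
        image_size_px=(w_px, h_px),
        noise_sd=noise_sd,
        motion_axis=motion_axis,
    )


def variable_breathing_motion(
    duration_s: float = 40.0,
    slow_bpm: float = 12.0,
    fast_bpm: float = 25.0,
    deep_amplitude_mm: float = 20.0,
    shallow_amplitude_mm: float = 5.0,
    pause_s: float = 0.2,
) -> SegmentedMotion:
    """Alternating deep-slow and shallow-fast breathing segments.

    Emulates a volunteer instructed to change breathing pattern every
    ~10 s: deep breathing at the slow rate, then shallow tachypnea at
    the fast rate, repeated until ``duration_s`` is covered.
    """
    slow = MotionModelParams(slow_bpm, deep_amplitude_mm, pause_s)
    fast = MotionModelParams(fast_bpm, shallow_amplitude_mm, pause_s)
    segments: list[tuple[MotionModelParams, int]] = []
    t = 0.0
    use_slow = True
    while t < duration_s:
        params = slow if use_slow else fast
        n = max(int(round(10.0 / params.period_s)), 1)
        segments.append((params, n))
        t += n * params.period_s
        use_slow = not use_slow
    return SegmentedMotion(segments)


def camera_for_scene(scene: PhantomScene) -> CameraModel:
    """Lateral-camera model matching a rendered scene's pixel scale."""
    return CameraModel(
        pixel_scale_px_per_mm=scene.pixel_scale_px_per_mm,
        axis_map=dict(LATERAL_AXIS_MAP),
    )


@dataclass
class PhantomRun:
    """Everything a phantom validation run produced."""

    report: ValidationReport
    traces: list[Trace]
    truth_traces: list[Trace]
    tracking: TrackingResult
    truth: GroundTruthTrajectory
    camera: CameraModel


def run_phantom_validation(
    scene: PhantomScene,
    motion: MotionModelParams | SegmentedMotion,
    fps: float = 30.0,
    duration_s: float = 60.0,
    seed: int = 0,
    tracker_config: TrackerConfig = TrackerConfig(),
    detection_config: DetectionConfig = DetectionConfig(),
    feature_config: FeatureConfig = FeatureConfig(),
    criteria: FailureCriteria = FailureCriteria(),
    fit: bool = True,
    fit_axis: str | None = None,
) -> PhantomRun:
    """Render, track and score one phantom scenario.

    Frames are streamed through the tracker one at a time, so arbitrarily
    long sequences use constant memory.  Returns the validation report
    together with the computed and ground-truth traces.
    """
    frames, truth = iter_rendered(scene, motion, fps, duration_s, seed=seed)
    frames = iter(frames)
    first = next(frames)
    markers = detect_markers(first, detection_config)
    if not markers:
        raise RuntimeError("no markers detected in the first frame")
    selection = select_features(first, markers, feature_config)
    if not selection.points:
        raise RuntimeError("no trackable feature points found")

    def chain():
        yield first
        yield from frames

    result = track_sequence(chain(), selection.points, config=tracker_config)
    camera = camera_for_scene(scene)
    motion_axis_name = camera.axis_map[scene.motion_axis][0]

    traces: list[Trace] = []
    truths: list[Trace] = []
    failure_events = []
    stats_all: dict = {}
    fit_result = None
    for mid in sorted(result.marker_positions_px):
        tr = trace_from_tracking(result, mid, camera)
        tt = truth_trace(truth, mid, camera)
        traces.append(tr)
        truths.append(tt)
        failure_events.extend(detect_failures(tr, tt, criteria))
        stats = error_statistics(tr, tt)
        if mid == 0:
            stats_all = stats
    if fit:
        fit_result = fit_modified_sine(traces[0], axis=motion_axis_name)
    discrepancy = None
    if len(traces) >= 2:
        _, discrepancy = multi_marker_discrepancy(traces, motion_axis_name)
    report = ValidationReport(
        n_frames=truth.n_frames,
        error_stats=stats_all,
        fit=fit_result,
        failure_events=failure_events,
        markers_without_features=selection.markers_without_features,
        discrepancy_mm=discrepancy,
        scenario={
            "fps": fps,
            "duration_s": duration_s,
            "seed": seed,
            "pixel_scale_px_per_mm": scene.pixel_scale_px_per_mm,
            "image_size_px": list(scene.image_size_px),
            "noise_sd": scene.noise_sd,
            "motion_axis": motion_axis_name,
        },
    )
    result.failure_events = failure_events
    return PhantomRun(
        report=report,
        traces=traces,
        truth_traces=truths,
        tracking=result,
        truth=truth,
        camera=camera,
    )
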