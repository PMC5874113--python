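"""Motion traces, gating alerts, failure detection and validation stats.

This module turns pixel trajectories into the quantities a respiratory
monitoring workflow reports: displacement from the initial location per
anatomical axis, amplitude-gating alerts, tracking-failure events
(long-term drift and per-frame step discrepancies), least-squares fits
of the modified-sine breathing model with R-squared and RMSE, per-axis
error statistics against ground truth, and the spread of motion across
several markers placed at different skin locations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from .calibration import CameraModel, px_to_mm
from .phantom import GroundTruthTrajectory, MotionModelParams
from .tracking import FailureCriteria, TrackingResult

__all__ = [
    "Trace",
    "GateConfig",
    "ErrorStats",
    "FitResult",
    "FailureEvent",
    "ValidationReport",
    "trace_from_tracking",
    "truth_trace",
    "displacement_from_baseline",
    "gate_signal",
    "fit_modified_sine",
    "error_statistics",
    "multi_marker_discrepancy",
    "detect_failures",
]


@dataclass
class Trace:
    """Displacement of one marker over time, in anatomical millimetres.

    ``displacement_mm`` maps axis name ('AP', 'SI', 'LR') to a per-frame
    array; NaN marks frames where the marker was not tracked.
    """

    marker_id: int
    timestamps_s: np.ndarray
    displacement_mm: dict[str, np.ndarray]
    camera_id: str = "lateral"

    def __post_init__(self) -> None:
        self.timestamps_s = np.asarray(self.timestamps_s, dtype=np.float64)
        n = len(self.timestamps_s)
        if n > 1 and not np.all(np.diff(self.timestamps_s) > 0):
            raise ValueError("timestamps must be strictly increasing")
        for ax, arr in self.displacement_mm.items():
            arr = np.asarray(arr, dtype=np.float64)
            if arr.shape != (n,):
                raise ValueError(f"axis {ax} length does not match timestamps")
            self.displacement_mm[ax] = arr

    @property
    def n_frames(self) -> int:
        return len(self.timestamps_s)

    @property
    def axes(self) -> list[str]:
        return sorted(self.displacement_mm)


def trace_from_tracking(
    result: TrackingResult, marker_id: int, camera: CameraModel
) -> Trace:
    """Convert a marker's tracked pixel positions to an anatomical trace.

    Displacement is taken relative to the first-frame position (the
    'initial location' the monitoring display reports).
    """
    pos = result.marker_positions_px[marker_id]
    rel = pos - pos[0]
    mm = px_to_mm(rel, camera)
    return Trace(marker_id, result.timestamps_s, mm, camera.camera_id)


def truth_trace(
    truth: GroundTruthTrajectory, marker_id: int, camera: CameraModel
) -> Trace:
    """Ground-truth displacement trace in the same frame as the tracker's."""
    pos = truth.centres_px[marker_id]
    rel = pos - pos[0]
    mm = px_to_mm(rel, camera)
    return Trace(marker_id, truth.timestamps_s, mm, camera.camera_id)


def displacement_from_baseline(
    trace: Trace, baseline: slice | tuple[int, int] = (0, 1)
) -> Trace:
    """Re-reference a trace to the mean position over a baseline window.

    ``baseline`` selects frames by index (slice or (start, stop) pair).
    """
    if isinstance(baseline, tuple):
        baseline = slice(*baseline)
    idx = np.arange(trace.n_frames)[baseline]
    if idx.size == 0:
        raise ValueError("baseline window is empty")
    out = {}
    for ax, arr in trace.displacement_mm.items():
        ref = np.nanmean(arr[idx])
        out[ax] = arr - ref
    return Trace(trace.marker_id, trace.timestamps_s.copy(), out, trace.camera_id)


@dataclass(frozen=True)
class GateConfig:
    """Amplitude-gating thresholds per anatomical axis, in mm."""

    thresholds_mm: dict
    latching: bool = False

    def __post_init__(self) -> None:
        for ax, thr in self.thresholds_mm.items():
            if thr <= 0:
                raise ValueError(f"gate threshold for {ax} must be positive")


def gate_signal(trace: Trace, config: GateConfig) -> np.ndarray:
    """Boolean alert per frame: any axis exceeds its amplitude threshold.

    With ``latching`` the alert stays on once raised.
    """
    for ax in trace.axes:
        if ax not in config.thresholds_mm:
            raise ValueError(f"no gate threshold configured for axis {ax}")
    alert = np.zeros(trace.n_frames, dtype=bool)
    for ax, thr in config.thresholds_mm.items():
        if ax in trace.displacement_mm:
            with np.errstate(invalid="ignore"):
                alert |= np.abs(trace.displacement_mm[ax]) > thr
    if config.latching:
        alert = np.maximum.accumulate(alert)
    return alert


def _unit_wave(t: np.ndarray, f_bpm: float, pause_s: float, phase_s: float) -> np.ndarray:
    """Modified-sine wave with unit amplitude (see the phantom module)."""
    T = 60.0 / f_bpm
    r = (T - 2.0 * pause_s) / 2.0
    tau = np.mod(t + phase_s, T)
    out = np.zeros_like(tau)
    rising = tau < r
    out[rising] = np.sin((np.pi / 2.0) * tau[rising] / r)
    out[(tau >= r) & (tau < r + pause_s)] = 1.0
    falling = (tau >= r + pause_s) & (tau < 2.0 * r + pause_s)
    out[falling] = np.cos((np.pi / 2.0) * (tau[falling] - r - pause_s) / r)
    return out


@dataclass
class FitResult:
    """Least-squares fit of the modified-sine breathing model."""

    params: MotionModelParams
    offset_mm: float
    r_squared: float
    rmse_mm: float
    success: bool
    message: str = ""


def _initial_guess(t: np.ndarray, y: np.ndarray) -> MotionModelParams:
    """Heuristic starting point: frequency from the FFT's dominant peak."""
    yc = y - np.mean(y)
    n = len(y)
    dt = float(np.median(np.diff(t)))
    spectrum = np.abs(np.fft.rfft(yc))
    freqs = np.fft.rfftfreq(n, d=dt)
    k = int(np.argmax(spectrum[1:])) + 1
    f_bpm = max(freqs[k] * 60.0, 1.0)
    lo, hi = np.percentile(y, [5, 95])
    a = max(hi - lo, 1e-6)
    return MotionModelParams(
        frequency_bpm=f_bpm, amplitude_mm=a, pause_s=0.05 * 60.0 / f_bpm
    )


def fit_modified_sine(
    trace: Trace,
    axis: str | None = None,
    init: MotionModelParams | None = None,
    n_phase_starts: int = 8,
) -> FitResult:
    """Fit the modified-sine motion law to one axis of a trace.

    Free parameters: amplitude, frequency, pause duration, phase and a
    constant offset.  The fit is restarted from several phase offsets
    spread over one period to escape local minima (the model is strongly
    multimodal in phase).  Requires the trace to span at least two
    breathing cycles of the initial-guess frequency.
    """
    if axis is None:
        axis = trace.axes[0]
    y_all = trace.displacement_mm[axis]
    t_all = trace.timestamps_s
    good = np.isfinite(y_all)
    t, y = t_all[good], y_all[good]
    if len(y) < 10:
        raise ValueError("too few valid samples to fit")
    guess = init if init is not None else _initial_guess(t, y)
    T0 = guess.period_s
    if t[-1] - t[0] < 2.0 * T0:
        raise ValueError("trace must span at least two breathing cycles")

    def model(x: np.ndarray) -> np.ndarray:
        a, f_bpm, pause, phase, offset = x
        T = 60.0 / f_bpm
        if pause >= 0.5 * T - 1e-9:
            return np.full_like(y, 1e6)
        return offset + a * _unit_wave(t, f_bpm, pause, phase)

    def residuals(x: np.ndarray) -> np.ndarray:
        return model(x) - y

    offset0 = float(np.percentile(y, 5))
    lower = [0.0, 0.5, 0.0, -np.inf, -np.inf]
    upper = [np.inf, 120.0, 30.0, np.inf, np.inf]
    phase0 = guess.phase_offset_s
    best = None
    for k in range(n_phase_starts):
        x0 = np.array(
            [
                guess.amplitude_mm,
                guess.frequency_bpm,
                guess.pause_s,
                phase0 + k * T0 / n_phase_starts,
                offset0,
            ]
        )
        try:
            sol = least_squares(residuals, x0, bounds=(lower, upper), method="trf")
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise RuntimeError("modified-sine fit failed from every starting point")
    res = residuals(best.x)
    ss_res = float(np.sum(res**2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    r_squared = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    rmse = float(np.sqrt(np.mean(res**2)))
    a, f_bpm, pause, phase, offset = best.x
    params = MotionModelParams(
        frequency_bpm=float(f_bpm),
        amplitude_mm=float(a),
        pause_s=float(min(pause, 0.499 * 60.0 / f_bpm)),
        phase_offset_s=float(np.mod(phase, 60.0 / f_bpm)),
    )
    return FitResult(
        params=params,
        offset_mm=float(offset),
        r_squared=r_squared,
        rmse_mm=rmse,
        success=bool(best.success),
        message=str(best.message),
    )


@dataclass(frozen=True)
class ErrorStats:
    """Summary of computed-minus-true differences on one axis, in mm."""

    mean: float
    sd: float
    min: float
    max: float
    mean_abs: float
    max_abs: float
    n: int

    def to_dict(self) -> dict:
        return {
            "mean_mm": self.mean,
            "sd_mm": self.sd,
            "min_mm": self.min,
            "max_mm": self.max,
            "mean_abs_mm": self.mean_abs,
            "max_abs_mm": self.max_abs,
            "n": self.n,
        }


def error_statistics(
    trace: Trace, truth: Trace, axes: Sequence[str] | None = None
) -> dict[str, ErrorStats]:
    """Per-axis statistics of computed minus true displacement.

    Frames where the computed trace is NaN (marker not tracked) are
    excluded; ``n`` records the number of compared samples.
    """
    if trace.n_frames != truth.n_frames or not np.allclose(
        trace.timestamps_s, truth.timestamps_s
    ):
        raise ValueError("trace and truth timestamps do not match")
    if axes is None:
        axes = [ax for ax in trace.axes if ax in truth.displacement_mm]
    out: dict[str, ErrorStats] = {}
    for ax in axes:
        diff = trace.displacement_mm[ax] - truth.displacement_mm[ax]
        valid = diff[np.isfinite(diff)]
        if valid.size == 0:
            raise ValueError(f"no valid samples on axis {ax}")
        out[ax] = ErrorStats(
            mean=float(valid.mean()),
            sd=float(valid.std(ddof=1)) if valid.size > 1 else 0.0,
            min=float(valid.min()),
            max=float(valid.max()),
            mean_abs=float(np.abs(valid).mean()),
            max_abs=float(np.abs(valid).max()),
            n=int(valid.size),
        )
    return out


def multi_marker_discrepancy(
    traces: Sequence[Trace], axis: str
) -> tuple[np.ndarray, float]:
    """Per-frame spread (max - min) of displacement across markers.

    Returns the per-frame range on the chosen axis and its maximum over
    the sequence — the figure of merit for how differently distinct skin
    locations move.
    """
    if len(traces) < 2:
        raise ValueError("need at least 2 traces")
    t0 = traces[0].timestamps_s
    for tr in traces[1:]:
        if tr.n_frames != len(t0) or not np.allclose(tr.timestamps_s, t0):
            raise ValueError("traces must share common timestamps")
    stack = np.vstack([tr.displacement_mm[axis] for tr in traces])
    per_frame = np.nanmax(stack, axis=0) - np.nanmin(stack, axis=0)
    return per_frame, float(np.nanmax(per_frame))


@dataclass(frozen=True)
class FailureEvent:
    """One tracking failure: kind is 'drift', 'step' or 'jump'."""

    kind: str
    marker_id: int
    frame_start: int
    frame_end: int
    magnitude_mm: float


def _merge_runs(flags: np.ndarray) -> list[tuple[int, int]]:
    """Merge consecutive flagged frames into (start, end) runs."""
    runs = []
    idx = np.flatnonzero(flags)
    if idx.size == 0:
        return runs
    start = prev = int(idx[0])
    for i in idx[1:]:
        if i == prev + 1:
            prev = int(i)
        else:
            runs.append((start, prev))
            start = prev = int(i)
    runs.append((start, prev))
    return runs


def detect_failures(
    trace: Trace,
    truth: Trace | None,
    criteria: FailureCriteria,
    max_speed_mm_s: float = 120.0,
) -> list[FailureEvent]:
    """Find tracking failures in a trace.

    With ground truth, two criteria are evaluated on the error vector
    ``e_t`` (computed minus true, over the shared axes): a *step*
    failure when the error changes by more than the step threshold
    between two successive frames (consecutive flagged frames merge into
    one event), and a *drift* failure whenever the error magnitude
    crosses the drift threshold upward (one event per excursion).

    Without ground truth the criterion degrades to a per-frame jump
    check against a design speed envelope: the marker cannot plausibly
    move faster than ``max_speed_mm_s``, so larger jumps are flagged.
    """
    if truth is not None:
        axes = [ax for ax in trace.axes if ax in truth.displacement_mm]
        err = np.vstack(
            [trace.displacement_mm[ax] - truth.displacement_mm[ax] for ax in axes]
        )
        mag = np.sqrt(np.sum(err**2, axis=0))
        with np.errstate(invalid="ignore"):
            step = np.sqrt(np.sum(np.diff(err, axis=1) ** 2, axis=0))
            step_flags = np.concatenate([[False], step > criteria.max_step_discrepancy_mm])
            drift_flags = mag > criteria.max_drift_mm
        events = [
            FailureEvent(
                "step",
                trace.marker_id,
                s,
                e,
                float(np.nanmax(step[max(s - 1, 0) : e])),
            )
            for s, e in _merge_runs(step_flags)
        ]
        # one drift event per upward crossing of the drift threshold
        for s, e in _merge_runs(drift_flags):
            events.append(
                FailureEvent(
                    "drift", trace.marker_id, s, e, float(np.nanmax(mag[s : e + 1]))
                )
            )
        events.sort(key=lambda ev: ev.frame_start)
        return events
    # live mode: no truth available
    disp = np.vstack([trace.displacement_mm[ax] for ax in trace.axes])
    with np.errstate(invalid="ignore"):
        jump = np.sqrt(np.sum(np.diff(disp, axis=1) ** 2, axis=0))
        dt = np.diff(trace.timestamps_s)
        speed = jump / dt
        flags = np.concatenate([[False], speed > max_speed_mm_s])
    return [
        FailureEvent(
            "jump", trace.marker_id, s, e, float(np.nanmax(jump[max(s - 1, 0) : e]))
        )
        for s, e in _merge_runs(flags)
    ]


@dataclass
class ValidationReport:
    """Aggregate outcome of a phantom validation run."""

    n_frames: int
    error_stats: dict[str, ErrorStats]
    fit: FitResult | None
    failure_events: list[FailureEvent]
    markers_without_features: list[int] = field(default_factory=list)
    discrepancy_mm: float | None = None
    scenario: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d: dict = {
            "n_frames": self.n_frames,
            "n_failure_events": len(self.failure_events),
            "failure_events": [
                {
                    "kind": ev.kind,
                    "marker_id": ev.marker_id,
                    "frame_start": ev.frame_start,
                    "frame_end": ev.frame_end,
                    "magnitude_mm": ev.magnitude_mm,
                }
                for ev in self.failure_events
            ],
            "markers_without_features": self.markers_without_features,
            "scenario": self.scenario,
        }
        for ax, stats in self.error_stats.items():
            d[f"error_{ax}"] = stats.to_dict()
        if self.fit is not None:
            d["fit"] = {
                "amplitude_mm": self.fit.params.amplitude_mm,
                "frequency_bpm": self.fit.params.frequency_bpm,
                "pause_s": self.fit.params.pause_s,
                "phase_s": self.fit.params.phase_offset_s,
                "offset_mm": self.fit.offset_mm,
                "r_squared": self.fit.r_squared,
                "rmse_mm": self.fit.rmse_mm,
            }
        if self.discrepancy_mm is not None:
            d["max_inter_marker_discrepancy_mm"] = self.discrepancy_mm
        return d
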