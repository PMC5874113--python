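"""Pyramidal Lucas-Kanade tracking of fiducial feature points.

Each frame is reduced to an image pyramid (5-tap binomial low-pass, then
2x decimation).  For every feature point the local optical flow between
consecutive frames is solved coarse-to-fine: at each level the classical
Lucas-Kanade normal equations ``G v = b`` are iterated with bilinear
sub-pixel sampling, where ``G`` is the structure tensor of the previous
frame's window and ``b`` accumulates the temporal difference projected
on the spatial gradients.  The solution at a coarse level, doubled,
seeds the next finer level, which lets the tracker follow inter-frame
motions much larger than the integration window.

A marker's reported position is the median over its surviving feature
points, which keeps a single drifting corner from corrupting the trace.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage

from .calibration import CameraModel, px_to_mm
from .detection import FeaturePoint
from .grids import ImageGrid, bilinear_sample, central_gradients

__all__ = [
    "Pyramid",
    "TrackedPoint",
    "FailureCriteria",
    "TrackerConfig",
    "TrackingResult",
    "build_pyramid",
    "lk_step",
    "track_sequence",
    "OK",
    "LOST",
    "FAILED",
]

OK, LOST, FAILED = "ok", "lost", "failed"

_BINOMIAL5 = np.array([1.0, 4.0, 6.0, 4.0, 1.0]) / 16.0


@dataclass
class Pyramid:
    """Multi-resolution stack of one frame; level 0 is full resolution."""

    levels: list[ImageGrid]

    @property
    def n_levels(self) -> int:
        return len(self.levels)


@dataclass(frozen=True)
class FailureCriteria:
    """Tracking-failure thresholds against ground truth.

    A failure is excessive long-term drift of the tracking error beyond
    ``max_drift_mm``, or a computed-versus-actual discrepancy between
    two successive frames beyond ``max_step_discrepancy_mm``.
    """

    max_drift_mm: float = 1.0
    max_step_discrepancy_mm: float = 0.5

    def __post_init__(self) -> None:
        if self.max_drift_mm <= 0 or self.max_step_discrepancy_mm <= 0:
            raise ValueError("failure thresholds must be positive")


@dataclass(frozen=True)
class TrackerConfig:
    """Pyramidal LK settings.

    ``window_halfwidth`` 7 gives a 15x15 integration window; iterations
    stop when the update falls below ``eps_px`` or after ``max_iter``.
    ``min_eig_per_px`` rejects windows whose structure tensor minimum
    eigenvalue (normalized by window pixel count) is too small to invert
    reliably.
    """

    n_levels: int = 3
    window_halfwidth: int = 7
    max_iter: int = 30
    eps_px: float = 0.01
    min_eig_per_px: float = 1e-4
    border_margin_px: float = 2.0


@dataclass
class TrackedPoint:
    """Trajectory of one feature point across a sequence.

    ``positions_px`` is (n_frames, 2) with NaN where the point is no
    longer tracked; ``status`` transitions only ok -> {ok, lost, failed}.
    """

    marker_id: int
    positions_px: np.ndarray
    status: np.ndarray  # array of str codes per frame
    residuals: np.ndarray


@dataclass
class TrackingResult:
    """Output of :func:`track_sequence`.

    ``marker_positions_px`` maps marker id -> (n_frames, 2) median
    position over that marker's surviving points (NaN once every point
    of the marker is gone).  ``all_lost`` is True when no point survived
    to the final frame — an explicit tracking-failure outcome.
    """

    points: list[TrackedPoint]
    marker_positions_px: dict[int, np.ndarray]
    timestamps_s: np.ndarray
    failure_events: list = field(default_factory=list)
    all_lost: bool = False


def build_pyramid(frame: ImageGrid, n_levels: int = 3) -> Pyramid:
    """Build an image pyramid by binomial low-pass filtering + decimation.

    Level L+1 keeps every other pixel of the filtered level L, so its
    dimensions are ``ceil(level_L / 2)``.  The top level must remain at
    least 16 px in each dimension.
    """
    if n_levels < 1:
        raise ValueError("n_levels must be >= 1")
    levels = [frame]
    img = frame.pixels
    for _ in range(n_levels - 1):
        lp = ndimage.correlate1d(img, _BINOMIAL5, axis=0, mode="nearest")
        lp = ndimage.correlate1d(lp, _BINOMIAL5, axis=1, mode="nearest")
        img = lp[::2, ::2]
        if min(img.shape) < 16:
            raise ValueError(
                f"frame {frame.shape} too small for a {n_levels}-level pyramid"
            )
        levels.append(ImageGrid(img, frame.timestamp_s))
    return Pyramid(levels)


def _window_offsets(w: int) -> tuple[np.ndarray, np.ndarray]:
    r = np.arange(-w, w + 1, dtype=np.float64)
    ox, oy = np.meshgrid(r, r)
    return ox.ravel(), oy.ravel()


def _lk_iterate(
    prev: np.ndarray,
    gx: np.ndarray,
    gy: np.ndarray,
    nxt: np.ndarray,
    p: np.ndarray,
    guess: np.ndarray,
    config: TrackerConfig,
) -> tuple[np.ndarray, float, bool]:
    """Core LK solve at one pyramid level with precomputed gradients."""
    w = config.window_halfwidth
    ox, oy = _window_offsets(w)
    xs, ys = p[0] + ox, p[1] + oy
    i0 = bilinear_sample(prev, xs, ys)
    ix = bilinear_sample(gx, xs, ys)
    iy = bilinear_sample(gy, xs, ys)
    gxx = float((ix * ix).sum())
    gxy = float((ix * iy).sum())
    gyy = float((iy * iy).sum())
    half_trace = (gxx + gyy) / 2.0
    det = gxx * gyy - gxy * gxy
    min_eig = half_trace - np.sqrt(max(half_trace**2 - det, 0.0))
    n_px = len(ox)
    if min_eig / n_px < config.min_eig_per_px or det <= 0:
        return guess, float("inf"), False
    inv = np.array([[gyy, -gxy], [-gxy, gxx]]) / det
    v = guess.astype(np.float64).copy()
    converged = False
    j = i0
    for _ in range(config.max_iter):
        j = bilinear_sample(nxt, xs + v[0], ys + v[1])
        diff = i0 - j
        b = np.array([float((diff * ix).sum()), float((diff * iy).sum())])
        delta = inv @ b
        v += delta
        if float(np.hypot(delta[0], delta[1])) < config.eps_px:
            converged = True
            break
    residual = float(np.sqrt(np.mean((i0 - j) ** 2)))
    return v, residual, converged


def lk_step(
    prev: ImageGrid,
    next_frame: ImageGrid,
    p: Sequence[float],
    guess: Sequence[float] = (0.0, 0.0),
    window_halfwidth: int = 7,
    max_iter: int = 30,
    eps_px: float = 0.01,
    min_eig_per_px: float = 1e-4,
) -> tuple[np.ndarray, float, bool]:
    """Single-level Lucas-Kanade flow at one point.

    Returns ``(flow, residual, converged)`` where ``flow`` is the (dx,
    dy) displacement of the window from ``prev`` to ``next_frame``,
    ``residual`` the final RMS window intensity difference, and
    ``converged`` False when the solve is ill-conditioned (structure
    tensor nearly singular) or the iteration budget ran out.
    """
    config = TrackerConfig(
        n_levels=1,
        window_halfwidth=window_halfwidth,
        max_iter=max_iter,
        eps_px=eps_px,
        min_eig_per_px=min_eig_per_px,
    )
    gx, gy = central_gradients(prev.pixels)
    return _lk_iterate(
        prev.pixels,
        gx,
        gy,
        next_frame.pixels,
        np.asarray(p, dtype=np.float64),
        np.asarray(guess, dtype=np.float64),
        config,
    )


class _GradPyramid:
    """Pyramid with per-level central-difference gradients, built once."""

    def __init__(self, pyramid: Pyramid):
        self.levels = [lvl.pixels for lvl in pyramid.levels]
        self.grads = [central_gradients(img) for img in self.levels]


def _track_point_pair(
    prev: _GradPyramid, nxt: _GradPyramid, p: np.ndarray, config: TrackerConfig
) -> tuple[np.ndarray, float, bool, bool]:
    """Coarse-to-fine LK for one point across one frame pair.

    Returns (new position, residual, converged, in_bounds).
    """
    n_levels = len(prev.levels)
    v = np.zeros(2)
    residual = float("inf")
    converged = True
    for lvl in range(n_levels - 1, -1, -1):
        scale = 2.0**lvl
        p_l = p / scale
        img_prev = prev.levels[lvl]
        gx, gy = prev.grads[lvl]
        v, residual, conv = _lk_iterate(
            img_prev, gx, gy, nxt.levels[lvl], p_l, v, config
        )
        converged = conv
        if lvl > 0:
            v = 2.0 * v
    new_p = p + v
    h, w = nxt.levels[0].shape
    m = config.window_halfwidth + config.border_margin_px
    in_bounds = (m <= new_p[0] <= w - 1 - m) and (m <= new_p[1] <= h - 1 - m)
    return new_p, residual, converged, in_bounds


def track_sequence(
    frames: Iterable[ImageGrid],
    initial: Sequence[FeaturePoint],
    camera: CameraModel | None = None,
    criteria: FailureCriteria | None = None,
    config: TrackerConfig = TrackerConfig(),
    truth=None,
) -> TrackingResult:
    """Track feature points through a frame sequence.

    ``frames`` may be any iterable (a generator streams long sequences
    with one pyramid in memory).  Points that leave the usable image
    area are marked ``lost``; points whose solve does not converge are
    marked ``failed``; either way tracking of that point stops.  The
    per-marker position is the per-axis median over the marker's
    surviving points.

    When ``truth`` (a ground-truth trajectory from the phantom renderer)
    and ``camera`` and ``criteria`` are supplied, the per-frame
    computed-versus-actual failure criteria are evaluated and recorded
    in ``failure_events``.
    """
    if not initial:
        raise ValueError("no initial feature points")
    positions = [np.array(fp.position_px, dtype=np.float64) for fp in initial]
    status = [OK] * len(initial)
    marker_ids = sorted({fp.marker_id for fp in initial})

    pos_hist: list[list[np.ndarray]] = [[] for _ in initial]
    stat_hist: list[list[str]] = [[] for _ in initial]
    res_hist: list[list[float]] = [[] for _ in initial]
    timestamps: list[float] = []

    prev_pyr: _GradPyramid | None = None
    n_frames = 0
    for frame in frames:
        pyr = _GradPyramid(build_pyramid(frame, config.n_levels))
        if prev_pyr is not None:
            for i in range(len(initial)):
                if status[i] != OK:
                    pos_hist[i].append(np.array([np.nan, np.nan]))
                    stat_hist[i].append(status[i])
                    res_hist[i].append(np.nan)
                    continue
                new_p, residual, conv, in_bounds = _track_point_pair(
                    prev_pyr, pyr, positions[i], config
                )
                if not in_bounds:
                    status[i] = LOST
                    pos_hist[i].append(np.array([np.nan, np.nan]))
                elif not conv:
                    status[i] = FAILED
                    pos_hist[i].append(np.array([np.nan, np.nan]))
                else:
                    positions[i] = new_p
                    pos_hist[i].append(new_p.copy())
                stat_hist[i].append(status[i])
                res_hist[i].append(residual)
        else:
            for i in range(len(initial)):
                pos_hist[i].append(positions[i].copy())
                stat_hist[i].append(OK)
                res_hist[i].append(0.0)
        timestamps.append(frame.timestamp_s)
        prev_pyr = pyr
        n_frames += 1

    if n_frames < 2:
        raise ValueError("track_sequence needs at least 2 frames")

    points = [
        TrackedPoint(
            marker_id=fp.marker_id,
            positions_px=np.vstack(pos_hist[i]),
            status=np.array(stat_hist[i]),
            residuals=np.array(res_hist[i]),
        )
        for i, fp in enumerate(initial)
    ]
    marker_positions: dict[int, np.ndarray] = {}
    for mid in marker_ids:
        stack = np.stack(
            [tp.positions_px for tp in points if tp.marker_id == mid], axis=0
        )
        import warnings as _warnings

        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore", RuntimeWarning)
            marker_positions[mid] = np.nanmedian(stack, axis=0)
    all_lost = all(s != OK for s in status)
    result = TrackingResult(
        points=points,
        marker_positions_px=marker_positions,
        timestamps_s=np.asarray(timestamps, dtype=np.float64),
        all_lost=all_lost,
    )
    if truth is not None and camera is not None and criteria is not None:
        from .analysis import detect_failures, trace_from_tracking, truth_trace

        for mid in marker_ids:
            computed = trace_from_tracking(result, mid, camera)
            actual = truth_trace(truth, mid, camera)
            result.failure_events.extend(
                detect_failures(computed, actual, criteria)
            )
    return result
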