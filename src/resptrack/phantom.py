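"""Digital twin of a stepper-driven thorax motion phantom.

The physical device this module emulates drives a high-contrast fiducial
marker through an anteroposterior "modified sine" trajectory: the marker
sits on an arm that rotates at constant angular speed from the horizontal
plane to vertical (0 to 90 degrees), pauses briefly at full inhale,
mirrors the motion back down, and pauses again at full exhale.  With
cycle period ``T = 60 / frequency_bpm`` and pause duration ``p``, each
quarter-sine rise or fall lasts ``r = (T - 2 p) / 2`` and the
displacement is

    d(t) = a * sin( (pi/2) * t / r )        during the rise,
    d(t) = a                                 for p seconds,
    mirrored fall, then d(t) = 0 for p seconds.

The renderer rasterizes markers (discs or squares) at a configurable
pixel scale with anti-aliasing, additive Gaussian noise and optional
multiplicative illumination drift, and records the exact sub-pixel marker
centre for every frame — the digital stand-in for the physical phantom's
optical encoder feedback.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np

from .grids import ImageGrid

__all__ = [
    "MotionModelParams",
    "MarkerSpec",
    "PhantomScene",
    "GroundTruthTrajectory",
    "SegmentedMotion",
    "modified_sine_displacement",
    "peak_speed",
    "quantize_motion",
    "render_frame",
    "render_sequence",
    "iter_rendered",
]


@dataclass(frozen=True)
class MotionModelParams:
    """Kinematic parameters of the breathing motion law.

    Attributes
    ----------
    frequency_bpm
        Breathing frequency f in breaths per minute (30 bpm = 0.5 Hz).
    amplitude_mm
        Peak displacement a in millimetres.
    pause_s
        Respiratory pause duration at each extremum (full inhale and
        full exhale), in seconds.
    n_cycles
        Number of cycles to run; ``None`` means unbounded.  After the
        last cycle the marker rests at baseline.
    phase_offset_s
        Time offset added to t before evaluating the cycle.
    """

    frequency_bpm: float
    amplitude_mm: float
    pause_s: float = 0.0
    n_cycles: int | None = None
    phase_offset_s: float = 0.0

    def __post_init__(self) -> None:
        if not self.frequency_bpm > 0:
            raise ValueError("frequency_bpm must be positive")
        if self.amplitude_mm < 0:
            raise ValueError("amplitude_mm must be non-negative")
        if self.pause_s < 0:
            raise ValueError("pause_s must be non-negative")
        if not self.period_s > 2.0 * self.pause_s:
            raise ValueError(
                "cycle period T = 60/frequency_bpm must exceed twice the pause"
            )
        if self.n_cycles is not None and self.n_cycles <= 0:
            raise ValueError("n_cycles must be positive when given")

    @property
    def period_s(self) -> float:
        """Cycle period T = 60 / f in seconds."""
        return 60.0 / self.frequency_bpm

    @property
    def rise_s(self) -> float:
        """Duration r of each quarter-sine rise/fall: (T - 2p) / 2."""
        return (self.period_s - 2.0 * self.pause_s) / 2.0


def modified_sine_displacement(
    t: float | np.ndarray, params: MotionModelParams
) -> float | np.ndarray:
    """Displacement in mm at time ``t`` (s) under the modified sine law.

    Periodic with period ``T = 60/frequency_bpm``; each cycle is a
    quarter-sine rise over ``r = (T - 2 pause)/2`` seconds, a plateau at
    the amplitude for ``pause`` seconds, the mirrored fall, and a plateau
    at baseline.  Output is always within ``[0, amplitude_mm]``.
    """
    t_arr = np.asarray(t, dtype=np.float64)
    if np.any(t_arr < 0):
        raise ValueError("t must be non-negative")
    T = params.period_s
    p = params.pause_s
    r = params.rise_s
    a = params.amplitude_mm
    te = t_arr + params.phase_offset_s
    tau = np.mod(te, T)
    d = np.zeros_like(tau)
    rising = tau < r
    d[rising] = a * np.sin((np.pi / 2.0) * tau[rising] / r)
    plateau = (tau >= r) & (tau < r + p)
    d[plateau] = a
    falling = (tau >= r + p) & (tau < 2.0 * r + p)
    d[falling] = a * np.cos((np.pi / 2.0) * (tau[falling] - r - p) / r)
    # beyond the configured number of cycles the phantom rests at baseline
    if params.n_cycles is not None:
        d[te >= params.n_cycles * T] = 0.0
    if np.isscalar(t):
        return float(d)
    return d


def peak_speed(params: MotionModelParams) -> float:
    """Worst-case design speed bound 2 f a in mm/s (f in Hz).

    This is the envelope used to rate a breathing scenario against the
    tracker's design capacity (f = 30/min with a = 50 mm gives 50 mm/s,
    i.e. 5 cm/s); the instantaneous quarter-sine peak slope is higher by
    a factor (pi/2) / (1 - 2 pause/T).
    """
    return 2.0 * (params.frequency_bpm / 60.0) * params.amplitude_mm


def quantize_motion(
    displacement_mm: float | np.ndarray, step_size_mm: float
) -> float | np.ndarray:
    """Round displacement to the nearest multiple of a stepper step.

    Emulates the granularity of the geared stepper motor driving the
    physical phantom.  ``step_size_mm = 0`` disables quantization.
    """
    if step_size_mm < 0:
        raise ValueError("step_size_mm must be non-negative")
    if step_size_mm == 0:
        return displacement_mm
    q = np.round(np.asarray(displacement_mm, dtype=np.float64) / step_size_mm)
    out = q * step_size_mm
    if np.isscalar(displacement_mm):
        return float(out)
    return out


@dataclass(frozen=True)
class MarkerSpec:
    """A single fiducial marker in the scene.

    ``centre_mm`` is the marker centre at zero displacement in scene
    millimetre coordinates (x right, y down, origin at the image's
    top-left corner).  ``size_mm`` is the diameter (disc) or side length
    (square).  ``amplitude_scale`` multiplies the scene motion law for
    this marker, letting several markers move with different amplitudes
    as different skin locations do.
    """

    centre_mm: tuple[float, float]
    size_mm: float = 10.0
    shape: str = "square"
    foreground: float = 0.9
    amplitude_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.shape not in ("disc", "square"):
            raise ValueError("marker shape must be 'disc' or 'square'")
        if self.size_mm <= 0:
            raise ValueError("size_mm must be positive")


@dataclass
class PhantomScene:
    """Geometry, optics and noise of a rendered phantom video.

    ``motion_axis`` selects the image axis carrying the breathing
    displacement: ``'y'`` (default) moves markers up the image
    (anteroposterior as seen by a lateral camera), ``'x'`` moves them to
    the right (superior-inferior).
    """

    markers: list[MarkerSpec]
    pixel_scale_px_per_mm: float = 10.0
    image_size_px: tuple[int, int] = (640, 480)  # (width, height)
    background: float = 0.1
    noise_sd: float = 0.01
    motion_axis: str = "y"
    illumination_drift: Sequence[float] | None = None

    def __post_init__(self) -> None:
        if self.pixel_scale_px_per_mm <= 0:
            raise ValueError("pixel_scale_px_per_mm must be positive")
        if self.motion_axis not in ("x", "y"):
            raise ValueError("motion_axis must be 'x' or 'y'")
        for m in self.markers:
            if m.size_mm * self.pixel_scale_px_per_mm < 4:
                raise ValueError("marker diameter must be at least 4 px")
            if not (0.0 <= m.foreground <= 1.0):
                raise ValueError("marker intensity outside representable range")
        if not (0.0 <= self.background <= 1.0):
            raise ValueError("background intensity outside representable range")


@dataclass
class GroundTruthTrajectory:
    """Frame-exact marker positions recorded by the renderer.

    ``displacement_mm`` maps marker id -> per-frame displacement along
    the motion axis in millimetres (anatomical frame, positive towards
    inhale).  ``centres_px`` maps marker id -> (n, 2) array of exact
    sub-pixel (x, y) marker centres.
    """

    timestamps_s: np.ndarray
    displacement_mm: dict[int, np.ndarray]
    centres_px: dict[int, np.ndarray]
    seed: int | None = None

    def __post_init__(self) -> None:
        ts = np.asarray(self.timestamps_s, dtype=np.float64)
        if ts.ndim != 1 or (len(ts) > 1 and not np.all(np.diff(ts) > 0)):
            raise ValueError("timestamps must be strictly increasing")
        self.timestamps_s = ts

    @property
    def n_frames(self) -> int:
        return len(self.timestamps_s)


class SegmentedMotion:
    """Concatenation of whole-cycle motion segments.

    Each segment runs an integer number of cycles of its own
    :class:`MotionModelParams`; because every full cycle starts and ends
    at baseline, the concatenated displacement is continuous.  Used to
    emulate variable breathing patterns (alternating slow deep and fast
    shallow segments).
    """

    def __init__(self, segments: Sequence[tuple[MotionModelParams, int]]):
        if not segments:
            raise ValueError("at least one segment required")
        self.segments = [(p, int(n)) for p, n in segments]
        for p, n in self.segments:
            if n <= 0:
                raise ValueError("segment cycle counts must be positive")
        self._durations = np.array(
            [p.period_s * n for p, n in self.segments], dtype=np.float64
        )
        self._starts = np.concatenate([[0.0], np.cumsum(self._durations)])

    @property
    def duration_s(self) -> float:
        return float(self._starts[-1])

    @property
    def amplitude_mm(self) -> float:
        return max(p.amplitude_mm for p, _ in self.segments)

    def displacement(self, t: float | np.ndarray) -> np.ndarray:
        t_arr = np.atleast_1d(np.asarray(t, dtype=np.float64))
        out = np.zeros_like(t_arr)
        for (params, _n), t0, t1 in zip(
            self.segments, self._starts[:-1], self._starts[1:]
        ):
            mask = (t_arr >= t0) & (t_arr < t1)
            if np.any(mask):
                out[mask] = modified_sine_displacement(t_arr[mask] - t0, params)
        return out


def _motion_displacement(motion, t: np.ndarray) -> np.ndarray:
    if isinstance(motion, MotionModelParams):
        return np.atleast_1d(modified_sine_displacement(t, motion))
    return motion.displacement(t)


def _rasterize_marker(
    frame: np.ndarray,
    marker: MarkerSpec,
    centre_px: tuple[float, float],
    radius_px: float,
    background: float,
) -> None:
    """Draw one anti-aliased marker into ``frame`` (in place)."""
    cx, cy = centre_px
    h, w = frame.shape
    x0 = max(int(np.floor(cx - radius_px - 1)), 0)
    x1 = min(int(np.ceil(cx + radius_px + 1)) + 1, w)
    y0 = max(int(np.floor(cy - radius_px - 1)), 0)
    y1 = min(int(np.ceil(cy + radius_px + 1)) + 1, h)
    if x0 >= x1 or y0 >= y1:
        return
    xs = np.arange(x0, x1, dtype=np.float64)
    ys = np.arange(y0, y1, dtype=np.float64)
    if marker.shape == "square":
        # exact analytic coverage: overlap of the pixel footprint with the
        # axis-aligned square, separable in x and y
        cov_x = np.clip(
            np.minimum(xs + 0.5, cx + radius_px) - np.maximum(xs - 0.5, cx - radius_px),
            0.0,
            1.0,
        )
        cov_y = np.clip(
            np.minimum(ys + 0.5, cy + radius_px) - np.maximum(ys - 0.5, cy - radius_px),
            0.0,
            1.0,
        )
        coverage = cov_y[:, None] * cov_x[None, :]
    else:
        # 4x4 supersampled disc coverage
        sub = (np.arange(4) + 0.5) / 4.0 - 0.5
        sx = xs[None, :, None] + sub[None, None, :]  # (1, nx, 4)
        sy = ys[:, None, None] + sub[None, None, :]  # (ny, 1, 4)
        dx2 = (sx - cx) ** 2  # (1, nx, 4)
        dy2 = (sy - cy) ** 2  # (ny, 1, 4)
        inside = (dx2[:, :, None, :] + dy2[:, :, :, None]) <= radius_px**2
        coverage = inside.mean(axis=(2, 3))
    patch = frame[y0:y1, x0:x1]
    patch += (marker.foreground - background) * coverage


def render_frame(
    scene: PhantomScene,
    displacement_mm: Sequence[float],
    timestamp_s: float = 0.0,
    rng: np.random.Generator | None = None,
    illumination: float = 1.0,
    allow_exit: bool = False,
) -> tuple[ImageGrid, np.ndarray]:
    """Render one frame; returns the frame and exact (x, y) centres in px.

    ``displacement_mm`` gives the motion-law displacement for each marker
    (already scaled per marker).  Positive displacement moves the marker
    up the image for ``motion_axis='y'`` and right for ``'x'``.
    """
    w, h = scene.image_size_px
    s = scene.pixel_scale_px_per_mm
    frame = np.full((h, w), scene.background, dtype=np.float64)
    centres = np.empty((len(scene.markers), 2), dtype=np.float64)
    for i, (marker, d) in enumerate(zip(scene.markers, displacement_mm)):
        cx = marker.centre_mm[0] * s
        cy = marker.centre_mm[1] * s
        if scene.motion_axis == "y":
            cy -= d * s
        else:
            cx += d * s
        radius = marker.size_mm * s / 2.0
        if not allow_exit and (
            cx - radius < 0 or cx + radius > w or cy - radius < 0 or cy + radius > h
        ):
            raise ValueError(
                f"marker {i} leaves the field of view at t={timestamp_s:.3f}s"
            )
        _rasterize_marker(frame, marker, (cx, cy), radius, scene.background)
        centres[i] = (cx, cy)
    frame *= illumination
    if rng is not None and scene.noise_sd > 0:
        frame += rng.normal(0.0, scene.noise_sd, size=frame.shape)
    np.clip(frame, 0.0, 1.0, out=frame)
    return ImageGrid(frame, timestamp_s), centres


def _trajectory(
    scene: PhantomScene, motion, fps: float, duration_s: float, step_size_mm: float = 0.0
) -> GroundTruthTrajectory:
    n = int(round(duration_s * fps))
    t = np.arange(n, dtype=np.float64) / fps
    base = _motion_displacement(motion, t)
    # with stepper quantization the actual phantom position is the
    # quantized one, so that is what ground truth records
    disp = {
        i: quantize_motion(base * m.amplitude_scale, step_size_mm)
        for i, m in enumerate(scene.markers)
    }
    centres: dict[int, np.ndarray] = {}
    s = scene.pixel_scale_px_per_mm
    for i, m in enumerate(scene.markers):
        c = np.empty((n, 2), dtype=np.float64)
        c[:, 0] = m.centre_mm[0] * s
        c[:, 1] = m.centre_mm[1] * s
        if scene.motion_axis == "y":
            c[:, 1] -= disp[i] * s
        else:
            c[:, 0] += disp[i] * s
        centres[i] = c
    return GroundTruthTrajectory(t, disp, centres)


def iter_rendered(
    scene: PhantomScene,
    motion: MotionModelParams | SegmentedMotion,
    fps: float,
    duration_s: float,
    seed: int = 0,
    step_size_mm: float = 0.0,
) -> tuple[Iterator[ImageGrid], GroundTruthTrajectory]:
    """Streaming renderer: yields frames one at a time.

    The ground-truth trajectory is computed up front (it is cheap); the
    frame iterator draws noise from a generator seeded with ``seed`` so a
    fixed seed gives bit-identical output.  Use this for long sequences
    so only one frame is in memory at a time.
    """
    if fps <= 0 or duration_s <= 0:
        raise ValueError("fps and duration_s must be positive")
    truth = _trajectory(scene, motion, fps, duration_s, step_size_mm)
    truth.seed = seed
    n = truth.n_frames
    drift = scene.illumination_drift

    def frames() -> Iterator[ImageGrid]:
        rng = np.random.default_rng(seed)
        for k in range(n):
            t = truth.timestamps_s[k]
            disp = [truth.displacement_mm[i][k] for i in range(len(scene.markers))]
            illum = 1.0 if drift is None else float(drift[k % len(drift)])
            frame, _ = render_frame(scene, disp, t, rng=rng, illumination=illum)
            yield frame

    return frames(), truth


def render_sequence(
    scene: PhantomScene,
    motion: MotionModelParams | SegmentedMotion,
    fps: float,
    duration_s: float,
    seed: int = 0,
    step_size_mm: float = 0.0,
) -> tuple[list[ImageGrid], GroundTruthTrajectory]:
    """Render a full phantom sequence into memory.

    Identical seeds produce bit-identical frames.  For long sequences
    prefer :func:`iter_rendered`, which streams frames.
    """
    frame_iter, truth = iter_rendered(
        scene, motion, fps, duration_s, seed=seed, step_size_mm=step_size_mm
    )
    return list(frame_iter), truth
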