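# Methods

## Motion model

The phantom emulates a marker on an arm rotated by a stepper motor from
the horizontal plane to vertical and back, with short stops at each
extremum. With breathing frequency `f` (breaths/min), period
`T = 60/f`, pause duration `p` (s) and amplitude `a` (mm), each cycle is

- a rise `d(t) = a·sin((π/2)·t/r)` over `r = (T − 2p)/2` seconds
  (constant angular speed, 0→90°),
- a plateau at `a` for `p` seconds (end-inhale pause),
- the time-mirrored fall over `r` seconds,
- a plateau at 0 for `p` seconds (end-exhale pause).

The law is exactly periodic and bounded in `[0, a]`. Its instantaneous
peak speed is `aπ/(2r)`; the simpler envelope `2fa` (50 mm/s at
30 bpm / 50 mm) is used to rate scenarios against the tracker's design
capacity, and the two are related by the factor `(π/2)/(1 − 2p/T)`.
Where the exact waveform between the stated anchor points (90° rotation,
plateau-topped cycles) was open, the constant-angular-speed
quarter-sine was chosen as the most direct reading of the mechanics; it
is the same functional form the fitting routine uses. Optional stepper
quantization rounds the displacement to a configurable step; the ground
truth then records the quantized (actual) position.

Variable breathing is modelled by concatenating whole cycles of
different parameter sets (`SegmentedMotion`); since every cycle starts
and ends at baseline the composite trajectory is continuous.

## Rendering and what it does (not) emulate

Frames are float64 intensities in [0, 1]. Markers are discs or squares;
squares use exact analytic pixel-coverage anti-aliasing (the coverage
integral is separable), discs a 4×4 supersample. Additive Gaussian
sensor noise (default SD 0.01 ≈ 1% of full scale, a realistic webcam
noise floor at good lighting) is drawn from a seeded generator, so a
fixed seed reproduces every frame bit for bit. A per-frame
multiplicative illumination sequence can emulate slow lighting drift.
The default scene is desk-scale: image dimensions are derived from the
motion amplitude, marker size and pixel scale with a 4 mm margin,
standing in for a camera framed on the monitored region.

The simulator does **not** emulate: optical blur / defocus, H.264
compression artefacts, rolling shutter, perspective foreshortening,
marker deformation on soft tissue, shadows, or frame-time jitter.
Passing the phantom benchmarks therefore demonstrates correctness and
numerical accuracy of the tracking chain under controlled conditions —
not performance on clinical video, where contrast, lighting and tissue
deformation dominate the error budget. Consistent with that, the
tracking errors measured here (≈0.01 mm) are much smaller than what a
physical camera system reports (≈0.15 mm mean); the phantom bounds are
upper bounds the implementation must stay under.

## Detection and feature selection

Thresholding uses Otsu's method by default (fixed threshold
configurable), connected components from `scipy.ndimage.label`, and
area/contrast filters. Centroids are intensity-weighted means with the
local background (mean outside the component within a 2 px-dilated
bounding box) subtracted, which makes the anti-aliased rim contribute
correctly; noiseless disc centroids agree with ground truth to well
under 0.05 px. Candidates are ordered by (y, x) for determinism.

The Shi-Tomasi score is the closed-form minimum eigenvalue of the
structure tensor over a 7×7 window (half-width 3), with
central-difference gradients and border replication. Per marker, up to
4 points above `quality_level = 0.2` of the marker's best score are
kept, with 7 px non-maximum suppression (ties break toward lower
(y, x)). Because the integer score peak of a step corner sits ~2–3 px
inside the true edge intersection, selected points are refined to
sub-pixel accuracy by solving the gradient-orthogonality normal
equations (every gradient in a window around the true corner is
perpendicular to its offset from the corner); on rendered squares this
lands within ~0.15 px of the geometric corner. Markers that yield no
usable point are reported explicitly, never dropped.

## Tracking

Pyramids use a 5-tap binomial low-pass followed by 2× decimation
(dimensions `ceil(prev/2)`, top level ≥ 16 px). The Lucas-Kanade solve
at one level samples the previous frame's window and gradients once
(classical LK: gradients are not recomputed per iteration), then
iterates `v ← v + G⁻¹ b` with the temporal difference resampled
bilinearly at the current estimate, stopping at a 0.01 px update or 30
iterations. Windows are 15×15 (half-width 7) by default; a solve is
declared non-converged when the structure tensor's minimum eigenvalue
per window pixel falls below 1e−4. Coarse-to-fine chaining doubles the
flow between levels; 3 levels with a 15×15 window comfortably cover the
~20 px/frame inter-frame motion of the fastest benchmark scenario.

Points are tracked by chaining frame pairs; a point whose estimate
leaves the frame margin is `lost`, a non-converging solve is `failed`,
and either state is terminal. The marker position is the per-axis
median over its surviving points (robust to a single drifting corner).
If every point terminates, the result carries an explicit `all_lost`
flag. Frames are consumed from an iterator and only one pyramid pair is
held in memory, so hour-long sequences run in constant memory.

## Calibration

A single scalar px/mm scale converts image displacements to
millimetres: the marker plane is treated as fronto-parallel at 2–4 m,
an approximation consistent with quoting one resolution figure for the
whole field. The axis map assigns image axes to signed anatomical axes
(lateral camera default: x → SI, y → −AP so anterior motion is
positive). Radial distortion `x_d = x_u(1 + k1 r² + k2 r⁴)` is
supported but defaults to zero (no coefficients are assumed);
undistortion inverts the model by fixed-point iteration to 1e−8 px and
raises after 50 iterations.

## Failure criteria

With ground truth, the error vector `e_t` (computed − true, mm) drives
two criteria: a **step** failure when `|e_t − e_{t−1}|` exceeds 0.5 mm
(consecutive flagged frames merge into one event, so a single-frame
glitch is one event) and a **drift** failure when `|e_t|` crosses 1 mm
upward (one event per excursion). The drift criterion reads the
"excessive long-term drift" threshold as *exceeding* 1 mm; both
thresholds are configurable. Without ground truth the step criterion is
not evaluable; live mode degrades to flagging per-frame jumps above a
design speed envelope (default 120 mm/s, ≈ the instantaneous peak speed
of the worst-case pattern with pauses), which is documented as a
surrogate rather than an equivalent.

## Modified-sine fitting

`fit_modified_sine` performs bounded least squares (`scipy`'s
trust-region reflective) over amplitude, frequency, pause, phase and a
constant offset, with the constraint `T > 2p` enforced by a residual
penalty. The phase landscape is multimodal, so the fit restarts from 8
phase offsets spread over one period and keeps the lowest cost. The
initial guess takes the frequency from the dominant FFT peak and the
amplitude from the 5th–95th percentile range. R² is the standard
coefficient of determination against the trace mean; RMSE is in mm.
On noiseless traces across 10–30 bpm, 2–50 mm and 0–330 ms pauses the
recovered frequency and amplitude are within 1% of truth.

## Benchmark scenarios and problem sizes

- Reference accuracy run: 30 bpm, 330 ms pauses, 25 mm amplitude,
  10 px/mm, 30 fps, 60 s (1,800 frames), noise SD 0.01.
- Robustness sweep: 10–30 bpm at 50 mm amplitude (the 2fa design
  envelope reaches 5 cm/s at 30 bpm), rendered at 5 px/mm so the 50 mm
  sweep stays in a desk-scale frame; 20 s per rate.
- Variable-breathing SI run: 40 s (1,200 frames) alternating ~10 s
  segments of 12 bpm / 20 mm and 25 bpm / 5 mm, motion mapped to the
  superior–inferior image axis at 10 px/mm.

These sizes keep a full validation to a few CPU-minutes while every
statistic remains stable to well below its acceptance margin. Gating is
amplitude-only (phase gating is out of scope), and hardware concerns —
capture latency, camera timing, multi-camera fusion — are outside the
package: timestamps are derived from a constant frame rate.

## Known limitations

- Chained frame-pair tracking accumulates a random-walk drift on real
  video; on the periodic, low-noise phantom it is negligible, and the
  drift failure criterion is the guard in deployment.
- Brightness-constancy LK degrades under fast illumination change; the
  renderer's illumination drift exists to probe this, but no
  photometric normalization is implemented.
- The scalar-scale camera model ignores perspective and assumes motion
  in the marker plane.
- Marker detection assumes markers are the brightest (or darkest)
  compact high-contrast objects in view; clutter rejection beyond
  area/contrast filters is not attempted.
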