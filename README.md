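# resptrack

Optical tracking of skin fiducial markers for respiratory motion
monitoring, with a digital breathing-phantom simulator.

## The problem

Thoracic radiotherapy must cope with breathing: chest and breast motion
of a centimetre or more moves the target during irradiation. Amplitude
gating — pausing the beam when a surface surrogate moves beyond a
threshold — needs a monitoring system that reports surface motion in
millimetres, in real time, with sub-millimetre accuracy. `resptrack`
implements the computer-vision core of such a system: high-contrast
markers placed on the skin are located in a video stream, corner points
on each marker are tracked frame to frame at sub-pixel resolution, and
pixel trajectories are calibrated into anatomical millimetres
(anteroposterior / superior–inferior / left–right) to drive displacement
traces, gating alerts and failure detection.

Because validating such a tracker requires ground truth no camera can
provide, the package also ships a digital phantom: a simulator of a
stepper-driven mechanical thorax phantom whose marker moves through a
"modified sine" breathing law and that records the exact sub-pixel
marker position for every rendered frame.

## The algorithms

- **Motion model.** The phantom marker rides an arm rotating at
  constant angular speed from 0° to 90°, so its displacement is
  `d(t) = a·sin(θ(t))` — a quarter-sine rise over
  `r = (T − 2p)/2` seconds (period `T = 60/f`, pause `p`), a plateau at
  the amplitude `a`, the mirrored fall, and a baseline pause. The
  worst-case design speed is `2fa` (5 cm/s at f = 30/min, a = 5 cm).
- **Detection.** Intensity thresholding (Otsu by default) + connected
  components + area/contrast filters; sub-pixel centroids by
  intensity-weighted means.
- **Feature selection.** Shi-Tomasi corners: the minimum eigenvalue
  `λ_min = tr/2 − √((tr/2)² − det)` of the structure tensor
  `G = Σ_w ∇I ∇Iᵀ`, with non-maximum suppression and sub-pixel corner
  refinement.
- **Tracking.** Pyramidal Lucas-Kanade: iterative solution of
  `G v = b` per window with bilinear sampling, coarse-to-fine through a
  binomial image pyramid; per-marker position is the median over its
  feature points.
- **Calibration.** Scalar px/mm scale plus the radial distortion model
  `x_d = x_u(1 + k1 r² + k2 r⁴)` inverted by fixed-point iteration.
- **Analysis.** Displacement from the initial location, amplitude
  gating, failure events (long-term drift > 1 mm, per-frame
  computed-vs-actual step discrepancy > 0.5 mm), least-squares
  modified-sine fits with R² and RMSE, and per-frame discrepancy across
  multiple markers.

## Worked example

```sh
python examples/02_track_phantom.py
```

renders 20 s of the benchmark scenario (30 bpm, 330 ms respiratory
pauses, 25 mm amplitude at 10 px/mm, 30 fps, mild sensor noise), tracks
it, and prints:

```
frames tracked:      600
mean |error|:        0.0028 mm   (computed vs true AP position)
max  |error|:        0.0073 mm
error SD:            0.0021 mm
failure events:      0

modified-sine fit:   R^2 = 1.000000, RMSE = 0.0020 mm
recovered motion:    30.00 bpm, 25.00 mm amplitude, 330 ms pauses
```

Mean and maximum errors are the per-frame differences between the
tracked marker position and the renderer's exact ground truth, in
millimetres on the anteroposterior axis; the fit line shows that the
tracked trajectory is indistinguishable from the commanded breathing
pattern and that its parameters are recovered essentially exactly. The
other example scripts cover the motion law itself, multi-marker
discrepancy + gating, and millimetre calibration.

A thin CLI wraps the same pipeline:

```sh
resptrack simulate --bpm 30 --amplitude-mm 25 --pause-ms 330 --duration-s 10 --out out/sim
resptrack track --input out/sim/frames --fps 30 --px-per-mm 10 --out out/tracked
resptrack analyze --traces out/tracked/traces.csv --gate-threshold-mm 5 --out out/analysis
resptrack validate --duration-s 20 --seed 0
```

`validate` exits non-zero when tracking accuracy, sine-fit quality or
the failure criteria are violated.

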