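# Methods

This note documents the models, conventions, numerical choices and
limitations behind `planegaze`, in the order the pipeline applies them.

## Coordinate conventions

Pixel coordinates are 0-based with the origin at the image's top-left
corner, x right, y down. Plane coordinates are in millimetres, x right,
y down (image-like, so a fronto-parallel view has aligned axes), origin
at the centre of the plane's bounding box, and z = x × y completing a
right-handed frame. A `Pose` maps plane-frame points to the camera
frame, `X_cam = R·X_plane + t`; a camera in front of the plane sees the
plane origin at positive camera-frame z (the canonical fronto-parallel
pose is `R = I`, `t = (0, 0, distance)`). Timestamps are seconds
(float) throughout; the gaze-file reader accepts a `time_unit="ms"`
flag for millisecond dialects.

## Camera model

Pinhole intrinsics (fx, fy, cx, cy) with Brown–Conrady distortion
(radial k1, k2, k3; tangential p1, p2). All-zero distortion reduces
every operation exactly to the linear pinhole formulas — this is an
enforced contract, not an approximation. Distortion is inverted by
fixed-point iteration on normalised coordinates (tolerance 1e-10, at
most 50 iterations); non-convergence signals a point outside the
invertible region. Fisheye/omnidirectional models and rolling-shutter
effects are out of scope.

## Gaze-to-plane mapping

Both mapping routes consume the same per-frame correspondences: the
four corners of every fully visible marker of a plane, matched to the
marker's known mm geometry (corner order top-left, top-right,
bottom-right, bottom-left, rotated in-plane and translated). A frame
yields geometry only when at least `min_markers` (default 3) of the
plane's markers are detected — pose from fewer markers, especially a
single one, is unreliable, and a single-marker observation (when
explicitly configured) is flagged `ambiguous pose risk`.

**Homography route.** Hartley-normalised DLT via SVD; when a
calibration with distortion is available, pixels are undistorted first
(this widens applicability without changing the distortion-free
contract). The smallest-but-one singular value is checked against a
relative 1e-12 floor to reject degenerate (e.g. collinear)
configurations. The reprojection RMS is reported on the result.

**Pose route (planar PnP).** The plane-to-normalised-image homography
is decomposed into an initial pose (columns r1, r2 scaled by the mean
inverse column norm, r3 = r1 × r2, projected onto SO(3) by SVD; the
sign is fixed so the plane origin lies in front of the camera). Planar
targets admit a second interpretation whose plane normal is the
reflection of the first about the line of sight; both branches are
refined by Levenberg–Marquardt on pixel reprojection error
(`scipy.optimize.least_squares`, xtol = ftol = 1e-15) and the lower-RMS
solution wins. When the first branch already fits to < 1e-8 px RMS the
alternative cannot tie and only its initial residual is evaluated. A
tie within 1% relative RMS is flagged `ambiguous` rather than silently
resolved. Gaze is then mapped by intersecting the undistorted,
back-projected pixel ray with the plane z = 0; rays within 1e-9 of
parallel, or intersections behind the camera, are rejected.

With `method="auto"` the pose route is preferred whenever a
calibration exists (it handles distortion and supports angular
measures); the homography route is the uncalibrated fallback. On
distortion-free synthetic data the two agree to better than 1e-3 mm.

Gaze samples are associated to video frames by nearest timestamp (ties
to the earlier frame); samples more than one median frame interval
outside the frame range stay unassociated. Frames without geometry
produce `valid=False` samples — geometry is deliberately *not*
interpolated across frames, since head motion between observed frames
is unconstrained.

The inverse transform (plane → pixels of another camera) pairs each
sample with the other camera's nearest frame in reference time and
applies that frame's pose projection (or inverse homography when the
other camera is uncalibrated).

## VOR latency estimation

The estimator automates what is traditionally a manual alignment. Both
the gaze track and the target's image track (the plane's centre target
projected through each frame's geometry) are resampled to a uniform
grid at the higher of their native rates, linearly interpolating across
gaps of at most 0.1 s. For each candidate shift on a ±1 s grid with
1 ms steps, the Pearson correlations of the x and y channels between
the shifted gaze and the target are averaged; the arg-max is refined by
a parabolic fit through the three top grid points. The returned offset
is the amount *added* to gaze timestamps.

With a T-periodic oscillation the correlation is T-periodic too, so the
search window must not exceed T/2; this is enforced against the target
signal's dominant periodogram frequency with 5% slack for bin
quantisation. Episodes with fewer than two oscillation cycles or a peak
correlation below 0.5 return a result flagged unreliable instead of
failing silently; a manually determined offset can always be applied
with `apply_gaze_time_offset` as an override. Correlation is computed
in scene-video pixels (both signals live on the scene camera).

## Multi-recording clock model

Each recording is mapped to the reference recording by the affine model
t_ref = a·t + b. Transient times are the first frame of each detected
transient episode — the transient must be abrupt for this to be sharp.
One shared transient gives a = 1 and a pure offset; two or more give
the least-squares line, whose slope captures clock-rate drift (|a−1| >
1e-3 raises a drift warning; the generalisation beyond two transients
is a single line, not piecewise). Gaze timestamps pass through the same
model as their recording's video. Spacing transients near the start and
end of the session conditions the slope estimate well; the
implementation reports the fit's residual RMS.

## Data quality

Computed per validation episode on gaze mapped to the validation plane
(nine targets, reading order, centre designated). Valid samples are
labelled with the nearest target in mm, the label sequence is
median-filtered over 5 samples to suppress flicker, and per target the
longest contiguous run of at least `min_samples` (default: 0.3 s worth
at the nominal rate) is kept. This nearest-target/longest-run rule is a
deliberate, fully specified replacement for classifier-based fixation
assignment; it assumes the dwell protocol was followed.

- **Accuracy**: per sample, the 3-D angle between the camera-frame
  directions to the gaze point and to the target; per-target accuracy
  is the *median* over the run (robust to onset/offset samples; the
  mean is the main alternative and would differ slightly on skewed
  runs).
- **Precision**: on the azimuth/elevation representation (azimuth
  atan2(x, z), elevation atan2(y, √(x²+z²)), degrees) so results are
  viewing-distance independent. RMS-S2S = √mean((Δφ)² + (Δθ)²) over
  consecutive pairs; STD = √(var(φ) + var(θ)) with population variance.
  For i.i.d. Gaussian angular noise σ per channel these converge to 2σ
  and σ√2 respectively.
- **Data loss**: 1 − n_received/(duration × expected rate), clamped to
  [0, 1]; non-finite samples count as lost; an unknown rate is
  estimated from the median inter-sample interval and flagged.

The viewing position is the scene-camera optical centre; the offset
between the eye and the head-mounted camera (a few cm) is ignored. At
typical viewing distances this biases angular measures by well under
the measurement noise, but it is a known limitation, and angular
measures require a calibrated camera.

## Setup validation

Errors: a marker id used in more than one plane, shared between a plane
and an individual marker, or an individual marker with two purposes.
Warning: the convex hull of a plane's marker centres covering less than
10% of the plane area ("markers too close together"). The 10% ratio is
a heuristic chosen to flag only near-degenerate layouts and is
configurable; no quantitative marker-size rule is encoded. Only flat
surfaces and in-plane marker rotations are supported.

## Trial segmentation

An individual marker's visibility episodes are maximal runs of frames
containing it, bridging internal gaps of at most `max_gap` (default
0.2 s, tolerant of single-frame detector dropouts) and dropping runs
shorter than `min_duration` (default 0.3 s). A trial runs from the
*end* of a start-marker episode to the *beginning* of the next
end-marker episode — the paddle is removed after presentation, so its
disappearance marks the trial boundary. Interleaving violations
(start-start-end, unpaired episodes) are reported as issues, not
errors. Trial numbers are session-global in reference time.

## Synthetic sessions

The simulator emulates the study conditions end to end and returns all
injected quantities:

- **Plane**: a 4×4 grid of 40 mm markers at 100 mm spacing (bounds
  `cols·spacing + edge`), with the nine-target validation layout.
- **Trajectory**: the default timeline is 2 s settling (with a
  synchronization transient), five 0.5 Hz yaw cycles then five pitch
  cycles at ±20° — the recommended VOR task — a nine-target dwell (1 s
  per target), one paddle-delimited trial, and a closing transient.
  Oscillations are pure rotations of the camera about its optical
  centre while the fixated world point stays put: the idealised VOR
  assumption of perfectly counter-phase eye-in-head movement.
- **Recordings**: by default two eye trackers and one overview camera —
  the largest configuration the tool targets. The second eye tracker
  carries an 80 ms gaze latency (within the observed range for real
  devices) and a clock warp (scale 1.0002, offset −3.2 s); the overview
  camera a warp of (0.9998, +5 s). The camera model is a 1920×1080
  pinhole with fx = fy = 1000 px and no distortion by default, placed
  ~600 mm from the plane (arm's length, per the validation protocol).
- **Detections** are computed analytically: projected marker corners
  plus optional i.i.d. Gaussian pixel noise, with a marker dropped
  whenever any corner leaves the image ("fully in view" rule). Flashed
  transients and trial paddles have no plane geometry; they are emitted
  as nominal image-centred squares, since only their episode timing is
  consumed downstream. No video is rendered — this decouples geometry
  and timing correctness from any particular marker detector, which
  remains a pluggable boundary (`detect_markers(detector=...)`).
- **Gaze**: the projection of the fixated world point through the
  per-sample camera pose, optionally tilted by a constant angle
  (injected inaccuracy; the tilt axis is orthogonal to the gaze
  direction so the angular offset is exact for every target) and
  perturbed by i.i.d. Gaussian angular noise. Gaze timestamps are the
  warped clock minus the injected latency.
- **Default noise**: 0.5 px corner noise and 0.3° gaze noise —
  plausible magnitudes for current devices, clearly placeholders since
  no authoritative values exist. Noise is white; real eye-tracking
  noise is temporally autocorrelated and real detector error depends on
  viewing angle and blur, so passing tests bound geometric and timing
  correctness, not real-device performance. Blinks, data loss and
  occlusion are likewise not simulated (data loss is exercised with
  directly constructed series).
- A fixed seed makes the generated project byte-identical; a
  ground-truth self-consistency assertion (true plane point reprojects
  onto the true pixel to ≤ 1e-9 px before noise) runs on every unique
  geometry during generation.

## Pipeline and file formats

All formats are plain text (TSV for data, TOML for configuration) and
round-trip losslessly. The pipeline steps (`validate-setup`, `detect`,
`code-auto`, `sync`, `map`, `quality`, `export`) are idempotent: a
step's status is a pure function of on-disk artifacts, re-running a
completed step is a no-op unless forced, and a step whose dependencies
have not run fails naming the missing step. The `detect` step verifies
the presence of a detections cache (produced externally by a plugged-in
detector, or by the simulator); per-frame geometry estimation is
memoized on the cache file's identity since several steps consume it.
Episode codings are frame-indexed, matching how a video coder works;
the simulator writes VOR and validation codings, while transients and
trials are auto-coded from individual-marker episodes. Vendor-specific
eye-tracker importers, GUIs, gaze-overlay video rendering, fixation
classification and AOI analysis are out of scope.

## Problem sizes used in tests

The canonical simulated session is 38 s at 50 fps video and 100 Hz
gaze; the drift-recovery session is 612 s at 25 fps with a single-
marker plane (clock fitting needs only transient timing, not plane
geometry); mapping unit tests use shorter static/dwell sessions at
25 fps. These sizes were chosen as the smallest that leave every
estimator in its asymptotic regime (≥ 5 oscillation cycles for VOR,
600 s transient spacing for drift, ≥ 1 s dwells for quality).

## Known limitations

- Viewing position equals the scene-camera centre (no eye offset).
- Single affine clock model per recording (no piecewise drift).
- No geometry interpolation across unobserved frames.
- The VOR estimator assumes the episode is dominated by one oscillation
  frequency; mixed-frequency head motion degrades the window check.
- `(t + offset) − offset` round-trips to ≤ 1 ulp, not bit-identically
  (IEEE-754 addition is not exactly invertible).
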