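# planegaze

World-referenced analysis of wearable eye-tracking data.

Head-mounted eye trackers report gaze as pixel coordinates on a scene
video that moves with the participant's head. Most research questions,
however, are about *where in the world* someone looked — on a screen, a
table, a poster. `planegaze` transforms head-centred gaze onto flat
world surfaces ("planes") delineated by square fiducial markers
(ArUco-style), and handles the timing problems that multi-device
recordings bring with them:

- **Gaze-to-plane mapping.** Per video frame, the marker corners detected
  in the scene image are matched to their known positions on the plane
  (in mm). Two routes map a gaze pixel **g** to plane coordinates:
  - *homography*: a 3×3 projective map **H** with **x**<sub>plane</sub> ∼ **H g**,
    estimated by Hartley-normalised DLT — needs no camera calibration
    when lens distortion is negligible;
  - *pose + ray intersection*: with calibrated intrinsics **K** and
    Brown–Conrady distortion, the planar Perspective-n-Point problem is
    solved for the camera pose (R, t), and the back-projected gaze ray
    is intersected with the plane z = 0.

  The inverse transform draws plane gaze into any other camera's view
  (another participant's scene camera, or an overview camera).
- **Gaze-vs-video synchronisation (VOR).** While a participant fixates a
  world target and oscillates their head (~0.5 Hz, ±20°), the
  vestibulo-ocular reflex keeps gaze on the target with essentially zero
  latency, so the gaze point and the target's image trace the same
  quasi-sinusoid on the scene video. Any lag of the gaze stream is
  recovered as the correlation-maximising time shift between the two
  signals (1 ms grid, parabolic refinement).
- **Multi-recording synchronisation.** Each recording's clock is mapped
  onto a reference recording by t<sub>ref</sub> = a·t + b, fitted from
  shared abrupt visual transients (e.g. a flashed marker). One transient
  fixes the offset; two or more, spaced far apart, also estimate the
  rate a and thereby correct clock drift.
- **Trial segmentation** from appearance episodes of individual markers
  (e.g. a paddle flipped at trial start/end).
- **Data quality** per validation target: angular accuracy, RMS
  sample-to-sample precision and STD precision (degrees, computed from
  the viewing position, i.e. the scene-camera optical centre), plus data
  loss.
- **Synthetic sessions.** A fully ground-truthed simulator generates
  multi-device sessions — camera trajectories, marker detections, VOR-
  obeying gaze, injected latency, clock offset/drift, inaccuracy and
  noise — so the entire toolchain is testable without any recordings.

The package is aimed at researchers analysing wearable eye-tracking
experiments (single or multi-participant, with or without overview
cameras) who want a scripted, inspectable pipeline rather than a GUI.

## Worked example

Generate a synthetic two-participant session (two eye trackers, one
overview camera; the second eye tracker has an 80 ms gaze latency and a
drifting clock) and process it:

```sh
planegaze simulate --project demo --seed 3 --corner-noise 0 --gaze-noise 0
planegaze run --project demo
```

`demo/output/sync_report.tsv` then contains the recovered timing models:

```
recording      a        b  residual_rms  n_pairs  vor_offset  vor_peak_correlation
      et1 1.0000  0.00000           0.0        0        0.00                   1.0
      et2 0.9998  3.19936           0.0        2        0.08                   1.0
      cam 1.0002 -5.00100           0.0        2         NaN                   NaN
```

Reading: `et1` is the reference recording (identity clock model). For
`et2` the injected clock (scale 1.0002, offset −3.2 s) is recovered as
the inverse map a = 1/1.0002 ≈ 0.9998, b = 3.2/1.0002 ≈ 3.19936, and
the injected 80 ms gaze latency appears as `vor_offset = 0.08` s — the
amount added to `et2`'s gaze timestamps before mapping. The overview
camera `cam` has no gaze stream, hence no VOR row entries.

`demo/output/export_et2.tsv` holds that participant's gaze on the
plane, in reference time, with trial numbers (0 = outside all trials):

```
 ref_timestamp recording  trial  plane  x_mm  y_mm method  valid
         -0.00       et2      0 poster   0.0  -0.0   pose   True
          0.01       et2      0 poster   0.0  -0.0   pose   True
```

and `demo/output/data_quality.tsv` the per-target validation measures —
with zero injected inaccuracy and noise, accuracy and precision are 0°
and the viewing distance is the simulated ~626 mm:

```
recording  episode_start_s  episode_end_s target  accuracy_deg  rms_s2s_deg  std_deg  n_samples  data_loss  viewing_distance_mm
      et2          18.8044        27.8062     T1           0.0          0.0      0.0         99     0.0002             625.8594
```

The same functionality is available as a library; see
`planegaze.simulate_session`, `planegaze.run_pipeline`, and the module
docstrings.

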