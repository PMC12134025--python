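"""Synthetic ground-truthed recording sessions.

Generates everything a real multi-device session would provide — scene
camera trajectories, per-frame marker-corner detections, gaze samples
obeying the vestibulo-ocular reflex, episode codings — with every
quantity of interest injected and returned as ground truth:

* a **gaze-vs-video latency** per eye tracker (gaze timestamps lag the
  video by a known amount);
* an affine **clock warp** per recording (scale + offset relative to
  world time) emulating start-time offsets and clock drift;
* shared **visual transients** (a flashed marker visible to all
  cameras at the same world instant);
* **trial paddle** appearances delimiting trials;
* a **validation episode** dwelling on nine poster targets in reading
  order, optionally with a constant angular gaze offset (inaccuracy)
  and angular gaze noise.

Head oscillations are pure rotations of the camera about its optical
centre while the fixated world point stays put — the idealized VOR
head-shake ("no") and nod ("yes") at 0.5 Hz, 20 deg each direction, five
cycles each, as recommended for the synchronization task.  Detections
are computed analytically (projected corners + optional Gaussian pixel
noise, dropped when not fully inside the image); no video rendering is
involved, which decouples geometry and timing correctness from any
particular marker detector.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .camera import (
    CameraCalibration,
    Pose,
    distort_normalized,
    intersect_gaze_ray,
    project_point,
)
from .mapping import MarkerDetection, write_detections
from .planes import (
    IndividualMarker,
    MarkerSpec,
    PlaneDefinition,
    TargetPoint,
    marker_corners_mm,
    save_plane_definition,
)

__all__ = [
    "SimRecording",
    "Segment",
    "SimulationSpec",
    "GroundTruth",
    "make_default_plane",
    "default_spec",
    "simulate_session",
    "TRIAL_START_ID",
    "TRIAL_END_ID",
    "SYNC_MARKER_ID",
]

TRIAL_START_ID = 80
TRIAL_END_ID = 81
SYNC_MARKER_ID = 90


# --------------------------------------------------------------------------
# spec
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SimRecording:
    """One simulated device: an eye tracker or an overview camera."""

    id: str
    role: str = "eye_tracker"           # "eye_tracker" | "overview_camera"
    camera_position: tuple[float, float, float] = (0.0, 0.0, -600.0)  # plane mm
    latency: float = 0.0                # s; gaze timestamps lag the video
    clock_scale: float = 1.0            # t_rec = scale * t_world + offset
    clock_offset: float = 0.0
    oscillates: bool = True             # head oscillation segments apply


@dataclass(frozen=True)
class Segment:
    """A piece of the session timeline.

    ``kind`` is one of ``static`` (fixate plane centre), ``yaw`` /
    ``pitch`` (head oscillation about the camera centre while fixating
    the plane centre), ``dwell`` (head static, gaze visits each plane
    target in reading order for ``dwell_s`` seconds).
    """

    kind: str
    duration: float
    amplitude_deg: float = 20.0
    frequency_hz: float = 0.5
    dwell_s: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("static", "yaw", "pitch", "dwell"):
            raise ValueError(f"unknown segment kind {self.kind!r}")
        if self.duration <= 0:
            raise ValueError("segment duration must be positive")
        if abs(self.amplitude_deg) >= 80:
            raise ValueError("oscillation amplitude must be < 80 deg")


@dataclass(frozen=True)
class SimulationSpec:
    """Full description of a synthetic session; the seed fixes all noise."""

    plane_rows: int = 4
    plane_cols: int = 4
    marker_edge_mm: float = 40.0
    marker_spacing_mm: float = 100.0
    calib: CameraCalibration = field(
        default_factory=lambda: CameraCalibration(
            fx=1000.0, fy=1000.0, cx=960.0, cy=540.0, w=1920, h=1080
        )
    )
    segments: tuple[Segment, ...] = ()
    gaze_rate_hz: float = 100.0
    video_fps: float = 50.0
    transient_times: tuple[float, ...] = ()      # world s, each shown 0.3 s
    transient_duration: float = 0.3
    trial_paddle_times: tuple[tuple[float, float], ...] = ()  # (start_show, end_show)
    paddle_duration: float = 0.4
    corner_noise_px: float = 0.5
    gaze_noise_deg: float = 0.3
    gaze_offset_deg: float = 0.0                 # constant azimuthal inaccuracy
    recordings: tuple[SimRecording, ...] = ()
    reference: str = "et1"
    session_name: str = "synthetic"
    seed: int = 0

    @property
    def duration(self) -> float:
        return sum(s.duration for s in self.segments)


def make_default_plane(
    rows: int = 4,
    cols: int = 4,
    edge: float = 40.0,
    spacing: float = 100.0,
    family: str = "4x4_50",
    with_targets: bool = True,
    name: str = "poster",
    first_id: int = 1,
) -> PlaneDefinition:
    """A rows x cols marker grid centred on the plane origin.

    Marker ids are sequential starting at ``first_id``; plane bounds are
    ``cols*spacing + edge`` by ``rows*spacing + edge`` (one spacing per
    marker column plus an edge-width margin).  ``with_targets`` adds the
    nine-point validation layout (reading order, centre designated).
    """
    if rows < 1 or cols < 1:
        raise ValueError("rows and cols must be >= 1")
    xs = (np.arange(cols) - (cols - 1) / 2.0) * spacing
    ys = (np.arange(rows) - (rows - 1) / 2.0) * spacing
    markers = tuple(
        MarkerSpec(first_id + r * cols + c, edge, (float(xs[c]), float(ys[r])), 0.0, family)
        for r in range(rows)
        for c in range(cols)
    )
    targets: tuple[TargetPoint, ...] = ()
    if with_targets:
        span = max((cols - 1), (rows - 1)) * spacing / 2.0 * 0.75
        coords = [-span, 0.0, span]
        targets = tuple(
            TargetPoint(f"T{r * 3 + c + 1}", coords[c], coords[r], is_center=(r == c == 1))
            for r in range(3)
            for c in range(3)
        )
    return PlaneDefinition(
        name=name,
        markers=markers,
        width=cols * spacing + edge,
        height=rows * spacing + edge,
        targets=targets,
    )


def default_spec(seed: int = 0, **overrides) -> SimulationSpec:
    """The canonical study conditions: 2 eye trackers + 1 overview camera.

    Timeline: 2 s settling with a synchronization transient, the VOR
    task (five 0.5 Hz yaw cycles then five pitch cycles at ±20 deg), the
    nine-target validation dwell, one demonstration trial delimited by
    paddle markers, and a closing transient.
    """
    segments = (
        Segment("static", 2.0),
        Segment("yaw", 10.0, amplitude_deg=20.0, frequency_hz=0.5),
        Segment("pitch", 10.0, amplitude_deg=20.0, frequency_hz=0.5),
        Segment("dwell", 9.0, dwell_s=1.0),
        Segment("static", 7.0),
    )
    recordings = (
        SimRecording("et1", "eye_tracker", (0.0, 0.0, -600.0)),
        SimRecording(
            "et2", "eye_tracker", (80.0, -30.0, -620.0),
            latency=0.08, clock_scale=1.0002, clock_offset=-3.2,
        ),
        SimRecording(
            "cam", "overview_camera", (250.0, -150.0, -900.0),
            clock_scale=0.9998, clock_offset=5.0, oscillates=False,
        ),
    )
    spec = SimulationSpec(
        segments=segments,
        transient_times=(0.6, 36.8),
        trial_paddle_times=((31.5, 34.5),),
        recordings=recordings,
        seed=seed,
    )
    return replace(spec, **overrides) if overrides else spec


# --------------------------------------------------------------------------
# ground truth
# --------------------------------------------------------------------------

@dataclass
class RecordingTruth:
    frame_world_times: np.ndarray
    frame_rec_times: np.ndarray
    poses: list[Pose]
    gaze_world_times: np.ndarray | None = None
    gaze_rec_times: np.ndarray | None = None
    true_gaze_px: np.ndarray | None = None       # pre-noise pixel
    true_plane_point: np.ndarray | None = None   # mm; where the gaze ray hits
    fixation_point: np.ndarray | None = None     # mm; the intended target
    detections: list = field(default_factory=list)
    noisy_gaze_px: np.ndarray | None = None


@dataclass
class GroundTruth:
    spec: SimulationSpec
    plane: PlaneDefinition
    recordings: dict[str, RecordingTruth]
    transient_world_times: tuple[float, ...]
    trial_world_intervals: tuple[tuple[float, float], ...]
    validation_window: tuple[float, float] | None
    vor_window: tuple[float, float] | None
    dwell_schedule: tuple[tuple[str, float, float], ...]


# --------------------------------------------------------------------------
# kinematics
# --------------------------------------------------------------------------

def _look_at(C: np.ndarray, target: np.ndarray) -> Pose:
    """Camera pose with optical axis through ``target``, y roughly plane-down."""
    z = target - C
    z = z / np.linalg.norm(z)
    x = np.cross(np.array([0.0, 1.0, 0.0]), z)
    x = x / np.linalg.norm(x)
    y = np.cross(z, x)
    R = np.vstack([x, y, z])
    return Pose(R, -R @ C)


def _rot(axis: str, angle_rad: float) -> np.ndarray:
    c, s = math.cos(angle_rad), math.sin(angle_rad)
    if axis == "y":  # yaw: about the camera's down axis
        return np.array([[c, 0.0, -s], [0.0, 1.0, 0.0], [s, 0.0, c]])
    return np.array([[1.0, 0.0, 0.0], [0.0, c, s], [0.0, -s, c]])  # pitch


class _Trajectory:
    """Resolves camera pose and fixation point at any world time."""

    def __init__(self, spec: SimulationSpec, plane: PlaneDefinition):
        self.spec = spec
        self.plane = plane
        self.bounds: list[tuple[float, float, Segment]] = []
        t = 0.0
        for seg in spec.segments:
            self.bounds.append((t, t + seg.duration, seg))
            t += seg.duration
        self.targets = list(plane.targets) or [plane.center_target()]

    def _segment(self, t: float) -> tuple[float, Segment]:
        for t0, t1, seg in self.bounds:
            if t0 <= t < t1:
                return t0, seg
        t0, t1, seg = self.bounds[-1]
        return t0, seg

    def head_angle(self, t: float) -> tuple[str, float]:
        t0, seg = self._segment(t)
        if seg.kind in ("yaw", "pitch"):
            a = math.radians(seg.amplitude_deg) * math.sin(
                2 * math.pi * seg.frequency_hz * (t - t0)
            )
            return ("y" if seg.kind == "yaw" else "x"), a
        return "y", 0.0

    def fixation(self, t: float) -> np.ndarray:
        t0, seg = self._segment(t)
        if seg.kind == "dwell":
            k = min(int((t - t0) / seg.dwell_s), len(self.targets) - 1)
            tgt = self.targets[k]
            return np.array([tgt.x, tgt.y])
        c = self.plane.center_target()
        return np.array([c.x, c.y])

    def dwell_schedule(self) -> tuple[tuple[str, float, float], ...]:
        out = []
        for t0, t1, seg in self.bounds:
            if seg.kind == "dwell":
                for k, tgt in enumerate(self.targets):
                    s = t0 + k * seg.dwell_s
                    e = min(s + seg.dwell_s, t1)
                    if s < t1:
                        out.append((tgt.name, s, e))
        return tuple(out)

    def pose(self, rec: SimRecording, t: float) -> Pose:
        C = np.asarray(rec.camera_position, dtype=float)
        base = _look_at(C, np.zeros(3))
        if rec.oscillates and rec.role == "eye_tracker":
            axis, ang = self.head_angle(t)
            if ang != 0.0:
                R = _rot(axis, ang) @ base.R
                return Pose(R, -R @ C)
        return base


# --------------------------------------------------------------------------
# generation
# --------------------------------------------------------------------------

def _nominal_square(calib: CameraCalibration, size: float = 120.0) -> np.ndarray:
    cx, cy, e = calib.cx, calib.cy, size / 2.0
    return np.array([[cx - e, cy - e], [cx + e, cy - e], [cx + e, cy + e], [cx - e, cy + e]])


def _project_gaze_px(
    F: np.ndarray, pose: Pose, calib: CameraCalibration,
    offset_rad: float,
) -> np.ndarray:
    """Pixel of the gaze direction to plane point F, tilted by a fixed angle.

    The inaccuracy offset rotates the gaze direction about an axis
    orthogonal to it (horizontal shift), so the angle between the true
    and offset directions equals ``offset_rad`` exactly for any target.
    """
    v = pose.R @ np.array([F[0], F[1], 0.0]) + pose.t
    if offset_rad:
        axis = np.cross(np.array([0.0, 1.0, 0.0]), v)
        axis = axis / np.linalg.norm(axis)
        c, s = math.cos(offset_rad), math.sin(offset_rad)
        K = np.array([[0, -axis[2], axis[1]],
                      [axis[2], 0, -axis[0]],
                      [-axis[1], axis[0], 0]])
        v = (np.eye(3) + s * K + (1 - c) * (K @ K)) @ v
    if v[2] <= 0:
        raise ValueError("fixated point behind camera")
    xy = v[:2] / v[2]
    if calib.has_distortion:
        xy = distort_normalized(xy, calib)
    return np.array([calib.fx * xy[0] + calib.cx, calib.fy * xy[1] + calib.cy])


def simulate_session(
    spec: SimulationSpec, project_dir=None
) -> GroundTruth:
    """Generate a session; optionally write it as a ready-to-process project.

    When ``project_dir`` is given, writes ``session.toml``, the plane
    definition, and per recording ``frames.tsv``, ``detections.tsv``,
    ``coding.tsv``, ``calibration.txt`` and (eye trackers) ``gaze.tsv``,
    plus ``ground_truth.json`` with the injected scalars.  Identical
    spec (including seed) yields byte-identical files.
    """
    if not spec.segments:
        raise ValueError("spec has no trajectory segments")
    if not spec.recordings:
        raise ValueError("spec has no recordings")
    if spec.reference not in {r.id for r in spec.recordings}:
        raise ValueError(f"reference recording {spec.reference!r} not in spec")

    rng = np.random.default_rng(spec.seed)
    plane = make_default_plane(
        spec.plane_rows, spec.plane_cols, spec.marker_edge_mm, spec.marker_spacing_mm
    )
    traj = _Trajectory(spec, plane)
    T = spec.duration
    frame_world = np.arange(0.0, T, 1.0 / spec.video_fps)

    # marker visibility windows for individual markers, world time
    windows: list[tuple[int, float, float]] = [
        (SYNC_MARKER_ID, t, t + spec.transient_duration) for t in spec.transient_times
    ]
    trial_world: list[tuple[float, float]] = []
    for s_show, e_show in spec.trial_paddle_times:
        windows.append((TRIAL_START_ID, s_show, s_show + spec.paddle_duration))
        windows.append((TRIAL_END_ID, e_show, e_show + spec.paddle_duration))
        trial_world.append((s_show + spec.paddle_duration, e_show))

    vor_win = None
    val_win = None
    t_acc = 0.0
    for seg in spec.segments:
        if seg.kind in ("yaw", "pitch"):
            vor_win = (vor_win[0], t_acc + seg.duration) if vor_win else (
                t_acc, t_acc + seg.duration)
        if seg.kind == "dwell":
            val_win = (t_acc, t_acc + seg.duration)
        t_acc += seg.duration

    truths: dict[str, RecordingTruth] = {}
    marker_corners_all = [(m.marker_id, marker_corners_mm(m)) for m in plane.markers]
    for rec in spec.recordings:
        rec_times = rec.clock_scale * frame_world + rec.clock_offset

        # geometry repeats exactly across static stretches and oscillation
        # cycles, so poses and projected corners are cached per unique
        # head angle; noise is still drawn fresh per frame
        geom_cache: dict[tuple, tuple[Pose, list[tuple[int, np.ndarray]]]] = {}

        def frame_geometry(t: float):
            axis, ang = traj.head_angle(t)
            key = (axis, round(ang, 12))
            if key in geom_cache:
                return geom_cache[key]
            pose = traj.pose(rec, t)
            visible: list[tuple[int, np.ndarray]] = []
            for mid, corners_mm in marker_corners_all:
                try:
                    px = project_point(corners_mm, pose, spec.calib)
                except Exception:
                    continue
                if (px[:, 0] < 0).any() or (px[:, 0] >= spec.calib.w).any() \
                        or (px[:, 1] < 0).any() or (px[:, 1] >= spec.calib.h).any():
                    continue  # markers count only when fully in view
                visible.append((mid, px))
            geom_cache[key] = (pose, visible)
            return geom_cache[key]

        poses: list[Pose] = []
        dets: list[MarkerDetection] = []
        for fi, tw in enumerate(frame_world):
            trec = float(rec_times[fi])
            pose, visible = frame_geometry(float(tw))
            poses.append(pose)
            for mid, px in visible:
                if spec.corner_noise_px > 0:
                    px = px + rng.normal(0.0, spec.corner_noise_px, px.shape)
                dets.append(MarkerDetection(fi, trec, mid, px))
            for mid, w0, w1 in windows:
                if w0 <= tw < w1:
                    sq = _nominal_square(spec.calib)
                    if spec.corner_noise_px > 0:
                        sq = sq + rng.normal(0.0, spec.corner_noise_px, sq.shape)
                    dets.append(MarkerDetection(fi, trec, mid, sq))

        rt = RecordingTruth(
            frame_world_times=frame_world,
            frame_rec_times=np.asarray(rec_times),
            poses=poses,
        )

        if rec.role == "eye_tracker":
            gw = np.arange(0.0, T, 1.0 / spec.gaze_rate_hz)
            true_px = np.empty((len(gw), 2))
            true_pp = np.empty((len(gw), 2))
            fix = np.empty((len(gw), 2))
            az_off = math.radians(spec.gaze_offset_deg)
            gaze_cache: dict[tuple, tuple[np.ndarray, np.ndarray]] = {}
            for i, t in enumerate(gw):
                F = traj.fixation(t)
                axis, ang = traj.head_angle(t)
                key = (axis, round(ang, 12), float(F[0]), float(F[1]))
                if key not in gaze_cache:
                    pose = traj.pose(rec, t)
                    px_i = _project_gaze_px(F, pose, spec.calib, az_off)
                    pp_i = intersect_gaze_ray(px_i, pose, spec.calib)
                    # ground-truth self-consistency: plane point reprojects to pixel
                    check = project_point(pp_i, pose, spec.calib)
                    assert np.max(np.abs(check - px_i)) <= 1e-9, \
                        "ground-truth projection identity violated"
                    gaze_cache[key] = (px_i, pp_i)
                fix[i] = F
                true_px[i], true_pp[i] = gaze_cache[key]
            noisy_px = true_px.copy()
            if spec.gaze_noise_deg > 0:
                sigma_px = np.array([spec.calib.fx, spec.calib.fy]) * math.tan(
                    math.radians(spec.gaze_noise_deg)
                )
                noisy_px = noisy_px + rng.normal(0.0, 1.0, noisy_px.shape) * sigma_px
            g_rec = rec.clock_scale * gw + rec.clock_offset - rec.latency
            rt.gaze_world_times = gw
            rt.gaze_rec_times = g_rec
            rt.true_gaze_px = true_px
            rt.true_plane_point = true_pp
            rt.fixation_point = fix
            rt.noisy_gaze_px = noisy_px
        rt.detections = dets
        truths[rec.id] = rt

        if project_dir is not None:
            _write_recording(
                Path(project_dir), rec, spec, plane, dets, rt, rt.noisy_gaze_px,
                frame_world, vor_win, val_win,
            )

    gt = GroundTruth(
        spec=spec,
        plane=plane,
        recordings=truths,
        transient_world_times=spec.transient_times,
        trial_world_intervals=tuple(trial_world),
        validation_window=val_win,
        vor_window=vor_win,
        dwell_schedule=traj.dwell_schedule(),
    )
    if project_dir is not None:
        _write_project_files(Path(project_dir), spec, plane, gt)
    return gt


# --------------------------------------------------------------------------
# file output
# --------------------------------------------------------------------------

def _world_window_to_frames(win, frame_world) -> tuple[int, int]:
    idx = np.nonzero((frame_world >= win[0]) & (frame_world <= win[1]))[0]
    return int(idx[0]), int(idx[-1])


def _write_recording(
    root: Path, rec: SimRecording, spec: SimulationSpec, plane, dets, rt,
    noisy_px, frame_world, vor_win, val_win,
) -> None:
    d = root / "recordings" / rec.id
    d.mkdir(parents=True, exist_ok=True)

    with open(d / "frames.tsv", "w", encoding="utf-8") as fh:
        fh.write("frame_idx\ttimestamp\n")
        for i, t in enumerate(rt.frame_rec_times):
            fh.write(f"{i}\t{t:.6f}\n")

    write_detections(dets, d / "detections.tsv")
    spec.calib.to_file(d / "calibration.txt")

    lines = ["kind\tstart_frame\tend_frame\tsource"]
    if vor_win and rec.role == "eye_tracker":
        f0, f1 = _world_window_to_frames(vor_win, frame_world)
        lines.append(f"sync_et\t{f0}\t{f1}\tmanual")
    if val_win and rec.role == "eye_tracker":
        f0, f1 = _world_window_to_frames(val_win, frame_world)
        lines.append(f"validation\t{f0}\t{f1}\tmanual")
    (d / "coding.tsv").write_text("\n".join(lines) + "\n", encoding="utf-8")

    if rec.role == "eye_tracker":
        with open(d / "gaze.tsv", "w", encoding="utf-8") as fh:
            fh.write("timestamp\tgaze_x\tgaze_y\n")
            for t, (x, y) in zip(rt.gaze_rec_times, noisy_px):
                fh.write(f"{t:.6f}\t{x:.4f}\t{y:.4f}\n")


def _write_project_files(root: Path, spec: SimulationSpec, plane, gt: GroundTruth) -> None:
    root.mkdir(parents=True, exist_ok=True)
    (root / "planes").mkdir(exist_ok=True)
    save_plane_definition(plane, root / "planes" / f"{plane.name}.toml")

    lines = [
        f'name = "{spec.session_name}"',
        f'reference_recording = "{spec.reference}"',
        "",
        "[options]",
        'method = "auto"',
        f"expected_gaze_rate_hz = {spec.gaze_rate_hz}",
        "",
        "[[plane]]",
        f'file = "planes/{plane.name}.toml"',
    ]
    for mid, purpose in (
        (TRIAL_START_ID, "trial_start"),
        (TRIAL_END_ID, "trial_end"),
        (SYNC_MARKER_ID, "sync_transient"),
    ):
        lines += ["", "[[individual_marker]]", f"id = {mid}", f'purpose = "{purpose}"']
    for rec in spec.recordings:
        lines += [
            "",
            "[[recording]]",
            f'id = "{rec.id}"',
            f'role = "{rec.role}"',
        ]
    (root / "session.toml").write_text("\n".join(lines) + "\n", encoding="utf-8")

    truth = {
        "recordings": {
            r.id: {
                "latency_s": r.latency,
                "clock_scale": r.clock_scale,
                "clock_offset_s": r.clock_offset,
                "role": r.role,
            }
            for r in spec.recordings
        },
        "transient_world_times_s": list(spec.transient_times),
        "trial_world_intervals_s": [list(t) for t in gt.trial_world_intervals],
        "validation_window_s": list(gt.validation_window) if gt.validation_window else None,
        "vor_window_s": list(gt.vor_window) if gt.vor_window else None,
        "dwell_schedule": [[n, s, e] for n, s, e in gt.dwell_schedule],
        "gaze_offset_deg": spec.gaze_offset_deg,
        "seed": spec.seed,
    }
    (root / "ground_truth.json").write_text(
        json.dumps(truth, indent=2) + "\n", encoding="utf-8"
    )
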