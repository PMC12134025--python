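"""Project configuration, recording I/O, episode coding, and the pipeline.

A *project* is a directory holding one session::

    project/
      session.toml            session + recording + marker configuration
      planes/<name>.toml      plane definitions
      recordings/<id>/
        gaze.tsv              internal gaze format (eye trackers only)
        frames.tsv            frame_idx -> recording timestamp
        detections.tsv        marker detections cache
        calibration.txt       optional camera calibration
        coding.tsv            episode coding (trial/validation/sync intervals)
      output/                 everything the pipeline writes

The internal gaze format is a tab-separated file with at least a
``timestamp`` (seconds by default), ``gaze_x`` and ``gaze_y`` column
per sample.  Episode codings are frame-indexed intervals, matching how
a video coder works.

The pipeline steps (``validate-setup``, ``detect``, ``code-auto``,
``sync``, ``map``, ``quality``, ``export``) are idempotent: a step
whose outputs already exist is skipped unless forced, and step status
is derived purely from on-disk artifacts.
"""

from __future__ import annotations

import json
import math
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .camera import CameraCalibration, Pose
from .mapping import (
    GazeSample,
    PlaneGaze,
    Trial,
    build_observations,
    detect_individual_marker_episodes,
    episodes_to_trials,
    map_gaze_to_plane,
    read_detections,
)
from .planes import (
    IndividualMarker,
    PlaneDefinition,
    load_plane_definition,
    validate_setup,
)
from .quality import (
    DataQualityResult,
    TargetQuality,
    assign_samples_to_targets,
    compute_accuracy,
    compute_data_loss,
    compute_precision,
    summarize_quality,
)
from .sync import (
    PlanarSignal,
    SyncModel,
    estimate_vor_offset,
    extract_target_signal,
    fit_sync_model,
    to_reference_time,
)

__all__ = [
    "SessionConfig",
    "RecordingMeta",
    "EpisodeCoding",
    "read_gaze_internal",
    "read_coding",
    "write_coding",
    "load_session_config",
    "collate_export",
    "run_pipeline",
    "PIPELINE_STEPS",
]

CODING_KINDS = ("trial", "validation", "sync_et", "sync_cam")
PIPELINE_STEPS = ("validate-setup", "detect", "code-auto", "sync", "map", "quality", "export")
_STEP_DEPS = {
    "validate-setup": (),
    "detect": (),
    "code-auto": ("detect",),
    "sync": ("detect",),
    "map": ("detect", "sync"),
    "quality": ("map",),
    "export": ("map", "sync", "code-auto"),
}


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class RecordingMeta:
    id: str
    role: str  # "eye_tracker" | "overview_camera"
    gaze_path: Path | None = None
    frames_path: Path | None = None
    detections_path: Path | None = None
    calibration_path: Path | None = None
    coding_path: Path | None = None

    def __post_init__(self) -> None:
        if self.role not in ("eye_tracker", "overview_camera"):
            raise ValueError(f"unknown recording role {self.role!r}")
        if self.role == "eye_tracker" and self.gaze_path is None:
            raise ValueError(f"eye-tracker recording {self.id!r} needs a gaze file")
        if self.role == "overview_camera" and self.gaze_path is not None:
            raise ValueError(f"overview camera {self.id!r} must not have a gaze file")


@dataclass(frozen=True)
class SessionConfig:
    name: str
    recordings: tuple[RecordingMeta, ...]
    planes: tuple[PlaneDefinition, ...]
    individual_markers: tuple[IndividualMarker, ...]
    reference: str
    method: str = "auto"
    expected_gaze_rate_hz: float | None = None
    vor_window_s: float = 1.0
    vor_step_s: float = 0.001
    min_samples_s: float = 0.3

    def __post_init__(self) -> None:
        ids = [r.id for r in self.recordings]
        if self.reference not in ids:
            raise ValueError(
                f"reference recording {self.reference!r} is not one of {ids}"
            )
        if not any(r.role == "eye_tracker" for r in self.recordings):
            raise ValueError("a session needs at least one eye-tracker recording")

    def recording(self, rec_id: str) -> RecordingMeta:
        for r in self.recordings:
            if r.id == rec_id:
                return r
        raise KeyError(rec_id)


@dataclass(frozen=True)
class EpisodeCoding:
    recording: str
    kind: str
    start_frame: int
    end_frame: int  # inclusive
    source: str = "manual"

    def __post_init__(self) -> None:
        if self.kind not in CODING_KINDS:
            raise ValueError(f"unknown episode kind {self.kind!r}")
        if self.start_frame > self.end_frame:
            raise ValueError("episode start_frame must be <= end_frame")
        if self.source not in ("manual", "auto", "auto_verified"):
            raise ValueError(f"unknown coding source {self.source!r}")


# --------------------------------------------------------------------------
# file formats
# --------------------------------------------------------------------------

def read_gaze_internal(path, time_unit: str = "s") -> list[GazeSample]:
    """Read the internal gaze format: TSV with timestamp, gaze_x, gaze_y.

    Extra columns are ignored.  Rows whose coordinates do not parse (or
    are NaN) are kept as missing-position samples.  Timestamps must be
    strictly increasing; a regression is an error naming the line.
    ``time_unit`` is ``"s"`` (default) or ``"ms"``.
    """
    scale = {"s": 1.0, "ms": 1e-3}[time_unit]
    df = pd.read_csv(path, sep="\t")
    required = {"timestamp", "gaze_x", "gaze_y"}
    if missing := required - set(df.columns):
        raise ValueError(f"gaze file {path} missing columns {sorted(missing)}")
    if len(df) == 0:
        raise ValueError(f"gaze file {path} is empty")
    out: list[GazeSample] = []
    prev = -math.inf
    for line_no, row in enumerate(df.itertuples(), start=2):
        t = float(row.timestamp) * scale
        if t <= prev:
            raise ValueError(f"gaze file {path}: timestamp regression at line {line_no}")
        prev = t
        try:
            x, y = float(row.gaze_x), float(row.gaze_y)
            pos = (x, y) if math.isfinite(x) and math.isfinite(y) else None
        except (TypeError, ValueError):
            pos = None
        out.append(GazeSample(t, pos))
    return out


def read_coding(path, recording: str = "") -> list[EpisodeCoding]:
    """Read a frame-indexed episode-coding TSV; same-kind overlaps rejected."""
    df = pd.read_csv(path, sep="\t")
    if missing := {"kind", "start_frame", "end_frame"} - set(df.columns):
        raise ValueError(f"coding file {path} missing columns {sorted(missing)}")
    eps = [
        EpisodeCoding(
            recording, str(r.kind), int(r.start_frame), int(r.end_frame),
            str(getattr(r, "source", "manual")),
        )
        for r in df.itertuples()
    ]
    by_kind: dict[str, list[EpisodeCoding]] = {}
    for e in eps:
        by_kind.setdefault(e.kind, []).append(e)
    for kind, group in by_kind.items():
        group = sorted(group, key=lambda e: e.start_frame)
        for a, b in zip(group, group[1:]):
            if b.start_frame <= a.end_frame:
                raise ValueError(
                    f"coding file {path}: overlapping {kind!r} episodes "
                    f"[{a.start_frame},{a.end_frame}] and [{b.start_frame},{b.end_frame}]"
                )
    return eps


def write_coding(episodes, path) -> None:
    rows = sorted(
        [(e.kind, e.start_frame, e.end_frame, e.source) for e in episodes],
        key=lambda r: (r[1], r[0]),
    )
    pd.DataFrame(rows, columns=["kind", "start_frame", "end_frame", "source"]).to_csv(
        path, sep="\t", index=False
    )


def load_session_config(project_dir) -> SessionConfig:
    """Load ``session.toml`` and the plane files it references."""
    root = Path(project_dir)
    cfg_path = root / "session.toml"
    with open(cfg_path, "rb") as fh:
        raw = tomllib.load(fh)

    planes = tuple(
        load_plane_definition(root / p["file"]) for p in raw.get("plane", [])
    )
    markers = tuple(
        IndividualMarker(
            marker_id=int(m["id"]),
            purpose=str(m["purpose"]),
            edge_size=float(m.get("edge_size_mm", 40.0)),
        )
        for m in raw.get("individual_marker", [])
    )
    recs = []
    for r in raw.get("recording", []):
        rid, role = str(r["id"]), str(r.get("role", "eye_tracker"))
        d = root / "recordings" / rid
        recs.append(RecordingMeta(
            id=rid,
            role=role,
            gaze_path=(d / "gaze.tsv") if role == "eye_tracker" else None,
            frames_path=d / "frames.tsv",
            detections_path=d / "detections.tsv",
            calibration_path=(d / "calibration.txt") if (d / "calibration.txt").exists() else None,
            coding_path=d / "coding.tsv",
        ))
    opts = raw.get("options", {})
    return SessionConfig(
        name=str(raw.get("name", root.name)),
        recordings=tuple(recs),
        planes=planes,
        individual_markers=markers,
        reference=str(raw["reference_recording"]),
        method=str(opts.get("method", "auto")),
        expected_gaze_rate_hz=opts.get("expected_gaze_rate_hz"),
        vor_window_s=float(opts.get("vor_window_s", 1.0)),
        vor_step_s=float(opts.get("vor_step_s", 0.001)),
        min_samples_s=float(opts.get("min_samples_s", 0.3)),
    )


def _read_frames(path) -> np.ndarray:
    df = pd.read_csv(path, sep="\t")
    return df["timestamp"].to_numpy(dtype=float)


# --------------------------------------------------------------------------
# export
# --------------------------------------------------------------------------

EXPORT_COLUMNS = [
    "ref_timestamp", "recording", "trial", "plane", "x_mm", "y_mm", "method", "valid",
]


def collate_export(
    recording: str,
    mapped: dict[str, list[PlaneGaze]],
    trials_ref: list[Trial],
    model: SyncModel,
) -> pd.DataFrame:
    """One participant's export table: plane gaze in reference time.

    Rows carry the trial number whose reference-time interval contains
    them (0 outside all trials); invalid samples carry no coordinates.
    """
    rows = []
    for plane_name, pgs in sorted(mapped.items()):
        for pg in pgs:
            t_ref = float(to_reference_time(model, pg.timestamp))
            trial_no = 0
            for tr in trials_ref:
                if tr.start <= t_ref <= tr.end:
                    trial_no = tr.number
                    break
            if pg.valid and pg.pos_mm is not None:
                rows.append([t_ref, recording, trial_no, plane_name,
                             pg.pos_mm[0], pg.pos_mm[1], pg.method, True])
            else:
                rows.append([t_ref, recording, trial_no, plane_name,
                             np.nan, np.nan, None, False])
    df = pd.DataFrame(rows, columns=EXPORT_COLUMNS)
    return df.sort_values(["plane", "ref_timestamp"], kind="stable").reset_index(drop=True)


# --------------------------------------------------------------------------
# pipeline
# --------------------------------------------------------------------------

class PipelineError(RuntimeError):
    pass


def _out(root: Path) -> Path:
    return Path(root) / "output"


def _step_done(root: Path, cfg: SessionConfig, step: str) -> bool:
    out = _out(root)
    if step == "validate-setup":
        return (out / "setup_validation.tsv").exists()
    if step == "detect":
        return all(
            r.detections_path and r.detections_path.exists()
            and r.frames_path and r.frames_path.exists()
            for r in cfg.recordings
        )
    if step == "code-auto":
        return all((out / r.id / "coding_auto.tsv").exists() for r in cfg.recordings)
    if step == "sync":
        return (out / "sync_report.tsv").exists()
    if step == "map":
        return all(
            (out / r.id / f"mapped_{p.name}.tsv").exists()
            for r in cfg.recordings
            for p in cfg.planes
        )
    if step == "quality":
        return (out / "data_quality.tsv").exists()
    if step == "export":
        return all(
            (out / f"export_{r.id}.tsv").exists()
            for r in cfg.recordings
            if r.role == "eye_tracker"
        )
    raise ValueError(f"unknown step {step!r}")


def _load_calib(meta: RecordingMeta) -> CameraCalibration | None:
    if meta.calibration_path and meta.calibration_path.exists():
        return CameraCalibration.from_file(meta.calibration_path)
    return None


_OBS_CACHE: dict[tuple, tuple] = {}


def _all_observations(cfg: SessionConfig, meta: RecordingMeta):
    """Per-plane frame observations for a recording, cached on file identity.

    Geometry estimation dominates pipeline runtime; several steps need
    the same observations, so they are memoized on the detections file's
    path and mtime (a pure function of the on-disk artifact).
    """
    key = (
        str(meta.detections_path), meta.detections_path.stat().st_mtime_ns,
        tuple(p.name for p in cfg.planes),
        str(meta.calibration_path) if meta.calibration_path else None,
    )
    if key in _OBS_CACHE:
        return _OBS_CACHE[key]
    dets = read_detections(meta.detections_path)
    calib = _load_calib(meta)
    result = ({p.name: build_observations(dets, p, calib) for p in cfg.planes}, dets, calib)
    if len(_OBS_CACHE) > 16:
        _OBS_CACHE.clear()
    _OBS_CACHE[key] = result
    return result


def _combined_coding(root: Path, meta: RecordingMeta) -> list[EpisodeCoding]:
    eps: list[EpisodeCoding] = []
    if meta.coding_path and meta.coding_path.exists():
        eps += read_coding(meta.coding_path, meta.id)
    auto = _out(root) / meta.id / "coding_auto.tsv"
    if auto.exists():
        eps += read_coding(auto, meta.id)
    return eps


def _read_sync_report(root: Path) -> pd.DataFrame:
    return pd.read_csv(_out(root) / "sync_report.tsv", sep="\t")


def _sync_model_for(root: Path, cfg: SessionConfig, rec_id: str) -> SyncModel:
    df = _read_sync_report(root)
    row = df[df.recording == rec_id]
    if len(row) == 0:
        raise PipelineError(f"no sync model for recording {rec_id!r}")
    r = row.iloc[0]
    return SyncModel(rec_id, cfg.reference, float(r.a), float(r.b),
                     float(r.residual_rms), int(r.n_pairs))


def _vor_offset_for(root: Path, rec_id: str) -> float:
    df = _read_sync_report(root)
    row = df[df.recording == rec_id]
    if len(row) == 0:
        return 0.0
    v = row.iloc[0].vor_offset
    return 0.0 if pd.isna(v) else float(v)


def run_pipeline(
    project_dir,
    steps=PIPELINE_STEPS,
    force: bool = False,
    method: str | None = None,
) -> dict[str, str]:
    """Run pipeline steps on a project directory; returns step -> status.

    Statuses: ``done``, ``skipped (up to date)``.  A step whose
    dependencies have not been run raises :class:`PipelineError` naming
    the missing step.  Re-running a completed step without ``force`` is
    a no-op.
    """
    root = Path(project_dir)
    cfg = load_session_config(root)
    if method:
        cfg = SessionConfig(**{**cfg.__dict__, "method": method})
    out = _out(root)
    out.mkdir(exist_ok=True)
    log = out / "pipeline.log"
    status: dict[str, str] = {}

    requested = [s for s in PIPELINE_STEPS if s in set(steps)]
    unknown = set(steps) - set(PIPELINE_STEPS)
    if unknown:
        raise ValueError(f"unknown pipeline steps: {sorted(unknown)}")

    for step in requested:
        for dep in _STEP_DEPS[step]:
            if not _step_done(root, cfg, dep) and dep not in requested[:requested.index(step)]:
                raise PipelineError(f"step {step!r} requires {dep!r} to have run first")
        if _step_done(root, cfg, step) and not force:
            status[step] = "skipped (up to date)"
            continue
        _STEP_FUNCS[step](root, cfg)
        status[step] = "done"
        with open(log, "a", encoding="utf-8") as fh:
            fh.write(f"{step}\tdone\n")
    return status


# -- individual steps ------------------------------------------------------

def _step_validate(root: Path, cfg: SessionConfig) -> None:
    issues = validate_setup(list(cfg.planes), list(cfg.individual_markers))
    df = pd.DataFrame(
        [(i.severity, i.message) for i in issues], columns=["severity", "message"]
    )
    df.to_csv(_out(root) / "setup_validation.tsv", sep="\t", index=False)
    if any(i.severity == "ERROR" for i in issues):
        raise PipelineError(
            "setup validation failed: "
            + "; ".join(i.message for i in issues if i.severity == "ERROR")
        )


def _step_detect(root: Path, cfg: SessionConfig) -> None:
    # detection itself is a pluggable boundary; this step verifies that a
    # detections cache and frame timestamps exist for every recording
    missing = [
        r.id for r in cfg.recordings
        if not (r.detections_path and r.detections_path.exists()
                and r.frames_path and r.frames_path.exists())
    ]
    if missing:
        raise PipelineError(
            f"no detections cache for recordings {missing}; run a marker "
            "detector externally or generate a synthetic session"
        )


def _step_code_auto(root: Path, cfg: SessionConfig) -> None:
    for meta in cfg.recordings:
        dets = read_detections(meta.detections_path)
        frames = _read_frames(meta.frames_path)

        def to_frames(s: float, e: float) -> tuple[int, int]:
            f0 = int(np.searchsorted(frames, s - 1e-9))
            f1 = max(f0, int(np.searchsorted(frames, e + 1e-9)) - 1)
            return f0, f1

        eps: list[EpisodeCoding] = []
        starts: list[tuple[float, float]] = []
        ends: list[tuple[float, float]] = []
        for m in cfg.individual_markers:
            found = detect_individual_marker_episodes(dets, m, 0.1, 0.2)
            if m.purpose == "sync_transient":
                for s, e in found:
                    f0, f1 = to_frames(s, e)
                    eps.append(EpisodeCoding(meta.id, "sync_cam", f0, f1, "auto"))
            elif m.purpose == "trial_start":
                starts += found
            else:
                ends += found
        trials, _ = episodes_to_trials(starts, ends)
        for tr in trials:
            f0, f1 = to_frames(tr.start, tr.end)
            eps.append(EpisodeCoding(meta.id, "trial", f0, f1, "auto"))
        d = _out(root) / meta.id
        d.mkdir(parents=True, exist_ok=True)
        write_coding(eps, d / "coding_auto.tsv")


def _step_sync(root: Path, cfg: SessionConfig) -> None:
    # transient times per recording (first frame of each detected episode)
    transient_ts: dict[str, list[float]] = {}
    for meta in cfg.recordings:
        dets = read_detections(meta.detections_path)
        sync_markers = [m for m in cfg.individual_markers if m.purpose == "sync_transient"]
        ts: list[float] = []
        for m in sync_markers:
            ts += [s for (s, _) in detect_individual_marker_episodes(dets, m, 0.1, 0.2)]
        transient_ts[meta.id] = sorted(ts)

    ref_ts = transient_ts.get(cfg.reference, [])
    rows = []
    for meta in cfg.recordings:
        if meta.id == cfg.reference:
            model = SyncModel.identity(cfg.reference)
        else:
            own = transient_ts[meta.id]
            n = min(len(own), len(ref_ts))
            if n == 0:
                raise PipelineError(
                    f"cannot sync recording {meta.id!r}: no shared transients detected"
                )
            model = fit_sync_model(list(zip(own[:n], ref_ts[:n])), meta.id, cfg.reference)

        vor_offset, vor_corr = np.nan, np.nan
        if meta.role == "eye_tracker":
            res = _estimate_recording_vor(root, cfg, meta)
            if res is not None:
                vor_offset, vor_corr = res.offset, res.peak_correlation
        rows.append([meta.id, model.a, model.b, model.residual_rms, model.n_pairs,
                     vor_offset, vor_corr])
    pd.DataFrame(
        rows,
        columns=["recording", "a", "b", "residual_rms", "n_pairs",
                 "vor_offset", "vor_peak_correlation"],
    ).to_csv(_out(root) / "sync_report.tsv", sep="\t", index=False, float_format="%.9f")


def _estimate_recording_vor(root: Path, cfg: SessionConfig, meta: RecordingMeta):
    coding = _combined_coding(root, meta)
    vor_eps = [e for e in coding if e.kind == "sync_et"]
    if not vor_eps:
        return None
    obs_by_plane, dets, calib = _all_observations(cfg, meta)
    frames = _read_frames(meta.frames_path)
    gaze = read_gaze_internal(meta.gaze_path)
    plane = cfg.planes[0]
    obs = obs_by_plane[plane.name]
    ep = vor_eps[0]
    fidx = list(range(ep.start_frame, min(ep.end_frame + 1, len(frames))))
    target = extract_target_signal(
        obs, fidx, frames[fidx], plane, plane.center_target(), calib
    )
    g = [s for s in gaze if s.gaze_px is not None
         and frames[ep.start_frame] - 1.5 <= s.timestamp <= frames[min(ep.end_frame, len(frames) - 1)] + 1.5]
    gsig = PlanarSignal(
        np.array([s.timestamp for s in g]),
        np.array([s.gaze_px for s in g]),
        label="gaze",
    )
    return estimate_vor_offset(gsig, target, window=cfg.vor_window_s, step=cfg.vor_step_s)


def _step_map(root: Path, cfg: SessionConfig) -> None:
    for meta in cfg.recordings:
        obs_by_plane, dets, calib = _all_observations(cfg, meta)
        frames = _read_frames(meta.frames_path)
        d = _out(root) / meta.id
        d.mkdir(parents=True, exist_ok=True)
        # overview cameras have no gaze; their observations are still cached
        # (pose/homography per frame) for cross-camera projection
        for plane in cfg.planes:
            obs = obs_by_plane[plane.name]
            if meta.role == "eye_tracker":
                gaze = read_gaze_internal(meta.gaze_path)
                offset = _vor_offset_for(root, meta.id)
                if offset:
                    gaze = [GazeSample(g.timestamp + offset, g.gaze_px) for g in gaze]
                pgs = map_gaze_to_plane(gaze, obs, frames, plane, calib, cfg.method)
                rows = [
                    [pg.timestamp, pg.frame_idx,
                     pg.pos_mm[0] if pg.valid else np.nan,
                     pg.pos_mm[1] if pg.valid else np.nan,
                     pg.method or "", pg.valid]
                    for pg in pgs
                ]
                pd.DataFrame(
                    rows, columns=["timestamp", "frame_idx", "x_mm", "y_mm", "method", "valid"],
                ).to_csv(d / f"mapped_{plane.name}.tsv", sep="\t", index=False,
                         float_format="%.6f")
            else:
                rows = [
                    [frames[fi], fi, o.n_markers_used, o.reprojection_rms,
                     o.pose is not None]
                    for fi, o in sorted(obs.items())
                ]
                pd.DataFrame(
                    rows,
                    columns=["timestamp", "frame_idx", "n_markers", "rms", "has_pose"],
                ).to_csv(d / f"mapped_{plane.name}.tsv", sep="\t", index=False,
                         float_format="%.6f")


def _step_quality(root: Path, cfg: SessionConfig) -> None:
    results: list[DataQualityResult] = []
    for meta in cfg.recordings:
        if meta.role != "eye_tracker":
            continue
        coding = _combined_coding(root, meta)
        val_eps = [e for e in coding if e.kind == "validation"]
        if not val_eps:
            continue
        obs_by_plane, dets, calib = _all_observations(cfg, meta)
        frames = _read_frames(meta.frames_path)
        gaze = read_gaze_internal(meta.gaze_path)
        offset = _vor_offset_for(root, meta.id)
        if offset:
            gaze = [GazeSample(g.timestamp + offset, g.gaze_px) for g in gaze]
        plane = cfg.planes[0]
        obs = obs_by_plane[plane.name]
        poses = {fi: o.pose for fi, o in obs.items() if o.pose is not None}
        rate = cfg.expected_gaze_rate_hz
        for ep in val_eps:
            t0, t1 = frames[ep.start_frame], frames[min(ep.end_frame, len(frames) - 1)]
            ep_gaze = [g for g in gaze if t0 <= g.timestamp <= t1]
            if not ep_gaze:
                continue
            pgs = map_gaze_to_plane(ep_gaze, obs, frames, plane, calib, cfg.method)
            min_samples = max(2, int(round(cfg.min_samples_s * (rate or _rate_of(ep_gaze)))))
            assigns = assign_samples_to_targets(pgs, plane.targets, min_samples)
            tqs = []
            for a in assigns:
                tgt = next(t for t in plane.targets if t.name == a.target)
                try:
                    acc = compute_accuracy(a, pgs, tgt, poses)
                except ValueError:
                    acc = None
                try:
                    rms, std = compute_precision(a, pgs, poses)
                except ValueError:
                    rms = std = None
                tqs.append(TargetQuality(a.target, acc, rms, std, len(a.indices)))
            loss, _ = compute_data_loss(ep_gaze, t1 - t0, rate)
            dist = _median_viewing_distance(pgs, poses)
            results.append(DataQualityResult(
                meta.id, (float(t0), float(t1)), tqs, loss, dist,
            ))
    summarize_quality(results).to_csv(
        _out(root) / "data_quality.tsv", sep="\t", index=False, float_format="%.4f"
    )


def _rate_of(gaze: list[GazeSample]) -> float:
    ts = np.array([g.timestamp for g in gaze])
    return 1.0 / float(np.median(np.diff(ts)))


def _median_viewing_distance(pgs: list[PlaneGaze], poses: dict[int, Pose]) -> float | None:
    ds = [
        float(np.linalg.norm(poses[pg.frame_idx].camera_center))
        for pg in pgs
        if pg.valid and pg.frame_idx in poses
    ]
    return float(np.median(ds)) if ds else None


def _step_export(root: Path, cfg: SessionConfig) -> None:
    multi = len(cfg.recordings) > 1
    # session-global trials in reference time, from the reference recording's
    # paddle-marker episodes
    ref_meta = cfg.recording(cfg.reference)
    dets_ref = read_detections(ref_meta.detections_path)
    start_m = [m for m in cfg.individual_markers if m.purpose == "trial_start"]
    end_m = [m for m in cfg.individual_markers if m.purpose == "trial_end"]
    starts, ends = [], []
    for m in start_m:
        starts += detect_individual_marker_episodes(dets_ref, m, 0.1, 0.2)
    for m in end_m:
        ends += detect_individual_marker_episodes(dets_ref, m, 0.1, 0.2)
    trials, trial_issues = episodes_to_trials(starts, ends)

    for meta in cfg.recordings:
        if meta.role != "eye_tracker":
            continue
        if multi:
            model = _sync_model_for(root, cfg, meta.id) if meta.id != cfg.reference \
                else SyncModel.identity(cfg.reference)
        else:
            model = SyncModel.identity(meta.id)
        mapped: dict[str, list[PlaneGaze]] = {}
        for plane in cfg.planes:
            path = _out(root) / meta.id / f"mapped_{plane.name}.tsv"
            df = pd.read_csv(path, sep="\t")
            mapped[plane.name] = [
                PlaneGaze(
                    float(r.timestamp), plane.name,
                    (float(r.x_mm), float(r.y_mm)) if bool(r.valid) else None,
                    (r.method if isinstance(r.method, str) and r.method else None),
                    int(r.frame_idx), bool(r.valid),
                )
                for r in df.itertuples()
            ]
        df = collate_export(meta.id, mapped, trials, model)
        df.to_csv(_out(root) / f"export_{meta.id}.tsv", sep="\t", index=False,
                  float_format="%.6f")
    if trial_issues:
        (_out(root) / "trial_issues.txt").write_text(
            "\n".join(trial_issues) + "\n", encoding="utf-8"
        )


_STEP_FUNCS = {
    "validate-setup": _step_validate,
    "detect": _step_detect,
    "code-auto": _step_code_auto,
    "sync": _step_sync,
    "map": _step_map,
    "quality": _step_quality,
    "export": _step_export,
}
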