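"""Per-frame plane geometry, gaze-to-plane mapping, and marker episodes.

The pipeline turns raw per-frame fiducial-marker corner detections into
per-frame plane geometry (homography and, with a calibrated camera, a
full pose), maps timestamped gaze pixels onto plane coordinates in mm,
transfers plane gaze into another camera's view, and segments
recordings into trials from the appearance episodes of individual
markers (e.g., a two-sided paddle flipped at trial start/end).

Marker *detection* itself is a pluggable boundary: any callable
producing :class:`MarkerDetection` rows can feed this module, and the
synthetic session generator emits detections analytically.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .camera import (
    CameraCalibration,
    GeometryError,
    Homography,
    Pose,
    apply_homography,
    estimate_homography,
    estimate_pose,
    intersect_gaze_ray,
    plane_to_pixel,
)
from .planes import IndividualMarker, PlaneDefinition, marker_corners_mm

__all__ = [
    "MarkerDetection",
    "FramePlaneObservation",
    "GazeSample",
    "PlaneGaze",
    "Trial",
    "detect_markers",
    "read_detections",
    "write_detections",
    "estimate_frame_geometry",
    "build_observations",
    "associate_gaze_to_frames",
    "map_gaze_to_plane",
    "map_plane_gaze_to_camera",
    "detect_individual_marker_episodes",
    "episodes_to_trials",
]


@dataclass(frozen=True)
class MarkerDetection:
    """One detected marker in one video frame; corners in detector order."""

    frame_idx: int
    frame_timestamp: float
    marker_id: int
    corners: np.ndarray  # (4, 2) pixels

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "corners", np.asarray(self.corners, dtype=float).reshape(4, 2)
        )


@dataclass(frozen=True)
class FramePlaneObservation:
    frame_idx: int
    plane: str
    homography: Homography | None
    pose: Pose | None
    n_markers_used: int
    reprojection_rms: float
    flags: tuple[str, ...] = ()


@dataclass(frozen=True)
class GazeSample:
    """Head-centred gaze: a timestamp (s, recording clock) and a scene-video pixel."""

    timestamp: float
    gaze_px: tuple[float, float] | None  # None = missing sample


@dataclass(frozen=True)
class PlaneGaze:
    """World-centred gaze: position on a named plane in mm."""

    timestamp: float
    plane: str
    pos_mm: tuple[float, float] | None
    method: str | None  # "homography" | "pose"
    frame_idx: int
    valid: bool


@dataclass(frozen=True)
class Trial:
    number: int
    start: float
    end: float


# --------------------------------------------------------------------------
# detection boundary + cache format
# --------------------------------------------------------------------------

def detect_markers(
    frames: Iterable, families: Sequence[str],
    detector: Callable[..., list[MarkerDetection]] | None = None,
) -> list[MarkerDetection]:
    """Run a pluggable fiducial-marker detector over video frames.

    This package ships no detector of its own; pass a callable
    ``detector(frames, families) -> list[MarkerDetection]`` wrapping
    e.g. an ArUco implementation.  All built-in processing consumes
    pre-computed detection caches instead (see :func:`read_detections`),
    which the synthetic session generator produces analytically.
    """
    if detector is None:
        raise NotImplementedError(
            "no marker detector plugged in; supply detector= or use a "
            "pre-computed detections cache"
        )
    return detector(frames, families)


_DET_COLUMNS = [
    "frame_idx", "timestamp", "marker_id",
    "c0x", "c0y", "c1x", "c1y", "c2x", "c2y", "c3x", "c3y",
]


def write_detections(dets: Iterable[MarkerDetection], path) -> None:
    rows = [
        [d.frame_idx, d.frame_timestamp, d.marker_id, *d.corners.ravel()]
        for d in dets
    ]
    pd.DataFrame(rows, columns=_DET_COLUMNS).to_csv(
        path, sep="\t", index=False, float_format="%.6f"
    )


def read_detections(path) -> list[MarkerDetection]:
    df = pd.read_csv(path, sep="\t")
    missing = set(_DET_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"detections cache {path} missing columns {sorted(missing)}")
    return [
        MarkerDetection(
            int(r.frame_idx), float(r.timestamp), int(r.marker_id),
            np.array([[r.c0x, r.c0y], [r.c1x, r.c1y], [r.c2x, r.c2y], [r.c3x, r.c3y]]),
        )
        for r in df.itertuples()
    ]


# --------------------------------------------------------------------------
# per-frame geometry
# --------------------------------------------------------------------------

def estimate_frame_geometry(
    dets: Sequence[MarkerDetection],
    plane: PlaneDefinition,
    calib: CameraCalibration | None = None,
) -> FramePlaneObservation | None:
    """Estimate plane geometry for one frame from its marker detections.

    Returns ``None`` when fewer than ``plane.min_markers`` of this
    plane's markers are detected or the correspondences are degenerate.
    The homography is always estimated from all detected corners; a
    pose is additionally estimated when a calibration is available.
    """
    dets = [d for d in dets if d.marker_id in plane.marker_ids]
    if not dets:
        return None
    frame_idxs = {d.frame_idx for d in dets}
    if len(frame_idxs) != 1:
        raise ValueError("detections must belong to a single frame")
    if len(dets) < plane.min_markers:
        return None

    pixels = np.vstack([d.corners for d in dets])
    plane_pts = np.vstack([marker_corners_mm(plane.marker_by_id(d.marker_id)) for d in dets])

    flags: list[str] = []
    if len(dets) == 1:
        flags.append("ambiguous pose risk")
    try:
        H = estimate_homography(pixels, plane_pts, calib)
    except GeometryError:
        return None
    pose = None
    rms = H.rms
    if calib is not None:
        try:
            pose, rms = estimate_pose(pixels, plane_pts, calib)
            if pose.ambiguous:
                flags.append("ambiguous")
        except GeometryError:
            pose = None
    return FramePlaneObservation(
        frame_idx=dets[0].frame_idx,
        plane=plane.name,
        homography=H,
        pose=pose,
        n_markers_used=len(dets),
        reprojection_rms=float(rms),
        flags=tuple(flags),
    )


def build_observations(
    dets: Sequence[MarkerDetection],
    plane: PlaneDefinition,
    calib: CameraCalibration | None = None,
) -> dict[int, FramePlaneObservation]:
    """Group detections by frame and estimate geometry frame by frame."""
    by_frame: dict[int, list[MarkerDetection]] = {}
    for d in dets:
        by_frame.setdefault(d.frame_idx, []).append(d)
    out: dict[int, FramePlaneObservation] = {}
    for idx in sorted(by_frame):
        obs = estimate_frame_geometry(by_frame[idx], plane, calib)
        if obs is not None:
            out[idx] = obs
    return out


# --------------------------------------------------------------------------
# gaze association + mapping
# --------------------------------------------------------------------------

def associate_gaze_to_frames(
    gaze_timestamps: np.ndarray, frame_timestamps: np.ndarray
) -> np.ndarray:
    """Assign each gaze sample the index of the nearest video frame.

    Ties go to the earlier frame.  Samples farther than one median
    frame interval beyond the first/last frame are flagged with -1.
    """
    gt = np.asarray(gaze_timestamps, dtype=float)
    ft = np.asarray(frame_timestamps, dtype=float)
    if gt.size == 0 or ft.size == 0:
        raise ValueError("empty timestamp series")
    right = np.searchsorted(ft, gt, side="left")
    left = np.clip(right - 1, 0, len(ft) - 1)
    right = np.clip(right, 0, len(ft) - 1)
    d_left = np.abs(gt - ft[left])
    d_right = np.abs(ft[right] - gt)
    idx = np.where(d_left <= d_right, left, right)  # tie -> earlier
    interval = float(np.median(np.diff(ft))) if len(ft) > 1 else np.inf
    out_of_range = (gt < ft[0] - interval) | (gt > ft[-1] + interval)
    idx = idx.astype(int)
    idx[out_of_range] = -1
    return idx


def map_gaze_to_plane(
    gaze: Sequence[GazeSample],
    observations: dict[int, FramePlaneObservation],
    frame_timestamps: np.ndarray,
    plane: PlaneDefinition,
    calib: CameraCalibration | None = None,
    method: str = "auto",
) -> list[PlaneGaze]:
    """Map gaze pixels to plane mm using per-frame geometry.

    ``method`` is ``"auto"`` (pose when available, else homography),
    ``"homography"`` or ``"pose"``.  Samples whose frame lacks a
    qualifying observation come back with ``valid=False``.
    """
    if method not in ("auto", "homography", "pose"):
        raise ValueError(f"unknown method {method!r}")
    if method == "pose" and calib is None:
        raise GeometryError("pose method requested but no calibration available")

    ts = np.array([g.timestamp for g in gaze], dtype=float)
    assignment = associate_gaze_to_frames(ts, frame_timestamps)

    out: list[PlaneGaze] = []
    for g, fidx in zip(gaze, assignment):
        obs = observations.get(int(fidx)) if fidx >= 0 else None
        invalid = PlaneGaze(g.timestamp, plane.name, None, None, int(fidx), False)
        if obs is None or g.gaze_px is None:
            out.append(invalid)
            continue
        use_pose = obs.pose is not None and calib is not None and method in ("auto", "pose")
        if method == "pose" and (obs.pose is None):
            out.append(invalid)
            continue
        try:
            if use_pose:
                pos = intersect_gaze_ray(np.asarray(g.gaze_px), obs.pose, calib)
                used = "pose"
            else:
                pos = apply_homography(obs.homography, np.asarray(g.gaze_px))
                used = "homography"
        except GeometryError:
            out.append(invalid)
            continue
        out.append(PlaneGaze(
            g.timestamp, plane.name, (float(pos[0]), float(pos[1])),
            used, int(fidx), True,
        ))
    return out


def map_plane_gaze_to_camera(
    plane_gaze: Sequence[PlaneGaze],
    source_to_ref: Callable[[float], float],
    observations_other: dict[int, FramePlaneObservation],
    frame_timestamps_other: np.ndarray,
    other_to_ref: Callable[[float], float],
    calib_other: CameraCalibration | None = None,
) -> list[tuple[float, tuple[float, float] | None]]:
    """Project plane gaze of one recording into another camera's view.

    Timestamps of both recordings are brought to reference time through
    their sync models (``source_to_ref`` / ``other_to_ref`` callables);
    each valid plane-gaze sample is paired with the other camera's
    nearest frame and mapped through that frame's geometry (pose path
    when the other camera is calibrated, else inverse homography).
    Returns ``(reference_timestamp, pixel-or-None)`` per input sample.
    """
    ft_ref = np.array([other_to_ref(t) for t in np.asarray(frame_timestamps_other, float)])
    frame_order = np.argsort(ft_ref, kind="stable")
    ft_sorted = ft_ref[frame_order]

    out: list[tuple[float, tuple[float, float] | None]] = []
    for pg in plane_gaze:
        t_ref = source_to_ref(pg.timestamp)
        if not pg.valid or pg.pos_mm is None:
            out.append((t_ref, None))
            continue
        pos = np.searchsorted(ft_sorted, t_ref, side="left")
        left = max(pos - 1, 0)
        right = min(pos, len(ft_sorted) - 1)
        k = left if abs(t_ref - ft_sorted[left]) <= abs(ft_sorted[right] - t_ref) else right
        fidx = int(frame_order[k])
        obs = observations_other.get(fidx)
        if obs is None:
            out.append((t_ref, None))
            continue
        try:
            if obs.pose is not None and calib_other is not None:
                px = plane_to_pixel(pg.pos_mm, pose=obs.pose, calib=calib_other)
            elif obs.homography is not None:
                px = plane_to_pixel(pg.pos_mm, homography=obs.homography)
            else:
                out.append((t_ref, None))
                continue
        except GeometryError:
            out.append((t_ref, None))
            continue
        out.append((t_ref, (float(px[0]), float(px[1]))))
    return out


# --------------------------------------------------------------------------
# individual-marker episodes and trials
# --------------------------------------------------------------------------

def detect_individual_marker_episodes(
    dets: Sequence[MarkerDetection],
    marker: IndividualMarker | int,
    min_duration: float = 0.3,
    max_gap: float = 0.2,
) -> list[tuple[float, float]]:
    """Find maximal visibility episodes of a single marker.

    Consecutive detections of the marker whose inter-frame gap is at
    most ``max_gap`` seconds belong to one episode; episodes shorter
    than ``min_duration`` are dropped.  Returns sorted, non-overlapping
    ``(start_ts, end_ts)`` pairs.
    """
    mid = marker.marker_id if isinstance(marker, IndividualMarker) else int(marker)
    ts = sorted({d.frame_timestamp for d in dets if d.marker_id == mid})
    episodes: list[tuple[float, float]] = []
    if not ts:
        return episodes
    start = prev = ts[0]
    for t in ts[1:]:
        if t - prev > max_gap:
            episodes.append((start, prev))
            start = t
        prev = t
    episodes.append((start, prev))
    return [(s, e) for s, e in episodes if e - s >= min_duration]


def episodes_to_trials(
    start_eps: Sequence[tuple[float, float]],
    end_eps: Sequence[tuple[float, float]],
) -> tuple[list[Trial], list[str]]:
    """Pair start/end marker episodes into numbered trials.

    A trial runs from the end of a start episode (the paddle is flipped
    away after presentation) to the beginning of the next end episode.
    Unpaired or interleaving-violating episodes are reported as issues.
    """
    starts = sorted(start_eps)
    ends = sorted(end_eps)
    trials: list[Trial] = []
    issues: list[str] = []
    i = j = 0
    pending: tuple[float, float] | None = None
    while i < len(starts) or j < len(ends):
        next_start = starts[i] if i < len(starts) else None
        next_end = ends[j] if j < len(ends) else None
        if next_end is not None and (next_start is None or next_end[0] < next_start[0]):
            if pending is None:
                issues.append(
                    f"end episode at {next_end[0]:.3f}s has no preceding start; skipped"
                )
            else:
                trials.append(Trial(len(trials) + 1, pending[1], next_end[0]))
                pending = None
            j += 1
        else:
            if pending is not None:
                issues.append(
                    f"start episode at {pending[0]:.3f}s unpaired before next start; dropped"
                )
            pending = next_start
            i += 1
    if pending is not None:
        issues.append(f"start episode at {pending[0]:.3f}s has no matching end; dropped")
    return trials, issues
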