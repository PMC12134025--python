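"""Gaze data-quality measures on a validation plane.

During a validation episode the participant fixates nine targets on a
marker-defined poster in reading order, ~1 s each.  From gaze mapped to
the poster plus the per-frame camera pose, the standard wearable
eye-tracking quality measures are computed per target:

* **accuracy** — median angular offset (deg) between the directions
  from the viewing position to the gaze point and to the target;
* **precision** — sample-to-sample RMS (RMS-S2S) and standard
  deviation of the angular gaze signal (deg), computed on
  azimuth/elevation so they are viewing-distance independent;
* **data loss** — fraction of expected samples missing in the episode.

The viewing position is the scene-camera optical centre; the offset
between the eye and the head-mounted camera is ignored (documented
limitation).  Angular measures therefore require a calibrated camera.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import median_filter

from .camera import Pose, angular_from_plane_point
from .mapping import GazeSample, PlaneGaze
from .planes import TargetPoint

__all__ = [
    "TargetAssignment",
    "DataQualityResult",
    "assign_samples_to_targets",
    "compute_accuracy",
    "compute_precision",
    "compute_data_loss",
    "summarize_quality",
]


@dataclass(frozen=True)
class TargetAssignment:
    """The contiguous run of plane-gaze samples attributed to one target."""

    target: str
    indices: tuple[int, ...]  # contiguous indices into the episode's PlaneGaze list


@dataclass
class TargetQuality:
    target: str
    accuracy_deg: float | None
    rms_s2s_deg: float | None
    std_deg: float | None
    n_samples: int


@dataclass
class DataQualityResult:
    recording: str
    episode: tuple[float, float]
    targets: list[TargetQuality]
    data_loss: float
    viewing_distance_mm: float | None
    flags: tuple[str, ...] = ()


# --------------------------------------------------------------------------

def assign_samples_to_targets(
    plane_gaze: Sequence[PlaneGaze],
    targets: Sequence[TargetPoint],
    min_samples: int,
) -> list[TargetAssignment]:
    """Attribute validation-episode samples to fixation targets.

    Each valid sample is labeled with its nearest target (Euclidean
    distance in mm); the label sequence is median-filtered over a
    5-sample window to suppress single-sample flicker; per target the
    longest contiguous run is kept, and runs shorter than
    ``min_samples`` are dropped.
    """
    if not targets:
        raise ValueError("need at least one target")
    tpos = np.array([[t.x, t.y] for t in targets], dtype=float)
    labels = np.full(len(plane_gaze), -1, dtype=int)
    for i, pg in enumerate(plane_gaze):
        if pg.valid and pg.pos_mm is not None:
            d = np.sum((tpos - np.asarray(pg.pos_mm)) ** 2, axis=1)
            labels[i] = int(np.argmin(d))
    if not np.any(labels >= 0):
        return []

    valid_idx = np.nonzero(labels >= 0)[0]
    filtered = labels.copy()
    filtered[valid_idx] = median_filter(
        labels[valid_idx], size=5, mode="nearest"
    )

    assignments: list[TargetAssignment] = []
    for k, t in enumerate(targets):
        runs: list[list[int]] = []
        cur: list[int] = []
        for i in valid_idx:
            if filtered[i] == k:
                if cur and i != cur[-1] + 1:
                    runs.append(cur)
                    cur = []
                cur.append(int(i))
            elif cur:
                runs.append(cur)
                cur = []
        if cur:
            runs.append(cur)
        if not runs:
            continue
        best = max(runs, key=len)
        if len(best) >= min_samples:
            assignments.append(TargetAssignment(t.name, tuple(best)))
    return assignments


def _angles_for_run(
    assign: TargetAssignment,
    plane_gaze: Sequence[PlaneGaze],
    poses: dict[int, Pose],
) -> np.ndarray:
    """(n, 2) azimuth/elevation in deg for the run's samples; requires poses."""
    out = []
    for i in assign.indices:
        pg = plane_gaze[i]
        pose = poses.get(pg.frame_idx)
        if pose is None or pg.pos_mm is None:
            continue
        a = angular_from_plane_point(pg.pos_mm, pose)
        out.append((a.azimuth, a.elevation))
    return np.asarray(out, dtype=float).reshape(-1, 2)


def compute_accuracy(
    assign: TargetAssignment,
    plane_gaze: Sequence[PlaneGaze],
    target: TargetPoint,
    poses: dict[int, Pose],
) -> float:
    """Median angular offset (deg) between gaze and target directions.

    Per sample the full 3-D angle between the camera-frame directions
    to the gaze point and to the target is taken; the run's accuracy is
    the median (robust to fixation onset/offset samples).
    """
    angles = []
    for i in assign.indices:
        pg = plane_gaze[i]
        pose = poses.get(pg.frame_idx)
        if pose is None:
            continue
        if pg.pos_mm is None:
            continue
        g = pose.R @ np.array([pg.pos_mm[0], pg.pos_mm[1], 0.0]) + pose.t
        tt = pose.R @ np.array([target.x, target.y, 0.0]) + pose.t
        cos = float(g @ tt / (np.linalg.norm(g) * np.linalg.norm(tt)))
        angles.append(math.degrees(math.acos(min(1.0, max(-1.0, cos)))))
    if not angles:
        raise ValueError("accuracy unavailable (uncalibrated): no poses for run")
    return float(np.median(angles))


def compute_precision(
    assign: TargetAssignment,
    plane_gaze: Sequence[PlaneGaze],
    poses: dict[int, Pose],
) -> tuple[float, float]:
    """(RMS-S2S, STD) of angular gaze over the run, in degrees.

    RMS-S2S is ``sqrt(mean((d_azimuth)^2 + (d_elevation)^2))`` over
    consecutive sample pairs; STD is ``sqrt(var(azimuth) +
    var(elevation))`` with population variance.
    """
    ang = _angles_for_run(assign, plane_gaze, poses)
    if len(ang) < 2:
        raise ValueError("precision undefined: run has fewer than 2 samples")
    d = np.diff(ang, axis=0)
    rms = float(np.sqrt(np.mean(np.sum(d**2, axis=1))))
    std = float(np.sqrt(ang[:, 0].var() + ang[:, 1].var()))
    return rms, std


def compute_data_loss(
    gaze: Sequence[GazeSample],
    duration: float,
    expected_rate: float | None = None,
) -> tuple[float, bool]:
    """Fraction of expected samples missing over the episode.

    ``1 - n_received / (duration * expected_rate)`` clamped to [0, 1];
    samples with non-finite coordinates count as lost.  When the
    expected rate is unknown it is estimated from the median
    inter-sample interval and the second return value is True.
    """
    if duration <= 0:
        raise ValueError("episode duration must be positive")
    estimated = False
    if expected_rate is None:
        ts = np.array([g.timestamp for g in gaze], dtype=float)
        if len(ts) < 2:
            raise ValueError("cannot estimate expected rate from < 2 samples")
        expected_rate = 1.0 / float(np.median(np.diff(ts)))
        estimated = True
    n_ok = sum(
        1 for g in gaze
        if g.gaze_px is not None and np.all(np.isfinite(g.gaze_px))
    )
    loss = 1.0 - n_ok / (duration * expected_rate)
    return float(min(1.0, max(0.0, loss))), estimated


# --------------------------------------------------------------------------

_QUALITY_COLUMNS = [
    "recording", "episode_start_s", "episode_end_s", "target",
    "accuracy_deg", "rms_s2s_deg", "std_deg", "n_samples",
    "data_loss", "viewing_distance_mm",
]


def summarize_quality(results: Sequence[DataQualityResult]) -> pd.DataFrame:
    """Collate per-target rows plus per-episode aggregate rows.

    The aggregate row (target ``"all(median)"``) holds the median
    across the episode's targets for each angular measure.
    """
    rows = []
    for r in results:
        for tq in r.targets:
            rows.append([
                r.recording, r.episode[0], r.episode[1], tq.target,
                tq.accuracy_deg, tq.rms_s2s_deg, tq.std_deg, tq.n_samples,
                r.data_loss, r.viewing_distance_mm,
            ])
        med = {
            name: (float(np.median([v for v in vals if v is not None]))
                   if any(v is not None for v in vals) else None)
            for name, vals in [
                ("acc", [t.accuracy_deg for t in r.targets]),
                ("rms", [t.rms_s2s_deg for t in r.targets]),
                ("std", [t.std_deg for t in r.targets]),
            ]
        }
        rows.append([
            r.recording, r.episode[0], r.episode[1], "all(median)",
            med["acc"], med["rms"], med["std"],
            int(sum(t.n_samples for t in r.targets)),
            r.data_loss, r.viewing_distance_mm,
        ])
    return pd.DataFrame(rows, columns=_QUALITY_COLUMNS)
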